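"""Per-population reports (text + XML) and cross-population TSV aggregation.

Every analysis run produces, per population, a machine-readable XML document
and a human-readable fixed-width text report; only the analyses actually
requested appear.  The aggregator mirrors a meta-analysis workflow: it reads
any number of per-population XML documents and emits a family of
tab-separated files, one per data granularity (locus, allele, genotype,
haplotype), generated dynamically — a file is written only when at least one
population contributed matching data.

TSV conventions: tab separators, LF line endings, a single header row, and
``NA`` for undefined values (e.g. ALD at a monomorphic locus).  The
permutation-test columns (``permu.n``, ``permu.pvalue``) appear only when a
permutation test was run.  Multi-locus haplotype files are named by their
locus count (``2-locus-haplo.tsv``, ``5-locus-haplo.tsv``, ...), with no
upper limit on the number of loci.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import IO, Sequence

from lxml import etree

from .ewens import EWResult
from .hardyweinberg import HWEChiSquareResult, HWEExactResult
from .haplotype import HaplotypeEstimate
from .linkage import LDPairResult, LDPermutationRecord
from .summaries import AlleleFrequencyTable, GenotypeCountTable

__all__ = [
    "LocusSummary",
    "HaplotypeBlock",
    "PopulationReport",
    "write_population_xml",
    "read_population_xml",
    "write_text_report",
    "aggregate_tsv",
    "TSV_SCHEMAS",
    "IHWG_COLUMNS",
]

# fixed, documented metadata columns for workshop-style meta-analyses;
# populated from .pop metadata keys of the same name, disabled by default
IHWG_COLUMNS = ("region", "ethnicity", "collection.site")


@dataclass
class LocusSummary:
    locus: str
    allele_table: AlleleFrequencyTable
    homozygosity: float
    genotype_table: GenotypeCountTable | None = None
    hwe_chisq: HWEChiSquareResult | None = None
    hwe_exact: HWEExactResult | None = None
    ew: EWResult | None = None
    n_untyped: int = 0  # individuals incomplete at this locus


@dataclass
class HaplotypeBlock:
    loci: tuple[str, ...]
    estimate: HaplotypeEstimate
    ld: LDPairResult | None = None  # pairwise blocks only


@dataclass
class PopulationReport:
    metadata: dict[str, str]
    loci: list[str]
    n_individuals: int
    locus_summaries: list[LocusSummary] = field(default_factory=list)
    haplotype_blocks: list[HaplotypeBlock] = field(default_factory=list)

    @property
    def name(self) -> str:
        return self.metadata.get("name", "unnamed")


# ---------------------------------------------------------------------------
# number formatting: frequencies to 6 significant digits, statistics at full
# precision (repr round-trips exactly through float())
# ---------------------------------------------------------------------------


def _freq(x: float) -> str:
    return f"{x:.6g}"


def _full(x: float) -> str:
    return repr(float(x))


def _opt(el: etree._Element, attr: str, value: float | int | None, fmt=_full) -> None:
    if value is not None:
        el.set(attr, fmt(value) if isinstance(value, float) else str(value))


# ---------------------------------------------------------------------------
# XML writer
# ---------------------------------------------------------------------------


def write_population_xml(report: PopulationReport, target: str | IO[bytes] | None = None) -> bytes:
    """Serialize a report to XML; returns the bytes and optionally writes them."""
    root = etree.Element("population", name=report.name)
    meta = etree.SubElement(root, "metadata")
    for key, value in report.metadata.items():
        etree.SubElement(meta, "entry", key=key).text = value
    etree.SubElement(root, "sample", **{"n-individuals": str(report.n_individuals)})

    for ls in report.locus_summaries:
        locus_el = etree.SubElement(root, "locus", name=ls.locus)
        etree.SubElement(
            locus_el,
            "summary",
            **{
                "n-gametes": str(ls.allele_table.n_gametes),
                "k": str(ls.allele_table.k),
                "homozygosity": _full(ls.homozygosity),
                "n-untyped": str(ls.n_untyped),
            },
        )
        alleles_el = etree.SubElement(locus_el, "alleles")
        freqs = ls.allele_table.freqs
        for allele, count in ls.allele_table.counts.items():
            etree.SubElement(
                alleles_el, "allele", name=allele, count=str(count), freq=_freq(freqs[allele])
            )
        if ls.genotype_table is not None:
            gt_el = etree.SubElement(locus_el, "genotypes")
            expected = ls.hwe_chisq.expected if ls.hwe_chisq else {}
            for (a, b), count in ls.genotype_table.counts.items():
                g = etree.SubElement(gt_el, "genotype", allele1=a, allele2=b, count=str(count))
                if (a, b) in expected:
                    g.set("expected", _full(expected[(a, b)]))
        if ls.hwe_chisq is not None:
            etree.SubElement(
                locus_el,
                "hardyweinberg-chisq",
                chisq=_full(ls.hwe_chisq.chisq),
                df=str(ls.hwe_chisq.df),
                pvalue=_full(ls.hwe_chisq.pvalue),
            )
        if ls.hwe_exact is not None:
            ex = etree.SubElement(
                locus_el,
                "hardyweinberg-exact",
                method=ls.hwe_exact.method,
                pvalue=_full(ls.hwe_exact.p_overall),
                **{
                    "p-het-excess": _full(ls.hwe_exact.p_het_excess),
                    "p-het-deficit": _full(ls.hwe_exact.p_het_deficit),
                },
            )
            _opt(ex, "n-tables", ls.hwe_exact.n_tables)
            _opt(ex, "n-steps", ls.hwe_exact.n_steps)
            _opt(ex, "seed", ls.hwe_exact.seed)
        if ls.ew is not None:
            ew_el = etree.SubElement(
                locus_el,
                "ewens-watterson",
                method=ls.ew.method,
                **{
                    "f-obs": _full(ls.ew.F_obs),
                    "e-f": _full(ls.ew.E_F),
                    "sd-f": _full(ls.ew.sd_F),
                    "f-nd": _full(ls.ew.F_nd),
                    "pvalue": _full(ls.ew.p_value),
                    "p-upper": _full(ls.ew.p_upper),
                },
            )
            _opt(ew_el, "n-samples", ls.ew.n_samples)
            _opt(ew_el, "seed", ls.ew.seed)

    for block in report.haplotype_blocks:
        bl = etree.SubElement(
            root,
            "haplotype-block",
            loci=":".join(block.loci),
            **{
                "n-individuals": str(block.estimate.n_individuals),
                "n-excluded": str(block.estimate.n_excluded),
                "loglik": _full(block.estimate.loglik),
                "n-iterations": str(block.estimate.n_iterations),
                "converged": "true" if block.estimate.converged else "false",
            },
        )
        counts = block.estimate.counts
        for name, f in block.estimate.freqs.items():
            etree.SubElement(
                bl, "haplotype", name=name, freq=_freq(f), count=_freq(counts[name])
            )
        if block.ld is not None:
            ld = block.ld
            ld_el = etree.SubElement(bl, "ld")
            ld_el.set("dprime", _full(ld.dprime))
            for attr, value in (("wn", ld.wn), ("ald-1-2", ld.ald_1_2), ("ald-2-1", ld.ald_2_1)):
                if value is not None:
                    ld_el.set(attr, _full(value))
            for i, a1 in enumerate(ld.alleles1):
                for j, a2 in enumerate(ld.alleles2):
                    etree.SubElement(
                        ld_el,
                        "pair",
                        allele1=a1,
                        allele2=a2,
                        d=_full(float(ld.d[i, j])),
                        dprime=_full(float(ld.dprime_ij[i, j])),
                    )
            if ld.permutation is not None:
                perm = etree.SubElement(
                    ld_el,
                    "permutation",
                    n=str(ld.permutation.n_permutations),
                    pvalue=_full(ld.permutation.p_value),
                    statistic=ld.permutation.statistic,
                )
                _opt(perm, "seed", ld.permutation.seed)

    blob = etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")
    if isinstance(target, str):
        with open(target, "wb") as fh:
            fh.write(blob)
    elif target is not None:
        target.write(blob)
    return blob


# ---------------------------------------------------------------------------
# XML reader: plain nested dicts, the substrate of the TSV aggregator
# ---------------------------------------------------------------------------


def _float_attr(el: etree._Element, attr: str) -> float | None:
    raw = el.get(attr)
    return None if raw is None else float(raw)


def _int_attr(el: etree._Element, attr: str) -> int | None:
    raw = el.get(attr)
    return None if raw is None else int(raw)


def read_population_xml(source: str | bytes | IO[bytes]) -> dict:
    """Parse a population XML document into nested dictionaries."""
    if isinstance(source, bytes):
        root = etree.fromstring(source)
    elif isinstance(source, str) and source.lstrip().startswith("<"):
        root = etree.fromstring(source.encode())
    else:
        root = etree.parse(source).getroot()
    if root.tag != "population":
        raise ValueError(f"expected <population> root element, got <{root.tag}>")

    doc: dict = {
        "name": root.get("name"),
        "metadata": {e.get("key"): (e.text or "") for e in root.iter("entry")},
        "n_individuals": int(root.find("sample").get("n-individuals")),
        "loci": [],
        "haplotype_blocks": [],
    }
    for locus_el in root.iter("locus"):
        summary = locus_el.find("summary")
        entry: dict = {
            "name": locus_el.get("name"),
            "n_gametes": int(summary.get("n-gametes")),
            "k": int(summary.get("k")),
            "homozygosity": float(summary.get("homozygosity")),
            "n_untyped": int(summary.get("n-untyped")),
            "alleles": [
                {
                    "name": a.get("name"),
                    "count": int(a.get("count")),
                    "freq": float(a.get("freq")),
                }
                for a in locus_el.iter("allele")
            ],
            "genotypes": None,
            "hwe_chisq": None,
            "hwe_exact": None,
            "ew": None,
        }
        gt = locus_el.find("genotypes")
        if gt is not None:
            entry["genotypes"] = [
                {
                    "allele1": g.get("allele1"),
                    "allele2": g.get("allele2"),
                    "count": int(g.get("count")),
                    "expected": _float_attr(g, "expected"),
                }
                for g in gt.iter("genotype")
            ]
        chisq = locus_el.find("hardyweinberg-chisq")
        if chisq is not None:
            entry["hwe_chisq"] = {
                "chisq": float(chisq.get("chisq")),
                "df": int(chisq.get("df")),
                "pvalue": float(chisq.get("pvalue")),
            }
        exact = locus_el.find("hardyweinberg-exact")
        if exact is not None:
            entry["hwe_exact"] = {
                "method": exact.get("method"),
                "pvalue": float(exact.get("pvalue")),
                "p_het_excess": float(exact.get("p-het-excess")),
                "p_het_deficit": float(exact.get("p-het-deficit")),
                "n_tables": _int_attr(exact, "n-tables"),
                "n_steps": _int_attr(exact, "n-steps"),
                "seed": _int_attr(exact, "seed"),
            }
        ew = locus_el.find("ewens-watterson")
        if ew is not None:
            entry["ew"] = {
                "method": ew.get("method"),
                "f_obs": float(ew.get("f-obs")),
                "e_f": float(ew.get("e-f")),
                "sd_f": float(ew.get("sd-f")),
                "f_nd": float(ew.get("f-nd")),
                "pvalue": float(ew.get("pvalue")),
                "p_upper": float(ew.get("p-upper")),
            }
        doc["loci"].append(entry)

    for bl in root.iter("haplotype-block"):
        block: dict = {
            "loci": tuple(bl.get("loci").split(":")),
            "n_individuals": int(bl.get("n-individuals")),
            "n_excluded": int(bl.get("n-excluded")),
            "loglik": float(bl.get("loglik")),
            "n_iterations": int(bl.get("n-iterations")),
            "converged": bl.get("converged") == "true",
            "haplotypes": [
                {
                    "name": h.get("name"),
                    "freq": float(h.get("freq")),
                    "count": float(h.get("count")),
                }
                for h in bl.iter("haplotype")
            ],
            "ld": None,
        }
        ld_el = bl.find("ld")
        if ld_el is not None:
            ld: dict = {
                "dprime": float(ld_el.get("dprime")),
                "wn": _float_attr(ld_el, "wn"),
                "ald_1_2": _float_attr(ld_el, "ald-1-2"),
                "ald_2_1": _float_attr(ld_el, "ald-2-1"),
                "pairs": {
                    (p.get("allele1"), p.get("allele2")): {
                        "d": float(p.get("d")),
                        "dprime": float(p.get("dprime")),
                    }
                    for p in ld_el.iter("pair")
                },
                "permutation": None,
            }
            perm = ld_el.find("permutation")
            if perm is not None:
                ld["permutation"] = {
                    "n": int(perm.get("n")),
                    "pvalue": float(perm.get("pvalue")),
                    "statistic": perm.get("statistic"),
                    "seed": _int_attr(perm, "seed"),
                }
            block["ld"] = ld
        doc["haplotype_blocks"].append(block)
    return doc


# ---------------------------------------------------------------------------
# text report
# ---------------------------------------------------------------------------


def _rule(title: str) -> str:
    return f"{title}\n{'-' * len(title)}\n"


def _table(headers: Sequence[str], rows: Sequence[Sequence[str]]) -> str:
    widths = [
        max(len(h), *(len(r[i]) for r in rows)) if rows else len(h)
        for i, h in enumerate(headers)
    ]
    def fmt(row: Sequence[str]) -> str:
        return "  ".join(cell.ljust(w) for cell, w in zip(row, widths)).rstrip()
    lines = [fmt(headers)]
    lines += [fmt(r) for r in rows]
    return "\n".join(lines) + "\n"


def _na(x: float | None, fmt=_freq) -> str:
    return "NA" if x is None else fmt(x)


def write_text_report(report: PopulationReport) -> str:
    """Fixed-width human-readable report covering exactly the requested analyses."""
    out: list[str] = []
    out.append(_rule(f"Population: {report.name}"))
    for key, value in report.metadata.items():
        out.append(f"{key}: {value}\n")
    out.append(f"individuals: {report.n_individuals}\n\n")

    for ls in report.locus_summaries:
        out.append(_rule(f"Locus {ls.locus}"))
        t = ls.allele_table
        out.append(
            f"gametes: {t.n_gametes}   distinct alleles (k): {t.k}   "
            f"homozygosity (F): {_freq(ls.homozygosity)}   untyped individuals: {ls.n_untyped}\n"
        )
        freqs = t.freqs
        out.append(
            _table(
                ["allele", "count", "frequency"],
                [[a, str(c), _freq(freqs[a])] for a, c in t.counts.items()],
            )
        )
        if ls.hwe_chisq is not None:
            c = ls.hwe_chisq
            out.append(
                f"HWP chi-square: chisq = {_freq(c.chisq)}, df = {c.df}, "
                f"p = {_freq(c.pvalue)}"
                + (f"  [{len(c.lumped)} classes lumped]" if c.lumped else "")
                + "\n"
            )
        if ls.hwe_exact is not None:
            e = ls.hwe_exact
            out.append(
                f"HWP exact ({e.method}): p = {_freq(e.p_overall)}, "
                f"het-excess p = {_freq(e.p_het_excess)}, "
                f"het-deficit p = {_freq(e.p_het_deficit)}\n"
            )
        if ls.ew is not None:
            w = ls.ew
            out.append(
                f"Ewens-Watterson ({w.method}): F = {_freq(w.F_obs)}, "
                f"E[F] = {_freq(w.E_F)}, F_nd = {_freq(w.F_nd)}, "
                f"p(F <= obs) = {_freq(w.p_value)}\n"
            )
        out.append("\n")

    for block in report.haplotype_blocks:
        est = block.estimate
        out.append(_rule(f"Haplotypes {':'.join(block.loci)}"))
        out.append(
            f"individuals used: {est.n_individuals} (excluded: {est.n_excluded})   "
            f"loglik: {_full(est.loglik)}   iterations: {est.n_iterations}   "
            f"converged: {'yes' if est.converged else 'no'}\n"
        )
        counts = est.counts
        out.append(
            _table(
                ["haplotype", "frequency", "count"],
                [[name, _freq(f), _freq(counts[name])] for name, f in est.freqs.items()],
            )
        )
        if block.ld is not None:
            ld = block.ld
            headers = ["locus pair", "D'", "Wn", "ALD_1_2", "ALD_2_1"]
            row = [
                f"{ld.locus1}:{ld.locus2}",
                _freq(ld.dprime),
                _na(ld.wn),
                _na(ld.ald_1_2),
                _na(ld.ald_2_1),
            ]
            if ld.permutation is not None:
                headers += ["# permu", "p-value"]
                row += [str(ld.permutation.n_permutations), _freq(ld.permutation.p_value)]
            out.append(_table(headers, [row]))
        out.append("\n")
    return "".join(out)


# ---------------------------------------------------------------------------
# TSV aggregation
# ---------------------------------------------------------------------------

TSV_SCHEMAS: dict[str, list[str]] = {
    "1-locus-summary": [
        "pop", "locus", "n.gametes", "k", "f.obs",
        "hwp.chisq.pvalue", "hwp.exact.pvalue", "ew.pvalue", "ew.f.nd",
    ],
    "1-locus-allele": ["pop", "locus", "allele", "allele.freq", "allele.count"],
    "1-locus-genotype": ["pop", "locus", "genotype", "obs.count", "exp.count"],
    "1-locus-hardyweinberg": [
        "pop", "locus", "k", "pval.chisq", "pval.exact", "method.exact",
        "pval.het.excess", "pval.het.deficit",
    ],
    "2-locus-summary": [
        "pop", "loci", "n.individuals", "ld.dprime", "ld.wn", "ald.1.2", "ald.2.1",
    ],
    "2-locus-haplo": [
        "pop", "loci", "haplotype", "haplo.freq", "haplo.count", "ld.d", "ld.dprime",
    ],
    "n-locus-summary": ["pop", "loci", "n.individuals", "n.haplotypes", "loglik"],
    "n-locus-haplo": ["pop", "loci", "haplotype", "haplo.freq", "haplo.count"],
}


def _tsv_value(x) -> str:
    if x is None:
        return "NA"
    if isinstance(x, float):
        return _freq(x)
    return str(x)


def aggregate_tsv(
    sources: Sequence[str | bytes | dict],
    outputdir: str = ".",
    prefix: str = "",
    enable_ihwg: bool = False,
) -> list[str]:
    """Aggregate per-population XML documents into the TSV file family.

    ``sources`` may be XML file paths, XML bytes, or dicts already produced
    by :func:`read_population_xml`.  Returns the paths written.  Only files
    with at least one data row are created.
    """
    if not sources:
        raise ValueError("no XML documents to aggregate")
    docs = []
    for src in sources:
        if isinstance(src, dict):
            docs.append(src)
            continue
        try:
            docs.append(read_population_xml(src))
        except (etree.XMLSyntaxError, OSError, ValueError) as exc:
            raise ValueError(f"malformed population XML {src!r}: {exc}") from exc

    def meta_cols(doc: dict) -> list[str]:
        md = doc["metadata"]
        return [md.get(c.replace(".", "_"), md.get(c, "NA")) or "NA" for c in IHWG_COLUMNS]

    tables: dict[str, list[list[str]]] = {}
    headers: dict[str, list[str]] = {}

    def add(fname: str, schema_key: str, doc: dict, values: list) -> None:
        cols = list(TSV_SCHEMAS[schema_key])
        row = [_tsv_value(v) for v in values]
        if enable_ihwg:
            cols = cols[:1] + [f"pop.{c}" for c in IHWG_COLUMNS] + cols[1:]
            row = row[:1] + meta_cols(doc) + row[1:]
        headers[fname] = cols
        tables.setdefault(fname, []).append(row)

    any_permutation = any(
        b["ld"] and b["ld"]["permutation"]
        for d in docs
        for b in d["haplotype_blocks"]
    )

    for doc in docs:
        pop = doc["name"]
        for locus in doc["loci"]:
            chisq, exact, ew = locus["hwe_chisq"], locus["hwe_exact"], locus["ew"]
            add(
                "1-locus-summary", "1-locus-summary", doc,
                [
                    pop, locus["name"], locus["n_gametes"], locus["k"],
                    locus["homozygosity"],
                    chisq["pvalue"] if chisq else None,
                    exact["pvalue"] if exact else None,
                    ew["pvalue"] if ew else None,
                    ew["f_nd"] if ew else None,
                ],
            )
            for allele in locus["alleles"]:
                add(
                    "1-locus-allele", "1-locus-allele", doc,
                    [pop, locus["name"], allele["name"], allele["freq"], allele["count"]],
                )
            if locus["genotypes"] is not None:
                for g in locus["genotypes"]:
                    add(
                        "1-locus-genotype", "1-locus-genotype", doc,
                        [
                            pop, locus["name"], f"{g['allele1']}/{g['allele2']}",
                            g["count"], g["expected"],
                        ],
                    )
            if chisq or exact:
                add(
                    "1-locus-hardyweinberg", "1-locus-hardyweinberg", doc,
                    [
                        pop, locus["name"], locus["k"],
                        chisq["pvalue"] if chisq else None,
                        exact["pvalue"] if exact else None,
                        exact["method"] if exact else None,
                        exact["p_het_excess"] if exact else None,
                        exact["p_het_deficit"] if exact else None,
                    ],
                )

        for block in doc["haplotype_blocks"]:
            n_loci = len(block["loci"])
            loci_name = ":".join(block["loci"])
            ld = block["ld"]
            if n_loci == 2:
                values = [
                    pop, loci_name, block["n_individuals"],
                    ld["dprime"] if ld else None,
                    ld["wn"] if ld else None,
                    ld["ald_1_2"] if ld else None,
                    ld["ald_2_1"] if ld else None,
                ]
                cols_key = "2-locus-summary"
                fname = "2-locus-summary"
                cols = list(TSV_SCHEMAS[cols_key])
                if any_permutation:
                    cols += ["permu.n", "permu.pvalue"]
                    perm = ld["permutation"] if ld else None
                    values += [perm["n"] if perm else None, perm["pvalue"] if perm else None]
                row = [_tsv_value(v) for v in values]
                if enable_ihwg:
                    cols = cols[:1] + [f"pop.{c}" for c in IHWG_COLUMNS] + cols[1:]
                    row = row[:1] + meta_cols(doc) + row[1:]
                headers[fname] = cols
                tables.setdefault(fname, []).append(row)
                for hap in block["haplotypes"]:
                    pair_ld = None
                    if ld:
                        key = tuple(hap["name"].split("~"))
                        pair_ld = ld["pairs"].get(key)
                    add(
                        "2-locus-haplo", "2-locus-haplo", doc,
                        [
                            pop, loci_name, hap["name"], hap["freq"], hap["count"],
                            pair_ld["d"] if pair_ld else None,
                            pair_ld["dprime"] if pair_ld else None,
                        ],
                    )
            else:
                add(
                    f"{n_loci}-locus-summary", "n-locus-summary", doc,
                    [
                        pop, loci_name, block["n_individuals"],
                        len(block["haplotypes"]), block["loglik"],
                    ],
                )
                for hap in block["haplotypes"]:
                    add(
                        f"{n_loci}-locus-haplo", "n-locus-haplo", doc,
                        [pop, loci_name, hap["name"], hap["freq"], hap["count"]],
                    )

    os.makedirs(outputdir, exist_ok=True)
    written: list[str] = []
    for fname in sorted(tables):
        if not tables[fname]:
            continue
        path = os.path.join(outputdir, f"{prefix}{fname}.tsv")
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("\t".join(headers[fname]) + "\n")
            for row in tables[fname]:
                fh.write("\t".join(row) + "\n")
        written.append(path)
    return written
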