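import io
import os

import pytest

from popkit.config import parse_config
from popkit.pipeline import run_analysis
from popkit.reporting import (
    aggregate_tsv,
    read_population_xml,
    write_population_xml,
    write_text_report,
)
from popkit.simulate import SimulationSpec, sample_population


def _population(name="popA", seed=1, loci=("A", "B"), n=40):
    spec = SimulationSpec(
        loci=loci,
        n_individuals=n,
        allele_freqs=[
            {"01:01": 0.5, "02:01": 0.3, "03:01": 0.2},
            {"01:01": 0.6, "02:01": 0.4},
        ][: len(loci)]
        + [{"01:01": 0.5, "02:01": 0.5}] * max(0, len(loci) - 2),
        seed=seed,
        population_name=name,
    )
    return sample_population(spec)[0]


FULL_CONFIG = """\
[HardyWeinberg]
chisq = yes
exact = yes
n-samples = 500

[EwensWatterson]
n-samples = 500

[Haplotypes]
loci = all-pairs

[Linkage]
pairs = all-pairs
"""


@pytest.fixture
def full_report():
    config = parse_config(FULL_CONFIG)
    return run_analysis(_population(), config, seed=5)


class TestXML:
    def test_requested_analyses_appear_exactly_once(self):
        config = parse_config("[HardyWeinberg]\nchisq = yes\nexact = yes\n")
        report = run_analysis(_population(), config, seed=5)
        doc = read_population_xml(write_population_xml(report))
        for locus in doc["loci"]:
            assert locus["hwe_chisq"] is not None
            assert locus["ew"] is None
        assert doc["haplotype_blocks"] == []

    def test_round_trip_numeric_fields(self, full_report):
        doc = read_population_xml(write_population_xml(full_report))
        ls = full_report.locus_summaries[0]
        entry = doc["loci"][0]
        # full-precision statistics survive exactly
        assert entry["homozygosity"] == ls.homozygosity
        assert entry["hwe_chisq"]["pvalue"] == ls.hwe_chisq.pvalue
        assert entry["hwe_exact"]["pvalue"] == ls.hwe_exact.p_overall
        assert entry["ew"]["f_nd"] == ls.ew.F_nd
        # frequencies survive to their serialized (6 significant digit) precision
        for allele, freq in zip(entry["alleles"], ls.allele_table.freqs.values()):
            assert allele["freq"] == pytest.approx(freq, rel=1e-5)
        block, bdoc = full_report.haplotype_blocks[0], doc["haplotype_blocks"][0]
        assert bdoc["loglik"] == block.estimate.loglik
        assert bdoc["ld"]["dprime"] == block.ld.dprime
        assert bdoc["ld"]["ald_1_2"] == block.ld.ald_1_2

    def test_two_populations_distinct_names(self):
        config = parse_config("[HardyWeinberg]\n")
        docs = [
            read_population_xml(
                write_population_xml(run_analysis(_population(name), config, seed=1))
            )
            for name in ("popA", "popB")
        ]
        assert {d["name"] for d in docs} == {"popA", "popB"}


class TestTextReport:
    def test_no_permutation_columns_without_permutation_test(self, full_report):
        text = write_text_report(full_report)
        assert "# permu" not in text
        assert "p-value" not in text
        assert "ALD_1_2" in text and "ALD_2_1" in text

    def test_permutation_columns_present_when_run(self):
        config = parse_config(FULL_CONFIG + "permutations = 20\n")
        report = run_analysis(_population(), config, seed=5)
        text = write_text_report(report)
        assert "# permu" in text and "p-value" in text

    def test_haplotype_names_use_gl_string_separator(self, full_report):
        assert "01:01~01:01" in write_text_report(full_report)

    def test_metadata_only_report(self):
        config = parse_config("")
        report = run_analysis(_population(), config, seed=5)
        report.locus_summaries.clear()
        text = write_text_report(report)
        assert "popA" in text
        assert "Locus" not in text


class TestAggregateTSV:
    def _xml_docs(self, config_text, names=("popA", "popB"), loci=("A", "B")):
        config = parse_config(config_text)
        return [
            write_population_xml(
                run_analysis(_population(name, seed=i + 1, loci=loci), config, seed=3)
            )
            for i, name in enumerate(names)
        ]

    def test_only_requested_files_appear(self, tmp_path):
        docs = self._xml_docs("[Haplotypes]\nloci = A:B\n")
        written = aggregate_tsv(docs, outputdir=str(tmp_path))
        names = {os.path.basename(p) for p in written}
        assert "2-locus-haplo.tsv" in names
        assert "3-locus-haplo.tsv" not in names
        assert "1-locus-hardyweinberg.tsv" not in names

    def test_five_locus_estimation_yields_five_locus_file(self, tmp_path):
        docs = self._xml_docs(
            "[Haplotypes]\nloci = A:B:C:D:E\n", loci=("A", "B", "C", "D", "E")
        )
        written = aggregate_tsv(docs, outputdir=str(tmp_path))
        names = {os.path.basename(p) for p in written}
        assert "5-locus-haplo.tsv" in names and "5-locus-summary.tsv" in names

    def test_two_populations_two_rows_per_locus(self, tmp_path):
        docs = self._xml_docs("[HardyWeinberg]\n")
        aggregate_tsv(docs, outputdir=str(tmp_path))
        lines = (tmp_path / "1-locus-summary.tsv").read_text().splitlines()
        assert len(lines) == 1 + 2 * 2  # header + 2 pops x 2 loci
        assert lines[0].split("\t")[:2] == ["pop", "locus"]

    def test_no_empty_files_and_na_for_undefined(self, tmp_path):
        docs = self._xml_docs(FULL_CONFIG)
        written = aggregate_tsv(docs, outputdir=str(tmp_path))
        for path in written:
            body = open(path).read().splitlines()
            assert len(body) >= 2  # header plus data
        summary = (tmp_path / "2-locus-summary.tsv").read_text()
        assert "permu" not in summary.splitlines()[0]

    def test_permutation_columns_only_when_run(self, tmp_path):
        docs = self._xml_docs(FULL_CONFIG + "permutations = 10\n")
        aggregate_tsv(docs, outputdir=str(tmp_path))
        header = (tmp_path / "2-locus-summary.tsv").read_text().splitlines()[0]
        assert header.endswith("permu.n\tpermu.pvalue")

    def test_prefix_and_ihwg_columns(self, tmp_path):
        docs = self._xml_docs("[HardyWeinberg]\n")
        written = aggregate_tsv(
            docs, outputdir=str(tmp_path), prefix="run1_", enable_ihwg=True
        )
        names = {os.path.basename(p) for p in written}
        assert any(n.startswith("run1_") for n in names)
        header = (tmp_path / "run1_1-locus-summary.tsv").read_text().splitlines()[0]
        assert "pop.region" in header and "pop.ethnicity" in header

    def test_errors(self, tmp_path):
        with pytest.raises(ValueError, match="no XML"):
            aggregate_tsv([], outputdir=str(tmp_path))
        bad = tmp_path / "bad.xml"
        bad.write_text("<not-a-population/>")
        with pytest.raises(ValueError, match="bad.xml"):
            aggregate_tsv([str(bad)], outputdir=str(tmp_path))
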