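"""Reading and writing of population genotype (``.pop``) files.

A ``.pop`` file is plain text (UTF-8, LF or CRLF) with three parts:

1. optional metadata lines of the form ``key: value`` (no tab characters),
   e.g. the population name or sampling labels;
2. a tab-separated header row with two columns per locus, named
   ``<locus>_1`` and ``<locus>_2``;
3. one tab-separated row per individual with one allele name per column.

Allele names are arbitrary non-whitespace tokens; in particular the modern
colon-delimited HLA nomenclature (``A*02:01:01:134Q``, ``DPB1*1372:01:01:02``)
passes through untouched.  An untyped (missing) allele is written as a marker
token, ``****`` by default.

Multi-locus haplotypes are rendered in GL String style, with ``~`` joining
the allele at each locus: a haplotype of ``A*01:01`` and ``B*08:01`` is
``A*01:01~B*08:01``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

DEFAULT_UNTYPED_MARKER = "****"

__all__ = [
    "AlleleName",
    "LocusGenotype",
    "PopulationDataset",
    "PopFileError",
    "parse_pop_file",
    "write_pop_file",
    "format_haplotype_name",
    "DEFAULT_UNTYPED_MARKER",
]


class PopFileError(ValueError):
    """Raised when a ``.pop`` stream violates the dialect."""


@dataclass(frozen=True, order=True)
class AlleleName:
    """An allele label at one locus, or the explicit absence of one.

    ``untyped`` alleles never participate in allele or genotype counts; a
    genotype containing one is "incomplete" at its locus.
    """

    raw: str
    untyped: bool = False

    def __post_init__(self) -> None:
        if not self.untyped and not self.raw:
            raise ValueError("typed allele name must be non-empty")

    def __str__(self) -> str:  # pragma: no cover - display helper
        return "<untyped>" if self.untyped else self.raw


UNTYPED = AlleleName("", untyped=True)


@dataclass(frozen=True)
class LocusGenotype:
    """An unordered pair of alleles carried by one individual at one locus."""

    allele1: AlleleName
    allele2: AlleleName

    @property
    def complete(self) -> bool:
        return not (self.allele1.untyped or self.allele2.untyped)

    def unordered(self) -> tuple[AlleleName, AlleleName]:
        """The pair in canonical (sorted) order."""
        a, b = self.allele1, self.allele2
        return (a, b) if (a.untyped, a.raw) <= (b.untyped, b.raw) else (b, a)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LocusGenotype):
            return NotImplemented
        return self.unordered() == other.unordered()

    def __hash__(self) -> int:
        return hash(self.unordered())


@dataclass
class PopulationDataset:
    """A population sample: individuals x loci matrix of unordered allele pairs.

    ``individuals[i][l]`` is the :class:`LocusGenotype` of individual ``i`` at
    ``loci[l]``.  Every row has exactly one genotype per locus.
    """

    metadata: dict[str, str]
    loci: list[str]
    individuals: list[tuple[LocusGenotype, ...]]
    untyped_marker: str = DEFAULT_UNTYPED_MARKER

    def __post_init__(self) -> None:
        if len(set(self.loci)) != len(self.loci):
            raise PopFileError("duplicate locus name in dataset")
        for i, row in enumerate(self.individuals):
            if len(row) != len(self.loci):
                raise PopFileError(
                    f"individual {i} has {len(row)} genotypes for {len(self.loci)} loci"
                )

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def name(self) -> str:
        return self.metadata.get("name", "unnamed")

    def locus_index(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise KeyError(f"locus {locus!r} not in dataset") from None

    def genotypes_at(self, locus: str) -> list[LocusGenotype]:
        li = self.locus_index(locus)
        return [row[li] for row in self.individuals]

    def replace_alleles(self, mapping: dict[str, dict[str, str]]) -> "PopulationDataset":
        """Return a copy with alleles renamed per ``mapping[locus][old] = new``.

        Untyped alleles and names absent from the mapping are untouched.
        """

        def remap(locus: str, a: AlleleName) -> AlleleName:
            if a.untyped:
                return a
            new = mapping.get(locus, {}).get(a.raw)
            return a if new is None else AlleleName(new)

        rows = [
            tuple(
                LocusGenotype(remap(locus, g.allele1), remap(locus, g.allele2))
                for locus, g in zip(self.loci, row)
            )
            for row in self.individuals
        ]
        return PopulationDataset(
            metadata=dict(self.metadata),
            loci=list(self.loci),
            individuals=rows,
            untyped_marker=self.untyped_marker,
        )


def _as_text_stream(source: str | IO[str]) -> IO[str]:
    if isinstance(source, str):
        return io.StringIO(source)
    return source


def parse_pop_file(
    source: str | IO[str], untyped_marker: str = DEFAULT_UNTYPED_MARKER
) -> PopulationDataset:
    """Parse a ``.pop`` stream (or literal string) into a :class:`PopulationDataset`.

    Raises :class:`PopFileError` on dialect violations, naming the offending
    line where possible.
    """
    stream = _as_text_stream(source)
    metadata: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[tuple[LocusGenotype, ...]] = []
    loci: list[str] = []

    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\r\n")
        if not line.strip():
            continue
        if header is None:
            if "\t" not in line:
                if ":" not in line:
                    raise PopFileError(
                        f"line {lineno}: expected 'key: value' metadata or tab-separated header"
                    )
                key, _, value = line.partition(":")
                metadata[key.strip()] = value.strip()
                continue
            header = line.split("\t")
            loci = _parse_header(header, lineno)
            continue
        fields = line.split("\t")
        if len(fields) != len(header):
            raise PopFileError(
                f"line {lineno}: expected {len(header)} allele fields "
                f"({len(loci)} loci x 2), found {len(fields)}"
            )
        genos = []
        for li in range(len(loci)):
            a1 = _parse_allele(fields[2 * li], untyped_marker)
            a2 = _parse_allele(fields[2 * li + 1], untyped_marker)
            genos.append(LocusGenotype(a1, a2))
        rows.append(tuple(genos))

    if header is None:
        raise PopFileError("no header row found (empty body)")
    if not rows:
        raise PopFileError("no individual rows found (empty body)")
    return PopulationDataset(
        metadata=metadata, loci=loci, individuals=rows, untyped_marker=untyped_marker
    )


def _parse_header(columns: Sequence[str], lineno: int) -> list[str]:
    if len(columns) % 2 != 0:
        raise PopFileError(
            f"line {lineno}: odd number of allele columns ({len(columns)}); "
            "each locus needs exactly two"
        )
    loci: list[str] = []
    for i in range(0, len(columns), 2):
        c1, c2 = columns[i].strip(), columns[i + 1].strip()
        if not (c1.endswith("_1") and c2.endswith("_2") and c1[:-2] == c2[:-2] and c1[:-2]):
            raise PopFileError(
                f"line {lineno}: header columns {i + 1},{i + 2} "
                f"({c1!r}, {c2!r}) must be '<locus>_1', '<locus>_2'"
            )
        locus = c1[:-2]
        if locus in loci:
            raise PopFileError(f"line {lineno}: duplicate locus name {locus!r}")
        loci.append(locus)
    return loci


def _parse_allele(token: str, untyped_marker: str) -> AlleleName:
    token = token.strip()
    if token == untyped_marker or token == "":
        return UNTYPED
    return AlleleName(token)


def write_pop_file(dataset: PopulationDataset, target: IO[str] | str) -> None:
    """Write ``dataset`` in the ``.pop`` dialect; inverse of :func:`parse_pop_file`.

    ``target`` may be a path or an open text stream.  Refuses to write a
    dataset with no individuals (such a file could not be parsed back).
    """
    if dataset.n_individuals == 0:
        raise PopFileError("refusing to write a dataset with 0 individuals")
    if isinstance(target, str):
        with open(target, "w", encoding="utf-8", newline="\n") as fh:
            _write_pop(dataset, fh)
    else:
        _write_pop(dataset, target)


def _write_pop(dataset: PopulationDataset, fh: IO[str]) -> None:
    for key, value in dataset.metadata.items():
        fh.write(f"{key}: {value}\n")
    header = []
    for locus in dataset.loci:
        header += [f"{locus}_1", f"{locus}_2"]
    fh.write("\t".join(header) + "\n")
    marker = dataset.untyped_marker
    for row in dataset.individuals:
        fields = []
        for g in row:
            for a in (g.allele1, g.allele2):
                fields.append(marker if a.untyped else a.raw)
        fh.write("\t".join(fields) + "\n")


def format_haplotype_name(alleles: Iterable[AlleleName | str]) -> str:
    """Join allele names with the GL String ``~`` separator, in locus order.

    Colons inside allele names are preserved verbatim; an untyped member is an
    error since a haplotype must be fully specified.
    """
    parts = []
    for a in alleles:
        if isinstance(a, AlleleName):
            if a.untyped:
                raise ValueError("cannot format a haplotype containing an untyped allele")
            parts.append(a.raw)
        else:
            if not a:
                raise ValueError("cannot format a haplotype with an empty allele name")
            parts.append(a)
    return "~".join(parts)
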