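"""Per-locus allele and genotype counting — the substrate of every test.

Individuals incomplete at a locus (one or both alleles untyped) are excluded
at that locus only; single-locus statistics use all remaining data.  Listwise
deletion across loci happens only in haplotype estimation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .dataio import AlleleName, PopulationDataset

__all__ = [
    "AlleleFrequencyTable",
    "GenotypeCountTable",
    "NoTypedDataError",
    "count_alleles",
    "genotype_counts",
    "observed_homozygosity",
]


class NoTypedDataError(ValueError):
    """No individual is typed at the requested locus."""


@dataclass
class AlleleFrequencyTable:
    locus: str
    counts: dict[str, int]  # allele name -> gamete count, sorted by name
    n_gametes: int  # 2 x individuals complete at this locus

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_gametes:
            raise ValueError("allele counts do not sum to the number of gametes")

    @property
    def k(self) -> int:
        return len(self.counts)

    @property
    def freqs(self) -> dict[str, float]:
        return {a: c / self.n_gametes for a, c in self.counts.items()}

    @property
    def n_individuals(self) -> int:
        return self.n_gametes // 2


@dataclass
class GenotypeCountTable:
    locus: str
    counts: dict[tuple[str, str], int]  # sorted allele pair -> count
    n_individuals: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_individuals:
            raise ValueError("genotype counts do not sum to the number of individuals")

    @property
    def allele_counts(self) -> dict[str, int]:
        """Marginal gamete counts; consistent with :func:`count_alleles`."""
        out: Counter[str] = Counter()
        for (a, b), c in self.counts.items():
            out[a] += c
            out[b] += c
        return dict(sorted(out.items()))

    @property
    def k(self) -> int:
        return len(self.allele_counts)

    @property
    def n_heterozygotes(self) -> int:
        return sum(c for (a, b), c in self.counts.items() if a != b)


def _complete_pairs(dataset: PopulationDataset, locus: str) -> list[tuple[AlleleName, AlleleName]]:
    pairs = [g.unordered() for g in dataset.genotypes_at(locus) if g.complete]
    if not pairs:
        raise NoTypedDataError(f"no typed data at locus {locus!r}")
    return pairs


def count_alleles(dataset: PopulationDataset, locus: str) -> AlleleFrequencyTable:
    """Gamete-level allele counts at one locus, excluding incomplete individuals."""
    pairs = _complete_pairs(dataset, locus)
    counts: Counter[str] = Counter()
    for a, b in pairs:
        counts[a.raw] += 1
        counts[b.raw] += 1
    return AlleleFrequencyTable(
        locus=locus, counts=dict(sorted(counts.items())), n_gametes=2 * len(pairs)
    )


def genotype_counts(dataset: PopulationDataset, locus: str) -> GenotypeCountTable:
    """Unordered genotype counts at one locus, excluding incomplete individuals."""
    pairs = _complete_pairs(dataset, locus)
    counts: Counter[tuple[str, str]] = Counter()
    for a, b in pairs:
        counts[(a.raw, b.raw)] += 1
    return GenotypeCountTable(
        locus=locus, counts=dict(sorted(counts.items())), n_individuals=len(pairs)
    )


def observed_homozygosity(table: AlleleFrequencyTable) -> float:
    """Watterson's observed homozygosity F = sum of squared allele frequencies.

    Bounded by 1/k (all alleles equifrequent) and 1 (monomorphic).
    """
    return sum(p * p for p in table.freqs.values())
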