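"""Synthetic population generator with known ground truth.

Datasets are drawn at the haplotype level: 2n gametes are sampled from a
specified multi-locus haplotype frequency vector and paired at random, so by
construction the population is in Hardy-Weinberg proportions at the haplotype
(and hence every single-locus) level.  Two departures can be injected:

* an inbreeding-like coefficient ``f``: with probability f an individual is
  formed by duplicating a single drawn haplotype, inflating homozygosity so
  that a biallelic locus has expected heterozygosity 2pq(1 - f);
* a missing-data rate: each locus genotype is independently replaced by the
  untyped marker with the stated probability.

Allele and haplotype frequencies, f and the missing rate are all recorded in
the returned ground truth, so every analysis module can be tested against
known values without external data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .dataio import (
    DEFAULT_UNTYPED_MARKER,
    UNTYPED,
    AlleleName,
    LocusGenotype,
    PopulationDataset,
    write_pop_file,
)

__all__ = ["SimulationSpec", "GroundTruth", "sample_population", "write_pop_file"]


def default_allele_names(k: int) -> list[str]:
    """HLA-flavoured colon-delimited names: 01:01, 02:01, ..."""
    return [f"{i + 1:02d}:01" for i in range(k)]


@dataclass
class SimulationSpec:
    """Parameters of one synthetic population.

    Either ``haplotype_freqs`` (multi-locus haplotype name-tuple -> frequency)
    or ``allele_freqs`` (per-locus allele -> frequency maps, loci combined
    independently) must be given.
    """

    loci: tuple[str, ...]
    n_individuals: int
    haplotype_freqs: dict[tuple[str, ...], float] | None = None
    allele_freqs: list[dict[str, float]] | None = None
    inbreeding_f: float = 0.0
    missing_rate: float = 0.0
    seed: int | None = None
    population_name: str = "synthetic"
    untyped_marker: str = DEFAULT_UNTYPED_MARKER

    def __post_init__(self) -> None:
        if not self.loci:
            raise ValueError("at least one locus required")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if not (0.0 <= self.inbreeding_f < 1.0):
            raise ValueError("inbreeding_f must be in [0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if (self.haplotype_freqs is None) == (self.allele_freqs is None):
            raise ValueError("give exactly one of haplotype_freqs or allele_freqs")
        if self.allele_freqs is not None and len(self.allele_freqs) != len(self.loci):
            raise ValueError("allele_freqs needs one frequency map per locus")

    def resolved_haplotypes(self) -> tuple[list[tuple[str, ...]], np.ndarray]:
        """The haplotype list and frequency vector actually sampled from."""
        if self.haplotype_freqs is not None:
            if not self.haplotype_freqs:
                raise ValueError("haplotype_freqs is empty")
            haps = list(self.haplotype_freqs)
            probs = np.array([self.haplotype_freqs[h] for h in haps], dtype=float)
        else:
            for i, fmap in enumerate(self.allele_freqs):
                if not fmap:
                    raise ValueError(f"locus {self.loci[i]!r} has zero alleles")
            haps = [tuple(c) for c in itertools.product(*[list(m) for m in self.allele_freqs])]
            probs = np.array(
                [
                    np.prod([m[a] for m, a in zip(self.allele_freqs, h)])
                    for h in haps
                ],
                dtype=float,
            )
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies must be non-negative and sum to 1")
        return haps, probs


@dataclass
class GroundTruth:
    haplotypes: list[tuple[str, ...]]
    haplotype_freqs: np.ndarray
    allele_freqs: list[dict[str, float]]  # marginals, one map per locus
    inbreeding_f: float
    missing_rate: float
    seed: int | None


def sample_population(
    spec: SimulationSpec, rng: np.random.Generator | None = None
) -> tuple[PopulationDataset, GroundTruth]:
    """Draw one population according to ``spec``; returns dataset + truth."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    haps, probs = spec.resolved_haplotypes()
    n = spec.n_individuals
    L = len(spec.loci)

    first = rng.choice(len(haps), size=n, p=probs)
    second = rng.choice(len(haps), size=n, p=probs)
    if spec.inbreeding_f > 0:
        dup = rng.random(n) < spec.inbreeding_f
        second = np.where(dup, first, second)
    missing = (
        rng.random((n, L)) < spec.missing_rate
        if spec.missing_rate > 0
        else np.zeros((n, L), dtype=bool)
    )

    rows = []
    for i in range(n):
        h1, h2 = haps[first[i]], haps[second[i]]
        genos = []
        for l in range(L):
            if missing[i, l]:
                genos.append(LocusGenotype(UNTYPED, UNTYPED))
            else:
                genos.append(LocusGenotype(AlleleName(h1[l]), AlleleName(h2[l])))
        rows.append(tuple(genos))

    dataset = PopulationDataset(
        metadata={"name": spec.population_name},
        loci=list(spec.loci),
        individuals=rows,
        untyped_marker=spec.untyped_marker,
    )
    marginals: list[dict[str, float]] = []
    for l in range(L):
        m: dict[str, float] = {}
        for h, pr in zip(haps, probs):
            m[h[l]] = m.get(h[l], 0.0) + float(pr)
        marginals.append(dict(sorted(m.items())))
    truth = GroundTruth(
        haplotypes=haps,
        haplotype_freqs=probs,
        allele_freqs=marginals,
        inbreeding_f=spec.inbreeding_f,
        missing_rate=spec.missing_rate,
        seed=spec.seed,
    )
    return dataset, truth
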