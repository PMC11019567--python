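"""Tests of conformity to Hardy-Weinberg proportions (HWP).

Three routes are provided:

* a chi-square goodness-of-fit test with classical lumping of rare genotype
  classes (expected < 5 pooled into one class);
* a conditional exact test by full enumeration of all genotype tables sharing
  the observed allele counts, feasible for small samples;
* a Monte-Carlo version of the exact test that samples tables from the same
  conditional distribution by randomly pairing the 2n gamete labels.

The conditional probability of a genotype table given its allele counts is

    P(table) = n! * prod_i c_i! * 2^H / ((2n)! * prod_{i<=j} n_ij!)

with c_i the allele (gamete) counts, n_ij the genotype counts and H the
number of heterozygous individuals.  The exact p-value sums P over tables no
more probable than the observed one; heterozygote-tail p-values sum P over
tables with at least (excess) or at most (deficit) the observed number of
heterozygotes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .summaries import GenotypeCountTable

__all__ = [
    "HWEChiSquareResult",
    "HWEExactResult",
    "EnumerationTooLarge",
    "hwe_chisq",
    "genotype_table_probability",
    "enumerate_tables",
    "hwe_exact_enumeration",
    "hwe_exact_montecarlo",
    "hwe_exact",
]

# absolute tolerance on log-probabilities when deciding P(table) <= P(obs)
_LOG_TIE_TOL = 1e-12


class EnumerationTooLarge(ValueError):
    """Full enumeration would exceed the table cap; use Monte Carlo."""


@dataclass
class HWEChiSquareResult:
    locus: str
    chisq: float
    df: int
    pvalue: float
    observed: dict[tuple[str, str], float]
    expected: dict[tuple[str, str], float]
    chi_contributions: dict[tuple[str, str], float]
    lumped: list[tuple[str, str]]  # genotype classes pooled into one
    lumped_observed: float = 0.0
    lumped_expected: float = 0.0


@dataclass
class HWEExactResult:
    locus: str
    p_overall: float
    method: str  # "enumeration" | "montecarlo"
    p_het_excess: float
    p_het_deficit: float
    n_tables: int | None = None  # enumeration only
    n_steps: int | None = None  # montecarlo only
    seed: int | None = None


def hwe_chisq(table: GenotypeCountTable, lump_threshold: float = 5.0) -> HWEChiSquareResult:
    """Chi-square goodness-of-fit test against HWP.

    Expected counts are ``n p_i^2`` (homozygotes) and ``2 n p_i p_j``
    (heterozygotes) with allele frequencies from the observed gamete counts.
    Classes with expected count below ``lump_threshold`` are pooled into a
    single lumped class.  Degrees of freedom are (number of classes after
    lumping) - k, floored at 1, since k - 1 allele frequencies are estimated
    and one degree goes to the total.
    """
    allele_counts = table.allele_counts
    k = len(allele_counts)
    if k < 2:
        raise ValueError(f"monomorphic locus {table.locus!r}: chi-square test undefined")
    n = table.n_individuals
    freqs = {a: c / (2 * n) for a, c in allele_counts.items()}
    alleles = list(allele_counts)

    expected: dict[tuple[str, str], float] = {}
    for i, a in enumerate(alleles):
        for b in alleles[i:]:
            expected[(a, b)] = (
                n * freqs[a] ** 2 if a == b else 2 * n * freqs[a] * freqs[b]
            )
    observed = {g: float(table.counts.get(g, 0)) for g in expected}

    kept = {g for g, e in expected.items() if e >= lump_threshold}
    lumped = sorted(set(expected) - kept)
    lump_obs = sum(observed[g] for g in lumped)
    lump_exp = sum(expected[g] for g in lumped)

    chi_contrib: dict[tuple[str, str], float] = {}
    chisq = 0.0
    n_classes = len(kept)
    for g in sorted(kept):
        c = (observed[g] - expected[g]) ** 2 / expected[g]
        chi_contrib[g] = c
        chisq += c
    if lumped and lump_exp > 0:
        chisq += (lump_obs - lump_exp) ** 2 / lump_exp
        n_classes += 1

    df = max(n_classes - k, 1)
    pvalue = float(stats.chi2.sf(chisq, df))
    return HWEChiSquareResult(
        locus=table.locus,
        chisq=chisq,
        df=df,
        pvalue=pvalue,
        observed=observed,
        expected=expected,
        chi_contributions=chi_contrib,
        lumped=lumped,
        lumped_observed=lump_obs,
        lumped_expected=lump_exp,
    )


def _log_table_probability(genotype_counts: dict[tuple[int, int], int], allele_counts: list[int]) -> float:
    n = sum(genotype_counts.values())
    h = sum(c for (i, j), c in genotype_counts.items() if i != j)
    logp = (
        gammaln(n + 1)
        + sum(gammaln(c + 1) for c in allele_counts)
        + h * math.log(2.0)
        - gammaln(2 * n + 1)
        - sum(gammaln(c + 1) for c in genotype_counts.values())
    )
    return float(logp)


def _coded_counts(table: GenotypeCountTable) -> tuple[dict[tuple[int, int], int], list[int], list[str]]:
    alleles = sorted(table.allele_counts)
    index = {a: i for i, a in enumerate(alleles)}
    coded = {
        tuple(sorted((index[a], index[b]))): c for (a, b), c in table.counts.items()
    }
    counts = [table.allele_counts[a] for a in alleles]
    return coded, counts, alleles


def genotype_table_probability(table: GenotypeCountTable) -> float:
    """Conditional probability of the genotype table given its allele counts."""
    coded, counts, _ = _coded_counts(table)
    return math.exp(_log_table_probability(coded, counts))


def enumerate_tables(
    allele_counts: list[int], max_tables: int = 2_000_000
) -> Iterator[dict[tuple[int, int], int]]:
    """Yield every genotype table consistent with the gamete counts.

    Tables are dicts mapping ordered index pairs (i <= j) to counts.  Raises
    :class:`EnumerationTooLarge` (lazily, when the cap is hit) if more than
    ``max_tables`` tables exist.
    """
    k = len(allele_counts)
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    yielded = 0

    def recurse(idx: int, remaining: list[int], het: dict[tuple[int, int], int]):
        nonlocal yielded
        if idx == len(pairs):
            table = dict(het)
            for i in range(k):
                if remaining[i] % 2 != 0 or remaining[i] < 0:
                    return
                table[(i, i)] = remaining[i] // 2
            table = {g: c for g, c in table.items() if c > 0}
            yielded += 1
            if yielded > max_tables:
                raise EnumerationTooLarge(
                    f"more than {max_tables} genotype tables; use Monte Carlo"
                )
            yield table
            return
        i, j = pairs[idx]
        cap = min(remaining[i], remaining[j])
        for nij in range(cap + 1):
            remaining[i] -= nij
            remaining[j] -= nij
            if nij:
                het[(i, j)] = nij
            yield from recurse(idx + 1, remaining, het)
            het.pop((i, j), None)
            remaining[i] += nij
            remaining[j] += nij

    yield from recurse(0, list(allele_counts), {})


def _het_count(coded: dict[tuple[int, int], int]) -> int:
    return sum(c for (i, j), c in coded.items() if i != j)


def hwe_exact_enumeration(
    table: GenotypeCountTable, max_tables: int = 2_000_000
) -> HWEExactResult:
    """Exact conditional HWP test by full enumeration.

    ``p_overall`` sums the probabilities of tables no more probable than the
    observed one; the heterozygote tails sum over tables with heterozygote
    count >= (excess) or <= (deficit) the observed count.
    """
    coded_obs, counts, _ = _coded_counts(table)
    log_obs = _log_table_probability(coded_obs, counts)
    het_obs = _het_count(coded_obs)

    p_overall = 0.0
    p_excess = 0.0
    p_deficit = 0.0
    total = 0.0
    n_tables = 0
    for t in enumerate_tables(counts, max_tables=max_tables):
        logp = _log_table_probability(t, counts)
        p = math.exp(logp)
        total += p
        n_tables += 1
        if logp <= log_obs + _LOG_TIE_TOL:
            p_overall += p
        het = _het_count(t)
        if het >= het_obs:
            p_excess += p
        if het <= het_obs:
            p_deficit += p
    if abs(total - 1.0) > 1e-8:
        raise AssertionError(f"enumerated probabilities sum to {total}, not 1")
    return HWEExactResult(
        locus=table.locus,
        p_overall=min(p_overall, 1.0),
        method="enumeration",
        p_het_excess=min(p_excess, 1.0),
        p_het_deficit=min(p_deficit, 1.0),
        n_tables=n_tables,
    )


def hwe_exact_montecarlo(
    table: GenotypeCountTable, n_samples: int = 10_000, seed: int | None = None
) -> HWEExactResult:
    """Monte-Carlo exact HWP test by random pairing of gamete labels.

    Shuffling the 2n gametes and pairing them off samples genotype tables
    i.i.d. from the conditional distribution given the allele counts.
    p-values use the (1 + hits) / (1 + n_samples) convention so they are never
    zero.  Reproducible for a fixed seed.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    coded_obs, counts, _ = _coded_counts(table)
    log_obs = _log_table_probability(coded_obs, counts)
    het_obs = _het_count(coded_obs)
    n = table.n_individuals
    k = len(counts)

    rng = np.random.default_rng(seed)
    gametes = np.repeat(np.arange(k), counts)
    hits = hits_excess = hits_deficit = 0
    # per-sample log-P differs from log_obs only through H log 2 and the
    # genotype-count factorials, so precompute the constant part
    const = (
        gammaln(n + 1)
        + sum(gammaln(c + 1) for c in counts)
        - gammaln(2 * n + 1)
    )
    for _ in range(n_samples):
        rng.shuffle(gametes)
        a = np.minimum(gametes[0::2], gametes[1::2])
        b = np.maximum(gametes[0::2], gametes[1::2])
        flat = a * k + b
        uniq, cnt = np.unique(flat, return_counts=True)
        het = int(cnt[uniq % k != uniq // k].sum())
        logp = const + het * math.log(2.0) - gammaln(cnt + 1).sum()
        if logp <= log_obs + _LOG_TIE_TOL:
            hits += 1
        if het >= het_obs:
            hits_excess += 1
        if het <= het_obs:
            hits_deficit += 1
    denom = 1 + n_samples
    return HWEExactResult(
        locus=table.locus,
        p_overall=(1 + hits) / denom,
        method="montecarlo",
        p_het_excess=(1 + hits_excess) / denom,
        p_het_deficit=(1 + hits_deficit) / denom,
        n_steps=n_samples,
        seed=seed,
    )


def hwe_exact(
    table: GenotypeCountTable,
    max_tables: int = 100_000,
    n_samples: int = 10_000,
    seed: int | None = None,
) -> HWEExactResult:
    """Exact test by enumeration when feasible, Monte Carlo otherwise."""
    try:
        return hwe_exact_enumeration(table, max_tables=max_tables)
    except EnumerationTooLarge:
        return hwe_exact_montecarlo(table, n_samples=n_samples, seed=seed)
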