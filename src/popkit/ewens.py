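"""Ewens-Watterson homozygosity test of neutrality.

Under the infinite-alleles neutral model, the allele-count configuration of a
sample of n gametes, conditioned on the number k of distinct alleles, follows
the Ewens sampling formula (ESF) with the mutation parameter cancelled out:

    P(config | n, k) = [ n! / (prod_j n_j * prod_m a_m!) ] / |s(n, k)|

where n_j are the allele counts, a_m the number of alleles observed exactly m
times, and |s(n, k)| the unsigned Stirling number of the first kind.  The
test statistic is Watterson's homozygosity F = sum (n_j / n)^2; its null
distribution conditional on (n, k) is obtained either by enumerating all
partitions of n into k parts or by Monte-Carlo sampling from the conditional
ESF.  The lower tail P(F <= F_obs) is reported as the primary p-value (small
F, i.e. unusually even frequencies, is the balancing-selection direction);
the upper tail is also returned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterator, Sequence

import numpy as np
from scipy.special import gammaln

from .summaries import AlleleFrequencyTable, observed_homozygosity

__all__ = [
    "EWResult",
    "EnumerationTooLarge",
    "esf_config_probability",
    "enumerate_partitions",
    "ew_exact_test",
    "ew_montecarlo_test",
    "ew_test",
]

_F_TIE_TOL = 1e-12


class EnumerationTooLarge(ValueError):
    """Partition enumeration would exceed the cap; use Monte Carlo."""


@dataclass
class EWResult:
    locus: str
    F_obs: float
    E_F: float
    sd_F: float
    F_nd: float  # normalized deviate (F_obs - E_F) / sd_F
    p_value: float  # lower tail P(F <= F_obs | n, k)
    p_upper: float  # upper tail P(F >= F_obs | n, k)
    method: str  # "enumeration" | "montecarlo"
    n: int
    k: int
    n_samples: int | None = None
    seed: int | None = None
    acceptance_rate: float | None = None


@lru_cache(maxsize=None)
def _stirling_unsigned(n: int, k: int) -> int:
    """Unsigned Stirling number of the first kind |s(n, k)|, exact integer."""
    if n == 0 and k == 0:
        return 1
    if n == 0 or k == 0 or k > n:
        return 0
    return _stirling_unsigned(n - 1, k - 1) + (n - 1) * _stirling_unsigned(n - 1, k)


def _log_config_weight(config: Sequence[int]) -> float:
    """log( n! / (prod_j n_j * prod_m a_m!) ) for one allele-count configuration."""
    n = sum(config)
    mult: dict[int, int] = {}
    for c in config:
        mult[c] = mult.get(c, 0) + 1
    return float(
        gammaln(n + 1)
        - sum(math.log(c) for c in config)
        - sum(gammaln(a + 1) for a in mult.values())
    )


def esf_config_probability(config: Sequence[int], n: int, k: int) -> float:
    """ESF probability of an allele-count configuration, conditional on k."""
    if len(config) != k or sum(config) != n or any(c < 1 for c in config):
        raise ValueError(f"configuration {tuple(config)} is not a partition of {n} into {k} parts")
    log_norm = math.log(_stirling_unsigned(n, k))
    return math.exp(_log_config_weight(config) - log_norm)


def enumerate_partitions(
    n: int, k: int, max_partitions: int = 500_000
) -> Iterator[tuple[int, ...]]:
    """All partitions of n into exactly k parts, non-increasing order.

    Raises :class:`EnumerationTooLarge` lazily when the cap is hit.
    """
    count = 0

    def recurse(remaining: int, parts_left: int, maximum: int, prefix: list[int]):
        nonlocal count
        if parts_left == 1:
            if 1 <= remaining <= maximum:
                count += 1
                if count > max_partitions:
                    raise EnumerationTooLarge(
                        f"more than {max_partitions} partitions; use Monte Carlo"
                    )
                yield tuple(prefix + [remaining])
            return
        # largest part first; each later part <= current and >= 1
        for part in range(min(maximum, remaining - (parts_left - 1)), 0, -1):
            if part * parts_left < remaining:
                break
            yield from recurse(remaining - part, parts_left - 1, part, prefix + [part])

    if k < 1 or k > n:
        raise ValueError(f"cannot partition {n} gametes into {k} alleles")
    yield from recurse(n, k, n, [])


def _homozygosity(config: Sequence[int], n: int) -> float:
    return sum((c / n) ** 2 for c in config)


def ew_exact_test(
    table: AlleleFrequencyTable, max_partitions: int = 500_000
) -> EWResult:
    """Exact Ewens-Watterson test by enumerating the conditional null."""
    n, k = table.n_gametes, table.k
    F_obs = observed_homozygosity(table)
    log_norm = math.log(_stirling_unsigned(n, k))

    p_lower = p_upper = 0.0
    total = 0.0
    m1 = m2 = 0.0
    for config in enumerate_partitions(n, k, max_partitions=max_partitions):
        p = math.exp(_log_config_weight(config) - log_norm)
        f = _homozygosity(config, n)
        total += p
        m1 += p * f
        m2 += p * f * f
        if f <= F_obs + _F_TIE_TOL:
            p_lower += p
        if f >= F_obs - _F_TIE_TOL:
            p_upper += p
    if abs(total - 1.0) > 1e-8:
        raise AssertionError(f"partition probabilities sum to {total}, not 1")
    E_F = m1
    var = max(m2 - m1 * m1, 0.0)
    sd_F = math.sqrt(var)
    F_nd = (F_obs - E_F) / sd_F if sd_F > 0 else 0.0
    return EWResult(
        locus=table.locus,
        F_obs=F_obs,
        E_F=E_F,
        sd_F=sd_F,
        F_nd=F_nd,
        p_value=min(p_lower, 1.0),
        p_upper=min(p_upper, 1.0),
        method="enumeration",
        n=n,
        k=k,
    )


def _solve_theta(n: int, k: int) -> float:
    """Solve E[K | theta, n] = sum_{i=0}^{n-1} theta/(theta+i) = k by Newton."""
    i = np.arange(n, dtype=float)
    theta = 1.0
    for _ in range(100):
        g = float(np.sum(theta / (theta + i))) - k
        if abs(g) < 1e-10:
            break
        dg = float(np.sum(i / (theta + i) ** 2))
        step = g / dg
        theta = max(theta - step, theta / 10.0)  # keep positive
    return theta


def _hoppe_urn_run(n: int, theta: float, rng: np.random.Generator) -> list[int]:
    """One Chinese-restaurant / Hoppe-urn sample: allele counts for n gametes."""
    counts: list[int] = []
    for i in range(n):
        if rng.random() * (theta + i) < theta:
            counts.append(1)
        else:
            # join an existing allele proportional to its count
            r = rng.random() * i
            acc = 0.0
            for j, c in enumerate(counts):
                acc += c
                if r < acc:
                    counts[j] += 1
                    break
    return counts


def ew_montecarlo_test(
    table: AlleleFrequencyTable,
    n_samples: int = 10_000,
    seed: int | None = None,
    max_attempts: int = 1_000_000,
) -> EWResult:
    """Monte-Carlo Ewens-Watterson test.

    Samples allele-count configurations from the ESF conditional on k by
    running a Hoppe urn with theta chosen so that the expected allele number
    equals k, rejecting runs whose realized allele number differs.  Moments
    and tail probabilities are then sample estimates; p-values use the
    (1 + hits) / (1 + n_samples) convention.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    n, k = table.n_gametes, table.k
    F_obs = observed_homozygosity(table)
    rng = np.random.default_rng(seed)

    if k == 1 or k == n:
        # degenerate conditionals: a single configuration exists
        f_samples = np.full(n_samples, 1.0 if k == 1 else k * (1 / k) ** 2)
        attempts = n_samples
    else:
        theta = _solve_theta(n, k)
        fs: list[float] = []
        attempts = 0
        while len(fs) < n_samples:
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError(
                    f"conditional ESF sampler: only {len(fs)}/{n_samples} accepted "
                    f"after {attempts - 1} attempts "
                    f"(acceptance rate {len(fs) / (attempts - 1):.2e})"
                )
            counts = _hoppe_urn_run(n, theta, rng)
            if len(counts) == k:
                fs.append(_homozygosity(counts, n))
        f_samples = np.asarray(fs)

    hits_lower = int(np.sum(f_samples <= F_obs + _F_TIE_TOL))
    hits_upper = int(np.sum(f_samples >= F_obs - _F_TIE_TOL))
    E_F = float(f_samples.mean())
    sd_F = float(f_samples.std(ddof=1)) if n_samples > 1 else 0.0
    return EWResult(
        locus=table.locus,
        F_obs=F_obs,
        E_F=E_F,
        sd_F=sd_F,
        F_nd=(F_obs - E_F) / sd_F if sd_F > 0 else 0.0,
        p_value=(1 + hits_lower) / (1 + n_samples),
        p_upper=(1 + hits_upper) / (1 + n_samples),
        method="montecarlo",
        n=n,
        k=k,
        n_samples=n_samples,
        seed=seed,
        acceptance_rate=n_samples / attempts if attempts else None,
    )


def ew_test(
    table: AlleleFrequencyTable,
    max_partitions: int = 500_000,
    n_samples: int = 10_000,
    seed: int | None = None,
) -> EWResult:
    """Exact test when the partition count permits, Monte Carlo otherwise."""
    try:
        return ew_exact_test(table, max_partitions=max_partitions)
    except EnumerationTooLarge:
        return ew_montecarlo_test(table, n_samples=n_samples, seed=seed)
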