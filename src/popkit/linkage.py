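"""Pairwise linkage disequilibrium, including the asymmetric ALD measures.

Given a two-locus haplotype frequency table h (I x J) with marginals p and q:

* haplotype-level coefficients  D_ij = h_ij - p_i q_j  and their normalized
  form D'_ij = D_ij / D_max(i, j), with the usual sign-dependent range bound;
* the overall D' summary weights |D'_ij| by the allele-frequency products;
* Wn, a Cramer's-V-style multiallelic correlation,
  Wn = sqrt( sum_ij D_ij^2 / (p_i q_j) / min(I - 1, J - 1) ),
  which reduces to |r| when both loci are biallelic;
* the asymmetric ALD pair (W12, W21).  W12 measures how much knowing the
  allele at locus 2 sharpens prediction of locus 1, via the excess of the
  conditional homozygosity F_{1|2} = sum_j (sum_i h_ij^2) / q_j over the
  unconditional F_1 = sum_i p_i^2:

      W12 = sqrt( (F_{1|2} - F_1) / (1 - F_1) ),

  and symmetrically for W21 conditioning on locus 1.  Both also equal |r|
  for biallelic loci, but differ from each other when the two loci carry
  different numbers (or shapes) of alleles.  ALD at a monomorphic locus is
  undefined and reported as None.

Significance is assessed by a permutation test: locus-2 genotypes are
shuffled across individuals (preserving both single-locus distributions,
destroying the association), haplotypes re-estimated by EM, and the observed
Wn compared with the permuted ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dataio import PopulationDataset
from .haplotype import HaplotypeEstimate, estimate_haplotypes

__all__ = [
    "LDPermutationRecord",
    "LDPairResult",
    "ld_coefficients",
    "dprime_overall",
    "wn_overall",
    "ald_pair",
    "ld_from_haplotypes",
    "compute_ld",
    "ld_permutation_test",
]

_MARGINAL_TOL = 1e-9
_RADICAND_TOL = 1e-12


class MarginalMismatchError(ValueError):
    """Haplotype table marginals disagree with the supplied allele frequencies."""


@dataclass
class LDPermutationRecord:
    n_permutations: int
    p_value: float
    statistic: str  # name of the permuted statistic ("Wn")
    observed: float
    seed: int | None = None
    n_redrawn: int = 0


@dataclass
class LDPairResult:
    locus1: str
    locus2: str
    alleles1: list[str]
    alleles2: list[str]
    p: np.ndarray  # locus-1 allele frequencies (aligned with alleles1)
    q: np.ndarray  # locus-2 allele frequencies (aligned with alleles2)
    d: np.ndarray  # I x J haplotype-level D_ij
    dprime_ij: np.ndarray  # I x J normalized D'_ij
    dprime: float  # overall summary D'
    wn: float | None  # None when either locus is monomorphic
    ald_1_2: float | None  # W12: LD at locus 1 conditional on locus 2
    ald_2_1: float | None  # W21: LD at locus 2 conditional on locus 1
    permutation: LDPermutationRecord | None = None

    @property
    def I(self) -> int:  # noqa: E743 - conventional symbol
        return len(self.alleles1)

    @property
    def J(self) -> int:
        return len(self.alleles2)


def _check_table(
    h: np.ndarray, p: np.ndarray | None, q: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    h = np.asarray(h, dtype=float)
    if h.ndim != 2:
        raise ValueError("haplotype table must be 2-dimensional")
    if np.any(h < -_MARGINAL_TOL) or abs(h.sum() - 1.0) > _MARGINAL_TOL:
        raise ValueError("haplotype frequencies must be non-negative and sum to 1")
    row = h.sum(axis=1)
    col = h.sum(axis=0)
    if p is None:
        p = row
    else:
        p = np.asarray(p, dtype=float)
        if p.shape != row.shape or np.abs(p - row).max() > _MARGINAL_TOL:
            raise MarginalMismatchError("locus-1 marginals inconsistent with haplotype table")
    if q is None:
        q = col
    else:
        q = np.asarray(q, dtype=float)
        if q.shape != col.shape or np.abs(q - col).max() > _MARGINAL_TOL:
            raise MarginalMismatchError("locus-2 marginals inconsistent with haplotype table")
    return h, p, q


def ld_coefficients(
    h: np.ndarray, p: np.ndarray | None = None, q: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Haplotype-level D_ij and D'_ij matrices.

    D_max is min(p_i q_j, (1-p_i)(1-q_j)) for negative D and
    min(p_i (1-q_j), (1-p_i) q_j) for positive D; D'_ij is 0 where D_ij is 0.
    """
    h, p, q = _check_table(h, p, q)
    d = h - np.outer(p, q)
    pi = p[:, None]
    qj = q[None, :]
    dmax_neg = np.minimum(pi * qj, (1 - pi) * (1 - qj))
    dmax_pos = np.minimum(pi * (1 - qj), (1 - pi) * qj)
    dmax = np.where(d < 0, dmax_neg, dmax_pos)
    with np.errstate(divide="ignore", invalid="ignore"):
        dprime = np.where(np.abs(d) > 0, d / dmax, 0.0)
    return d, dprime


def dprime_overall(dprime_ij: np.ndarray, p: np.ndarray, q: np.ndarray) -> float:
    """Overall D': allele-frequency-product weighted mean of |D'_ij|."""
    return float(np.sum(np.outer(p, q) * np.abs(dprime_ij)))


def wn_overall(d: np.ndarray, p: np.ndarray, q: np.ndarray) -> float | None:
    """Multiallelic correlation Wn; None when either locus is monomorphic."""
    I, J = d.shape
    if I < 2 or J < 2:
        return None
    chi_norm = float(np.sum(d * d / np.outer(p, q)))
    return math.sqrt(chi_norm / min(I - 1, J - 1))


def ald_pair(
    h: np.ndarray, p: np.ndarray | None = None, q: np.ndarray | None = None
) -> tuple[float | None, float | None]:
    """Asymmetric LD measures (W12, W21).

    W12 (ALD_1_2) compares the homozygosity of locus 1 conditional on the
    locus-2 allele with its unconditional homozygosity; it is undefined
    (None) when locus 1 is monomorphic, and symmetrically for W21.
    Radicands within -1e-12 of zero are clamped to 0.
    """
    h, p, q = _check_table(h, p, q)

    def one_direction(h_cond: np.ndarray, marg_given: np.ndarray, marg_target: np.ndarray) -> float | None:
        f_target = float(np.sum(marg_target**2))
        if 1.0 - f_target <= _RADICAND_TOL:
            return None  # target locus monomorphic
        with np.errstate(divide="ignore", invalid="ignore"):
            cond = np.where(marg_given > 0, (h_cond**2).sum(axis=0) / marg_given, 0.0)
        f_cond = float(cond.sum())
        radicand = (f_cond - f_target) / (1.0 - f_target)
        if radicand < 0:
            if radicand < -_RADICAND_TOL:
                raise AssertionError(f"conditional homozygosity below unconditional: {radicand}")
            radicand = 0.0
        return math.sqrt(min(radicand, 1.0))

    w12 = one_direction(h, q, p)  # condition on locus 2, measure locus 1
    w21 = one_direction(h.T, p, q)  # condition on locus 1, measure locus 2
    return w12, w21


def ld_from_haplotypes(
    estimate: HaplotypeEstimate, permutation: LDPermutationRecord | None = None
) -> LDPairResult:
    """Assemble all pairwise LD measures from a two-locus haplotype estimate."""
    if len(estimate.loci) != 2:
        raise ValueError("pairwise LD needs a 2-locus haplotype estimate")
    locus1, locus2 = estimate.loci
    alleles1 = sorted(estimate.locus_marginals(locus1))
    alleles2 = sorted(estimate.locus_marginals(locus2))
    i1 = {a: i for i, a in enumerate(alleles1)}
    i2 = {a: i for i, a in enumerate(alleles2)}
    h = np.zeros((len(alleles1), len(alleles2)))
    for hap, f in zip(estimate.haplotypes, estimate.frequencies):
        h[i1[hap[0]], i2[hap[1]]] += float(f)
    p = h.sum(axis=1)
    q = h.sum(axis=0)
    d, dp = ld_coefficients(h, p, q)
    w12, w21 = ald_pair(h, p, q)
    return LDPairResult(
        locus1=locus1,
        locus2=locus2,
        alleles1=alleles1,
        alleles2=alleles2,
        p=p,
        q=q,
        d=d,
        dprime_ij=dp,
        dprime=dprime_overall(dp, p, q),
        wn=wn_overall(d, p, q),
        ald_1_2=w12,
        ald_2_1=w21,
        permutation=permutation,
    )


# ---------------------------------------------------------------------------
# fast 2-locus EM on integer-coded genotypes (used by the permutation test)
# ---------------------------------------------------------------------------


def _coded_pair_genotypes(
    dataset: PopulationDataset, locus1: str, locus2: str
) -> tuple[np.ndarray, list[str], list[str]]:
    """(n x 4) array of allele codes (a1, b1, a2, b2), complete pairs only."""
    g1 = dataset.genotypes_at(locus1)
    g2 = dataset.genotypes_at(locus2)
    rows = []
    names1: dict[str, int] = {}
    names2: dict[str, int] = {}

    def code(table: dict[str, int], raw: str) -> int:
        if raw not in table:
            table[raw] = len(table)
        return table[raw]

    for x, y in zip(g1, g2):
        if not (x.complete and y.complete):
            continue
        rows.append(
            (
                code(names1, x.allele1.raw),
                code(names1, x.allele2.raw),
                code(names2, y.allele1.raw),
                code(names2, y.allele2.raw),
            )
        )
    if not rows:
        raise ValueError(f"no individuals typed at both {locus1!r} and {locus2!r}")
    return np.asarray(rows, dtype=np.intp), list(names1), list(names2)


def _pair_em_wn(codes: np.ndarray, k1: int, k2: int, tol: float, max_iter: int) -> float:
    """Wn from a minimal 2-locus EM over integer-coded genotype rows."""
    # build flat resolution arrays: each row yields 1 or 2 haplotype pairs
    h1: list[int] = []
    h2: list[int] = []
    offsets = [0]
    for a1, b1, a2, b2 in codes:
        if a1 != b1 and a2 != b2:
            h1 += [a1 * k2 + a2, a1 * k2 + b2]
            h2 += [b1 * k2 + b2, b1 * k2 + a2]
        else:
            h1.append(a1 * k2 + a2)
            h2.append(b1 * k2 + b2)
        offsets.append(len(h1))
    h1a = np.asarray(h1, dtype=np.intp)
    h2a = np.asarray(h2, dtype=np.intp)
    off = np.asarray(offsets, dtype=np.intp)
    starts = off[:-1]
    sizes = np.diff(off)
    het = np.where(h1a != h2a, 2.0, 1.0)
    n = len(codes)
    used = np.union1d(h1a, h2a)
    m_total = k1 * k2
    f = np.zeros(m_total)
    f[used] = 1.0 / len(used)
    for _ in range(max_iter):
        w = het * f[h1a] * f[h2a]
        per = np.add.reduceat(w, starts)
        w /= np.repeat(per, sizes)
        f_new = (
            np.bincount(h1a, weights=w, minlength=m_total)
            + np.bincount(h2a, weights=w, minlength=m_total)
        ) / (2 * n)
        if np.abs(f_new - f).max() < tol:
            f = f_new
            break
        f = f_new
    h = f.reshape(k1, k2)
    p = h.sum(axis=1)
    q = h.sum(axis=0)
    h = h[p > 0][:, q > 0]
    d = h - np.outer(h.sum(axis=1), h.sum(axis=0))
    wn = wn_overall(d, h.sum(axis=1), h.sum(axis=0))
    return 0.0 if wn is None else wn


def ld_permutation_test(
    dataset: PopulationDataset,
    locus1: str,
    locus2: str,
    n_permutations: int,
    seed: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> LDPermutationRecord:
    """Permutation significance test for pairwise LD.

    The observed statistic is Wn from EM-estimated haplotype frequencies.
    Each permutation shuffles the locus-2 genotype column across individuals
    and re-runs the EM; p = (1 + #{Wn_perm >= Wn_obs}) / (1 + n_permutations).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    codes, names1, names2 = _coded_pair_genotypes(dataset, locus1, locus2)
    k1, k2 = len(names1), len(names2)
    obs = _pair_em_wn(codes, k1, k2, tol, max_iter)
    rng = np.random.default_rng(seed)
    hits = 0
    perm = codes.copy()
    for _ in range(n_permutations):
        order = rng.permutation(len(codes))
        perm[:, 2:] = codes[order, 2:]
        stat = _pair_em_wn(perm, k1, k2, tol, max_iter)
        if stat >= obs - 1e-12:
            hits += 1
    return LDPermutationRecord(
        n_permutations=n_permutations,
        p_value=(1 + hits) / (1 + n_permutations),
        statistic="Wn",
        observed=obs,
        seed=seed,
    )


def compute_ld(
    dataset: PopulationDataset,
    locus1: str,
    locus2: str,
    n_permutations: int = 0,
    seed: int | None = None,
    tol: float = 1e-7,
    max_iter: int = 1000,
) -> LDPairResult:
    """EM-estimate two-locus haplotypes and derive every pairwise LD measure.

    With ``n_permutations`` = 0 no permutation test is run and the
    permutation record is absent from the result (and from all reports).
    """
    estimate = estimate_haplotypes(dataset, (locus1, locus2), tol=tol, max_iter=max_iter)
    record = None
    if n_permutations > 0:
        record = ld_permutation_test(
            dataset, locus1, locus2, n_permutations, seed=seed
        )
    return ld_from_haplotypes(estimate, permutation=record)
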