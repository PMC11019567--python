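"""EM estimation of multi-locus haplotype frequencies from unphased genotypes.

Each individual's multi-locus genotype is compatible with 2^(h-1) ordered-
normalized haplotype pairs, h being the number of heterozygous loci (1 pair
when h <= 1).  The E-step weights pair (h1, h2) by f(h1) f(h2), doubled for
h1 != h2, normalized within the individual; the M-step sets each haplotype
frequency to its expected gamete share.  The likelihood never decreases, so
iteration stops when the largest frequency change falls below a tolerance.
Multiple restarts (uniform initialization first, then random simplex draws)
guard against local optima in larger systems.

Individuals untyped at any requested locus are excluded listwise and the
exclusion count reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dataio import PopulationDataset, format_haplotype_name

__all__ = [
    "ResolutionSet",
    "HaplotypeEstimate",
    "enumerate_resolutions",
    "em_estimate",
    "estimate_haplotypes",
]

MAX_LOCI = 8
DROP_THRESHOLD = 1e-8


@dataclass
class ResolutionSet:
    """Phase-consistent haplotype-pair resolutions for every usable individual."""

    loci: tuple[str, ...]
    haplotypes: list[tuple[str, ...]]  # allele tuples, indexed by pair arrays
    pair_h1: np.ndarray  # flat arrays over all (individual, resolution) pairs
    pair_h2: np.ndarray
    offsets: np.ndarray  # individual i owns pairs offsets[i]:offsets[i+1]
    n_individuals: int
    n_excluded: int  # dropped listwise for missing data

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)


def enumerate_resolutions(
    dataset: PopulationDataset,
    loci: Sequence[str],
    max_resolutions: int = 4096,
) -> ResolutionSet:
    """Enumerate all haplotype-pair resolutions over the requested loci.

    An individual heterozygous at h of the loci contributes 2^(h-1) pairs
    (fixing the first heterozygous locus breaks the mirror symmetry).
    """
    loci = tuple(loci)
    if len(loci) > MAX_LOCI:
        raise ValueError(f"{len(loci)} loci requested; cap is {MAX_LOCI}")
    idx = [dataset.locus_index(l) for l in loci]

    hap_index: dict[tuple[str, ...], int] = {}
    pair_h1: list[int] = []
    pair_h2: list[int] = []
    offsets = [0]
    n_excluded = 0

    def hap_id(hap: tuple[str, ...]) -> int:
        hid = hap_index.get(hap)
        if hid is None:
            hid = len(hap_index)
            hap_index[hap] = hid
        return hid

    for ind_no, row in enumerate(dataset.individuals):
        genos = [row[i] for i in idx]
        if not all(g.complete for g in genos):
            n_excluded += 1
            continue
        pairs = [(g.allele1.raw, g.allele2.raw) for g in genos]
        het = [li for li, (a, b) in enumerate(pairs) if a != b]
        n_res = 1 << max(len(het) - 1, 0)
        if n_res > max_resolutions:
            raise ValueError(
                f"individual {ind_no} has {n_res} phase resolutions "
                f"(cap {max_resolutions})"
            )
        for mask in range(n_res):
            h1, h2 = [], []
            bit = 0
            for li, (a, b) in enumerate(pairs):
                if a == b:
                    h1.append(a)
                    h2.append(a)
                elif li == (het[0] if het else -1):
                    h1.append(a)  # anchor: first het locus keeps file order
                    h2.append(b)
                else:
                    flip = (mask >> bit) & 1
                    bit += 1
                    h1.append(b if flip else a)
                    h2.append(a if flip else b)
            pair_h1.append(hap_id(tuple(h1)))
            pair_h2.append(hap_id(tuple(h2)))
        offsets.append(len(pair_h1))

    if len(offsets) == 1:
        raise ValueError(f"no individuals completely typed at loci {loci}")
    return ResolutionSet(
        loci=loci,
        haplotypes=list(hap_index),
        pair_h1=np.asarray(pair_h1, dtype=np.intp),
        pair_h2=np.asarray(pair_h2, dtype=np.intp),
        offsets=np.asarray(offsets, dtype=np.intp),
        n_individuals=len(offsets) - 1,
        n_excluded=n_excluded,
    )


@dataclass
class HaplotypeEstimate:
    loci: tuple[str, ...]
    haplotypes: list[tuple[str, ...]]  # all haplotypes seen by the EM
    frequencies: np.ndarray  # aligned with `haplotypes`, sums to 1
    loglik: float
    n_iterations: int
    converged: bool
    n_individuals: int
    n_excluded: int
    n_restarts: int = 1
    seed: int | None = None

    @property
    def n_gametes(self) -> int:
        return 2 * self.n_individuals

    @property
    def freqs(self) -> dict[str, float]:
        """GL-String-named haplotype frequencies, rare estimates dropped."""
        out = {
            format_haplotype_name(h): float(f)
            for h, f in zip(self.haplotypes, self.frequencies)
            if f >= DROP_THRESHOLD
        }
        return dict(sorted(out.items()))

    @property
    def counts(self) -> dict[str, float]:
        return {name: f * self.n_gametes for name, f in self.freqs.items()}

    def locus_marginals(self, locus: str) -> dict[str, float]:
        """Allele frequencies at one locus implied by the haplotype estimate."""
        li = self.loci.index(locus)
        out: dict[str, float] = {}
        for h, f in zip(self.haplotypes, self.frequencies):
            out[h[li]] = out.get(h[li], 0.0) + float(f)
        return dict(sorted(out.items()))


def _em_run(
    res: ResolutionSet,
    f0: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, float, int, bool]:
    h1, h2, offsets = res.pair_h1, res.pair_h2, res.offsets
    starts = offsets[:-1]
    het_factor = np.where(h1 != h2, 2.0, 1.0)
    n = res.n_individuals
    f = f0.copy()
    loglik = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = het_factor * f[h1] * f[h2]
        per_ind = np.add.reduceat(w, starts)
        loglik = float(np.log(per_ind).sum())
        w /= np.repeat(per_ind, np.diff(offsets))
        f_new = (
            np.bincount(h1, weights=w, minlength=res.n_haplotypes)
            + np.bincount(h2, weights=w, minlength=res.n_haplotypes)
        ) / (2 * n)
        delta = float(np.abs(f_new - f).max())
        f = f_new
        if delta < tol:
            converged = True
            break
    # final log-likelihood at the returned frequencies
    w = het_factor * f[h1] * f[h2]
    loglik = float(np.log(np.add.reduceat(w, starts)).sum())
    return f, loglik, it, converged


def em_estimate(
    res: ResolutionSet,
    tol: float = 1e-7,
    max_iter: int = 1000,
    n_restarts: int = 1,
    seed: int | None = None,
) -> HaplotypeEstimate:
    """Run the EM to convergence; return the best solution over restarts.

    Restart 0 starts from uniform frequencies; later restarts draw the
    starting point from a flat Dirichlet under ``seed``.
    """
    m = res.n_haplotypes
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, float, int, bool] | None = None
    for r in range(max(n_restarts, 1)):
        f0 = np.full(m, 1.0 / m) if r == 0 else rng.dirichlet(np.ones(m))
        run = _em_run(res, f0, tol, max_iter)
        if best is None or run[1] > best[1]:
            best = run
    f, loglik, n_iter, converged = best
    return HaplotypeEstimate(
        loci=res.loci,
        haplotypes=res.haplotypes,
        frequencies=f,
        loglik=loglik,
        n_iterations=n_iter,
        converged=converged,
        n_individuals=res.n_individuals,
        n_excluded=res.n_excluded,
        n_restarts=max(n_restarts, 1),
        seed=seed,
    )


def estimate_haplotypes(
    dataset: PopulationDataset,
    loci: Sequence[str],
    tol: float = 1e-7,
    max_iter: int = 1000,
    n_restarts: int = 1,
    seed: int | None = None,
) -> HaplotypeEstimate:
    """Convenience wrapper: enumerate resolutions, then run the EM."""
    res = enumerate_resolutions(dataset, loci)
    return em_estimate(res, tol=tol, max_iter=max_iter, n_restarts=n_restarts, seed=seed)
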