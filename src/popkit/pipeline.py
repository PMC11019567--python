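"""Orchestration: run the analyses an :class:`AnalysisConfig` requests.

Per-analysis random seeds are derived deterministically from one master seed
and a stable per-analysis tag, so a whole run is byte-reproducible while
independent analyses still use independent streams.
"""

from __future__ import annotations

import zlib

from .config import AnalysisConfig, apply_binning
from .dataio import PopulationDataset
from .ewens import ew_exact_test, ew_montecarlo_test, ew_test
from .ewens import EnumerationTooLarge as EWTooLarge
from .hardyweinberg import (
    EnumerationTooLarge as HWETooLarge,
    hwe_chisq,
    hwe_exact_enumeration,
    hwe_exact_montecarlo,
)
from .haplotype import estimate_haplotypes
from .linkage import ld_from_haplotypes, ld_permutation_test
from .reporting import HaplotypeBlock, LocusSummary, PopulationReport
from .summaries import NoTypedDataError, count_alleles, genotype_counts, observed_homozygosity

__all__ = ["derive_seed", "run_analysis"]


def derive_seed(master: int | None, tag: str) -> int | None:
    """A reproducible child seed (< 2^31) from a master seed and a tag."""
    if master is None:
        return None
    return (master * 1_000_003 + zlib.crc32(tag.encode())) % (2**31)


def run_analysis(
    dataset: PopulationDataset, config: AnalysisConfig, seed: int | None = None
) -> PopulationReport:
    """Run every requested analysis on one population and build its report."""
    if config.binning is not None:
        dataset = apply_binning(dataset, config.binning)
    if seed is None:
        seed = config.seed(0)

    report = PopulationReport(
        metadata=dict(dataset.metadata),
        loci=list(dataset.loci),
        n_individuals=dataset.n_individuals,
    )

    include_genotypes = config.getbool("General", "output-genotypes", False)
    lump = config.getfloat("HardyWeinberg", "lump-threshold", 5.0)
    hwe_max_tables = config.getint("HardyWeinberg", "max-tables", 100_000)
    hwe_samples = config.getint("HardyWeinberg", "n-samples", 10_000)
    hwe_method = config.get("HardyWeinberg", "method", "auto")
    ew_max_partitions = config.getint("EwensWatterson", "max-partitions", 500_000)
    ew_samples = config.getint("EwensWatterson", "n-samples", 10_000)
    ew_method = config.get("EwensWatterson", "method", "auto")

    for locus in dataset.loci:
        try:
            freq_table = count_alleles(dataset, locus)
        except NoTypedDataError:
            continue  # locus entirely untyped: no summary block
        gt_table = genotype_counts(dataset, locus)
        summary = LocusSummary(
            locus=locus,
            allele_table=freq_table,
            homozygosity=observed_homozygosity(freq_table),
            genotype_table=gt_table if include_genotypes else None,
            n_untyped=dataset.n_individuals - freq_table.n_individuals,
        )
        polymorphic = freq_table.k >= 2
        if config.hwe_chisq_enabled and polymorphic:
            summary.hwe_chisq = hwe_chisq(gt_table, lump_threshold=lump)
        if config.hwe_exact_enabled and polymorphic:
            mc_seed = derive_seed(seed, f"hwe:{locus}")
            if hwe_method == "montecarlo":
                summary.hwe_exact = hwe_exact_montecarlo(gt_table, hwe_samples, seed=mc_seed)
            elif hwe_method == "enumeration":
                summary.hwe_exact = hwe_exact_enumeration(gt_table, max_tables=hwe_max_tables)
            else:
                try:
                    summary.hwe_exact = hwe_exact_enumeration(gt_table, max_tables=hwe_max_tables)
                except HWETooLarge:
                    summary.hwe_exact = hwe_exact_montecarlo(gt_table, hwe_samples, seed=mc_seed)
        if config.ewens_watterson_enabled and polymorphic:
            ew_seed = derive_seed(seed, f"ew:{locus}")
            if ew_method == "montecarlo":
                summary.ew = ew_montecarlo_test(freq_table, ew_samples, seed=ew_seed)
            elif ew_method == "enumeration":
                summary.ew = ew_exact_test(freq_table, max_partitions=ew_max_partitions)
            else:
                summary.ew = ew_test(
                    freq_table,
                    max_partitions=ew_max_partitions,
                    n_samples=ew_samples,
                    seed=ew_seed,
                )
        report.locus_summaries.append(summary)

    tol = config.getfloat("Haplotypes", "tol", 1e-7)
    max_iter = config.getint("Haplotypes", "max-iter", 1000)
    restarts = config.getint("Haplotypes", "restarts", 1)
    n_perm = config.ld_permutations

    blocks: dict[tuple[str, ...], HaplotypeBlock] = {}
    for locus_set in config.haplotype_locus_sets(dataset.loci):
        if locus_set in blocks:
            continue
        est = estimate_haplotypes(
            dataset,
            locus_set,
            tol=tol,
            max_iter=max_iter,
            n_restarts=restarts,
            seed=derive_seed(seed, f"em:{':'.join(locus_set)}"),
        )
        blocks[locus_set] = HaplotypeBlock(loci=locus_set, estimate=est)

    for pair in config.linkage_pairs(dataset.loci):
        block = blocks.get(pair)
        if block is None:
            est = estimate_haplotypes(
                dataset,
                pair,
                tol=tol,
                max_iter=max_iter,
                n_restarts=restarts,
                seed=derive_seed(seed, f"em:{':'.join(pair)}"),
            )
            block = HaplotypeBlock(loci=pair, estimate=est)
            blocks[pair] = block
        record = None
        if n_perm > 0:
            record = ld_permutation_test(
                dataset,
                pair[0],
                pair[1],
                n_perm,
                seed=derive_seed(seed, f"perm:{':'.join(pair)}"),
            )
        block.ld = ld_from_haplotypes(block.estimate, permutation=record)

    report.haplotype_blocks = list(blocks.values())
    return report
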