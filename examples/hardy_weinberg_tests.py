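"""Hardy-Weinberg testing on a simulated population with inbreeding.

Simulates 300 individuals at one triallelic locus with inbreeding
coefficient f = 0.2 (homozygote excess), then runs the chi-square test and
the conditional exact test (enumeration if feasible, else Monte Carlo).
"""

from popkit import SimulationSpec, genotype_counts, hwe_chisq, hwe_exact, sample_population

spec = SimulationSpec(
    loci=("DRB1",),
    n_individuals=300,
    allele_freqs=[{"01:01": 0.5, "04:01": 0.3, "07:01": 0.2}],
    inbreeding_f=0.2,
    seed=42,
)
dataset, truth = sample_population(spec)
table = genotype_counts(dataset, "DRB1")

chisq = hwe_chisq(table)
exact = hwe_exact(table, seed=42)

print(f"individuals: {table.n_individuals}, heterozygotes: {table.n_heterozygotes}")
print(f"chi-square:  chisq = {chisq.chisq:.3f}, df = {chisq.df}, p = {chisq.pvalue:.3g}")
print(f"exact test ({exact.method}): p = {exact.p_overall:.3g}")
print(f"  heterozygote deficit p = {exact.p_het_deficit:.3g}  (small: too few hets)")
print(f"  heterozygote excess  p = {exact.p_het_excess:.3g}")
print()
print(
    "With f = 0.2 the population has ~20% fewer heterozygotes than random\n"
    "mating predicts, so both tests reject Hardy-Weinberg proportions and\n"
    "the deficit tail carries the signal."
)
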