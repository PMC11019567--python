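"""EM haplotype frequency estimation with a known ground truth.

Simulates 500 individuals from a specified two-locus haplotype distribution
(with linkage disequilibrium), estimates haplotype frequencies by EM from
the unphased genotypes, and compares the estimates with the truth.
"""

from popkit import SimulationSpec, compute_ld, estimate_haplotypes, sample_population

truth = {
    ("A*01:01", "B*08:01"): 0.30,
    ("A*01:01", "B*07:02"): 0.05,
    ("A*02:01", "B*08:01"): 0.10,
    ("A*02:01", "B*07:02"): 0.35,
    ("A*03:01", "B*07:02"): 0.20,
}
spec = SimulationSpec(loci=("A", "B"), n_individuals=500, haplotype_freqs=truth, seed=11)
dataset, _ = sample_population(spec)

est = estimate_haplotypes(dataset, ("A", "B"))
print(f"EM converged in {est.n_iterations} iterations, loglik = {est.loglik:.2f}")
print(f"{'haplotype':24s} {'true':>6s} {'estimated':>9s}")
for hap, f_true in sorted(truth.items()):
    name = "~".join(hap)
    print(f"{name:24s} {f_true:6.3f} {est.freqs.get(name, 0.0):9.3f}")

ld = compute_ld(dataset, "A", "B")
print()
print(f"D' = {ld.dprime:.3f}, Wn = {ld.wn:.3f}, W12 = {ld.ald_1_2:.3f}, W21 = {ld.ald_2_1:.3f}")
print()
print(
    "Estimates track the generating frequencies to a few per cent at this\n"
    "sample size; the LD summaries are then derived from the same EM fit."
)
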