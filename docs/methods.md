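# Methods

This note documents the statistical models behind popkit, the conventions
and tunable parameters, the design choices that were genuinely open, and
what the synthetic-data generator does and does not emulate.

## Data model and input conventions

A population is an individuals × loci matrix of unordered allele pairs plus
free-form metadata. The `.pop` dialect is: optional `key: value` metadata
lines (no tabs), a tab-separated header with two columns per locus named
`<locus>_1`/`<locus>_2`, then one tab-separated row per individual. The
untyped marker is `****` (configurable, `[General] untypedAllele`). Allele
names are arbitrary non-whitespace tokens, so colon-delimited HLA names of
any length survive verbatim; validation is deliberately permissive because
rejecting unknown names would require a nomenclature database, which is out
of scope. Haplotypes are rendered with the GL String `~` separator.

Missing data are handled per-locus for single-locus statistics (an
individual untyped at locus A still contributes to locus B) and listwise
within each requested locus set for haplotype estimation; both exclusion
counts are reported, and no individual is ever dropped silently.

Custom binning (`[CustomBinning]`) replaces member alleles by their group
identifier before any analysis. Matching is exact and case-sensitive —
HLA names are case-normalized upstream, and silent case-folding would mask
data errors. An allele claimed by two groups at one locus is a hard error;
transitive binning (a group identifier that is itself a member elsewhere)
is likewise rejected rather than resolved, because either order of
application would be defensible and silent disambiguation is worse than an
error. Unmatched and untyped alleles pass through unchanged, which makes
the operation idempotent in the supported configurations.

## Hardy-Weinberg tests

The chi-square test compares observed genotype counts with n·pᵢ² and
2n·pᵢpⱼ, where p comes from the observed gamete counts. Genotype classes
with expected count below the lump threshold (default 5, the classical
rule; `lump-threshold`) are pooled into a single class. Degrees of freedom
are (#classes after lumping) − k, floored at 1, accounting for the k − 1
estimated allele frequencies plus the total.

The exact test conditions on the allele counts; the probability of a
genotype table is P = n!·∏cᵢ!·2ᴴ / ((2n)!·∏nᵢⱼ!), with H the heterozygote
count. The overall p-value sums P over tables no more probable than the
observed one; the heterozygote excess/deficit tails sum P over tables with
H ≥ (resp. ≤) the observed H. Those tail statistics are a declared
convention of this package: the total heterozygote count is the natural
one-dimensional axis for the direction of departure. Full enumeration is
used up to `max-tables` (default 100 000) tables; beyond that a Monte-Carlo
version samples tables i.i.d. by shuffling the 2n gamete labels into n
pairs — an exchangeable pairing is exactly the conditional null. A
Markov-chain sampler with switch proposals would target the same
distribution; the i.i.d. shuffler was chosen because it has no mixing time
or autocorrelation to argue about and is directly validated against
enumeration. All Monte-Carlo p-values use (1 + hits)/(1 + N) so a reported
p is never 0. Probability ties are compared on log-probabilities with
absolute tolerance 1e−12.

## Ewens–Watterson test

Under the neutral infinite-alleles model, conditional on sample size n
(gametes) and allele number k, the allele-count configuration follows the
Ewens sampling formula with the mutation parameter cancelled:
P(config) = [n!/(∏ⱼnⱼ·∏ₘaₘ!)]/|s(n,k)|, with |s(n,k)| the unsigned Stirling
number of the first kind (computed exactly by integer recurrence). The test
statistic is F = Σ(nⱼ/n)². The exact route enumerates all partitions of n
into k parts (cap `max-partitions`, default 500 000); the Monte-Carlo route
runs a Hoppe urn with θ solved from Σᵢθ/(θ+i) = k by Newton iteration and
rejects runs whose realized allele number is not k — this targets the
conditional law exactly, at acceptance rates that are comfortable for the
(n, k) ranges where enumeration is infeasible but the test is still
meaningful. The primary p-value is the lower tail P(F ≤ F_obs), because
unusually even frequencies (low F) are the balancing-selection direction of
interest at immune loci; the upper tail is also reported, as is the
normalized deviate F_nd = (F_obs − E[F])/sd(F), negative under
balancing-selection-like evenness.

## EM haplotype estimation

Each individual heterozygous at h of the requested loci is compatible with
2^(h−1) ordered-normalized haplotype pairs. The E-step weights pair
(h₁, h₂) by f(h₁)f(h₂), doubled when h₁ ≠ h₂, normalized within the
individual; the M-step sets each f to its expected gamete share. The
log-likelihood is non-decreasing by construction and is asserted so in
tests. Convergence: max |Δf| < 1e−7, at most 1000 iterations,
non-convergence reported rather than raised. Restart 0 is uniform; optional
extra restarts draw starting points from a flat Dirichlet under the run
seed, and the best log-likelihood wins. The locus cap is 8 (resolution
count grows as 2^(h−1) per individual and the full haplotype space is
retained); haplotypes with final frequency below 1e−8 are dropped from
reports after normalization. With phase-unambiguous data the EM fixed point
equals direct gamete counting exactly, which is used as an oracle test.

## Linkage disequilibrium and ALD

From a two-locus haplotype table h with marginals p, q: Dᵢⱼ = hᵢⱼ − pᵢqⱼ;
D′ᵢⱼ normalizes by min(pᵢqⱼ, (1−pᵢ)(1−qⱼ)) for negative D and
min(pᵢ(1−qⱼ), (1−pᵢ)qⱼ) for positive D. Overall D′ = ΣᵢⱼpᵢqⱼD′ᵢⱼ;
Wn = √(ΣᵢⱼDᵢⱼ²/(pᵢqⱼ)/min(I−1, J−1)). The asymmetric pair uses conditional
homozygosity: F₁|₂ = Σⱼ(Σᵢhᵢⱼ²)/qⱼ and W12 = √((F₁|₂ − F₁)/(1 − F₁)),
symmetrically W21. The orientation is fixed: W12 (ALD_1_2 in outputs)
conditions on the *second* locus, W21 on the first. ALD at a monomorphic
target locus is undefined and reported as NA, not 0 — a zero would claim
evidence of no association where the quantity has no meaning. Floating-
point radicands in (−1e−12, 0) are clamped to 0. For biallelic pairs both
measures equal |r|, verified to 1e−10 over random tables.

LD is computed from EM haplotype estimates treated as known frequencies;
EM sampling error is not propagated into D′/Wn/ALD. Significance therefore
comes from a permutation test: locus-2 genotype columns are shuffled across
individuals (preserving both single-locus genotype distributions,
destroying the between-locus pairing), the EM re-run, and the observed Wn
compared with the permuted distribution, p = (1 + hits)/(1 + N). Wn was
chosen as the permutation statistic because it is a single bounded summary
with the SNP-r limit; an EM likelihood-ratio statistic would be a
reasonable alternative but is not the default. The permutation EM cannot
fail (a non-converged run still yields a valid statistic), so no
permutation is ever discarded.

## Synthetic data

The generator draws 2n haplotypes from specified frequencies (or from
independent per-locus allele frequencies) and pairs them at random, so the
population is in Hardy-Weinberg proportions at the haplotype level by
construction. Two controlled departures exist: an inbreeding-like
coefficient f (with probability f an individual is a duplicated single
haplotype draw, giving expected heterozygosity 2pq(1−f) at a biallelic
locus — chosen because it has closed-form expectations to test against),
and an i.i.d. missing-data rate. It does not emulate genotyping-error
ambiguity codes, allele dropout correlated with genotype, population
structure, or mutation/coalescent history; passing tests therefore
demonstrate correctness of the statistics under random mating and clean
typing, not robustness to structured artefacts in real HLA data.

## Reports and aggregation

XML is the canonical machine-readable output; the text report and the TSV
aggregation are derived views. Frequencies are serialized to 6 significant
digits; test statistics and p-values at full precision (`repr`
round-trip). The XML element vocabulary is defined by this package and
round-trip tested (write → read reproduces every numeric field); the TSV
family mirrors the classic meta-analysis layout: per-locus summary, allele,
genotype and Hardy-Weinberg files, pairwise files with D′/Wn/ALD columns,
and n-locus files (named `3-locus-haplo.tsv`, `5-locus-haplo.tsv`, ... as
needed) without pairwise statistics. Files are emitted only when data
exist; undefined values are `NA`; permutation columns appear only when a
permutation test ran. Workshop-style metadata columns (region, ethnicity,
collection site, taken from `.pop` metadata) are off by default
(`--enable-ihwg`). All randomness derives per-analysis seeds from one
master seed via a stable tag hash, so a rerun with the same inputs and seed
is byte-identical.

## Problem sizes used in the validation suite

The shipped tests and the acceptance script run at desk scale, chosen to
exercise every code path while keeping the whole suite fast: exact-test
oracle comparisons on allele-count configurations up to n = 12, k = 4
(where enumeration is trivially checkable), Ewens–Watterson cases up to
n = 50, k = 6, EM recovery at 2n = 2000 over 20 seeds, and permutation
calibration with 200 replicates × 200 permutations at n = 50. These sizes
make the binomial/KS tolerances meaningful; the methods themselves scale
well beyond them.

## Known limitations

* The exact HWE test enumerates genotype tables; for many alleles at large
  n only the Monte-Carlo route is practical.
* The EM retains the full resolution set per individual, hence the 8-locus
  cap; no partial-phasing imputation for individuals missing a subset of
  the requested loci.
* Phase-known haplotype counting and LD are not implemented.
* ALD variance/confidence intervals are not computed; inference is by
  permutation only.
* Allele names are not validated against any nomenclature database, and
  curated community binning tables (G/P-groups, supertypes, TCE, NMDP) are
  not bundled — only the binning mechanism is provided.
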