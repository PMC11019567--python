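# popkit

Population-genetics analyses for highly polymorphic, multi-locus genotype
data — the regime typified by the HLA genes of the human MHC, where a single
locus can carry dozens of alleles in one sample and standard biallelic
tooling does not apply.

Given plaintext population genotype files (`.pop`) and an INI configuration,
popkit computes, per population:

* **Hardy-Weinberg conformity**: a chi-square goodness-of-fit test with
  classical lumping of rare genotype classes, and the conditional exact test
  based on the table probability
  P(table) = n! ∏ᵢcᵢ! 2ᴴ / ((2n)! ∏ᵢ≤ⱼ nᵢⱼ!), by full enumeration when
  feasible and otherwise by Monte-Carlo gamete shuffling, with heterozygote
  excess/deficit tail tests;
* **Ewens–Watterson neutrality tests**: observed homozygosity F = Σpᵢ²
  against its null distribution under the Ewens sampling formula conditional
  on (n, k), by partition enumeration or a conditional Hoppe-urn sampler;
* **haplotype frequencies** for 2..8 loci by EM over all phase-consistent
  resolutions of each unphased multi-locus genotype;
* **pairwise linkage disequilibrium**: haplotype-level Dᵢⱼ = hᵢⱼ − pᵢqⱼ and
  D′ᵢⱼ, the frequency-weighted overall D′, the multiallelic correlation
  Wn = √(Σᵢⱼ Dᵢⱼ²/(pᵢqⱼ) / min(I−1, J−1)), and the **asymmetric LD (ALD)**
  pair W12 = √((F₁|₂ − F₁)/(1 − F₁)) and W21 (conditional vs unconditional
  homozygosity), which both reduce to |r| for SNPs but expose directionality
  when allele numbers differ; significance by a genotype-permutation test;
* **reports**: one machine-readable XML and one human-readable text report
  per population, and a cross-population TSV family (1-locus-summary,
  1-locus-allele, ..., *n*-locus-haplo) generated dynamically from whatever
  analyses were actually requested.

Modern colon-delimited allele names (`A*02:01:01:134Q`) pass through
untouched, haplotypes are printed in GL String style (`A*01:01~B*08:01`),
and a `[CustomBinning]` config section can collapse alleles into
user-defined groups (G/P-groups, supertypes, TCE groups, NMDP codes, ...)
before analysis. A synthetic-data module generates `.pop` datasets with
known haplotype frequencies, inbreeding-like HWE deviation and missing data,
so every statistic can be validated against ground truth.

## A worked example

```python
import numpy as np
from popkit import ld_coefficients, dprime_overall, wn_overall, ald_pair

# two loci: 2 alleles (0.5/0.5) x 3 alleles (0.4/0.3/0.3)
h = np.array([[0.40, 0.10, 0.00],
              [0.00, 0.20, 0.30]])
p, q = h.sum(axis=1), h.sum(axis=0)
d, dp = ld_coefficients(h)
print(round(dprime_overall(dp, p, q), 4))   # 0.8
print(round(wn_overall(d, p, q), 4))        # 0.8563
print([round(w, 4) for w in ald_pair(h)])   # [0.8563, 0.6276]
```

`D′ = 0.8` and `Wn = 0.8563` summarize overall LD symmetrically; the ALD
pair shows the asymmetry the symmetric measures hide — the three-allele
locus predicts the two-allele locus better (W12 = 0.8563) than the reverse
(W21 = 0.6276).

From the shell, the same pipeline runs end to end:

```bash
popkit simulate -c sim.ini -o pop1.pop           # synthetic dataset
popkit analyze -c analysis.ini --enable-tsv \
       --outputdir out --seed 7 pop1.pop pop2.pop
popkit meta --outputdir tsv out/*-out.xml        # cross-population TSVs
```

Each `.pop` input yields `X-out.xml` and `X-out.txt`; the aggregation step
writes only the TSV files for which data exist (e.g. `5-locus-haplo.tsv`
appears only if 5-locus haplotypes were estimated, and the `# permu` /
`p-value` columns only if a permutation test was run).

The `examples/` directory contains one short narrative script per
capability (`ld_ald_measures.py`, `hardy_weinberg_tests.py`,
`ewens_watterson_test.py`, `haplotype_estimation.py`, `full_pipeline.py`).

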