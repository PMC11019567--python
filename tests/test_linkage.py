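import math

import numpy as np
import pytest

from popkit.linkage import (
    MarginalMismatchError,
    ald_pair,
    compute_ld,
    dprime_overall,
    ld_coefficients,
    ld_permutation_test,
    wn_overall,
)
from popkit.simulate import SimulationSpec, sample_population

from conftest import random_haplotype_table

# hand-worked 2x3 table: p = (0.5, 0.5), q = (0.4, 0.3, 0.3)
H23 = np.array([[0.4, 0.1, 0.0], [0.0, 0.2, 0.3]])
COMPLETE = np.array([[0.5, 0.0], [0.0, 0.5]])


def brute_force_ald(h):
    """Independent evaluation of the conditional-homozygosity formulas."""
    h = np.asarray(h, float)
    p = h.sum(axis=1)
    q = h.sum(axis=0)
    f1 = sum(x * x for x in p)
    f2 = sum(x * x for x in q)
    f1_given_2 = sum(
        h[i, j] ** 2 / q[j] for i in range(h.shape[0]) for j in range(h.shape[1]) if q[j] > 0
    )
    f2_given_1 = sum(
        h[i, j] ** 2 / p[i] for i in range(h.shape[0]) for j in range(h.shape[1]) if p[i] > 0
    )
    w12 = None if f1 >= 1 else math.sqrt(max((f1_given_2 - f1) / (1 - f1), 0.0))
    w21 = None if f2 >= 1 else math.sqrt(max((f2_given_1 - f2) / (1 - f2), 0.0))
    return w12, w21


def snp_r(h):
    """|r| for a 2x2 haplotype table."""
    p = h.sum(axis=1)
    q = h.sum(axis=0)
    d = h[0, 0] - p[0] * q[0]
    return abs(d) / math.sqrt(p[0] * p[1] * q[0] * q[1])


class TestCoefficients:
    def test_complete_ld_biallelic(self):
        d, dp = ld_coefficients(COMPLETE)
        assert d[0, 0] == pytest.approx(0.25)
        assert dp[0, 0] == pytest.approx(1.0)

    def test_independence_gives_zero(self):
        p = np.array([0.6, 0.4])
        q = np.array([0.2, 0.3, 0.5])
        d, dp = ld_coefficients(np.outer(p, q))
        assert np.allclose(d, 0.0, atol=1e-15)
        assert np.allclose(dp, 0.0)

    def test_hand_worked_2x3_values(self):
        d, dp = ld_coefficients(H23)
        assert d[0, 0] == pytest.approx(0.2)
        assert dp[0, 0] == pytest.approx(1.0)
        assert d[0, 1] == pytest.approx(-0.05)
        assert abs(dp[0, 1]) == pytest.approx(1 / 3)

    def test_d_sums_to_zero(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            h = random_haplotype_table(rng, rng.integers(2, 6), rng.integers(2, 6))
            d, _ = ld_coefficients(h)
            assert abs(d.sum()) < 1e-10

    def test_marginal_inconsistency_rejected(self):
        with pytest.raises(MarginalMismatchError):
            ld_coefficients(H23, p=np.array([0.7, 0.3]))


class TestOverallSummaries:
    def test_dprime_limits(self):
        d, dp = ld_coefficients(COMPLETE)
        assert dprime_overall(dp, *_margins(COMPLETE)) == pytest.approx(1.0)
        indep = np.outer([0.5, 0.5], [0.4, 0.6])
        d, dp = ld_coefficients(indep)
        assert dprime_overall(dp, *_margins(indep)) == pytest.approx(0.0)

    def test_hand_worked_dprime(self):
        _, dp = ld_coefficients(H23)
        assert dprime_overall(dp, *_margins(H23)) == pytest.approx(0.8)

    def test_hand_worked_wn(self):
        d, _ = ld_coefficients(H23)
        assert wn_overall(d, *_margins(H23)) == pytest.approx(math.sqrt(0.7333333333333333))

    def test_wn_equals_r_for_biallelic(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            h = random_haplotype_table(rng, 2, 2)
            d, _ = ld_coefficients(h)
            assert wn_overall(d, *_margins(h)) == pytest.approx(snp_r(h), abs=1e-12)

    def test_monomorphic_wn_undefined(self):
        h = np.array([[0.6], [0.4]])
        d = h - np.outer(h.sum(1), h.sum(0))
        assert wn_overall(d, h.sum(1), h.sum(0)) is None

    def test_all_measures_in_unit_interval(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            h = random_haplotype_table(rng, rng.integers(2, 5), rng.integers(2, 5))
            d, dp = ld_coefficients(h)
            p, q = _margins(h)
            assert 0.0 <= dprime_overall(dp, p, q) <= 1.0 + 1e-12
            assert 0.0 <= wn_overall(d, p, q) <= 1.0 + 1e-12
            w12, w21 = ald_pair(h)
            assert 0.0 <= w12 <= 1.0 + 1e-12
            assert 0.0 <= w21 <= 1.0 + 1e-12


def _margins(h):
    return h.sum(axis=1), h.sum(axis=0)


class TestALD:
    def test_independence_gives_zero(self):
        h = np.outer([0.6, 0.4], [0.2, 0.3, 0.5])
        w12, w21 = ald_pair(h)
        assert w12 == pytest.approx(0.0, abs=1e-12)
        assert w21 == pytest.approx(0.0, abs=1e-12)

    def test_complete_determination_gives_one(self):
        w12, w21 = ald_pair(COMPLETE)
        assert w12 == pytest.approx(1.0)
        assert w21 == pytest.approx(1.0)

    def test_hand_worked_asymmetry(self):
        w12, w21 = ald_pair(H23)
        assert w12 == pytest.approx(math.sqrt(0.7333333333333333))  # ~0.8563
        assert w21 == pytest.approx(math.sqrt(0.26 / 0.66))  # ~0.6276
        assert w12 != pytest.approx(w21)

    def test_snp_equivalence_thousand_tables(self):
        # for biallelic x biallelic tables both ALD directions equal |r|
        rng = np.random.default_rng(3)
        worst = 0.0
        for _ in range(1000):
            h = random_haplotype_table(rng, 2, 2)
            w12, w21 = ald_pair(h)
            r = snp_r(h)
            worst = max(worst, abs(w12 - r), abs(w21 - r))
        assert worst < 1e-10

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            h = random_haplotype_table(rng, rng.integers(2, 6), rng.integers(2, 6))
            w12, w21 = ald_pair(h)
            b12, b21 = brute_force_ald(h)
            assert abs(w12 - b12) < 1e-12
            assert abs(w21 - b21) < 1e-12

    def test_symmetric_square_table_has_no_asymmetry(self):
        rng = np.random.default_rng(5)
        h = random_haplotype_table(rng, 3, 3)
        h = (h + h.T) / 2
        h /= h.sum()
        w12, w21 = ald_pair(h)
        assert w12 == pytest.approx(w21, abs=1e-12)

    def test_monomorphic_locus_undefined(self):
        h = np.array([[0.6], [0.4]])  # locus 2 monomorphic
        w12, w21 = ald_pair(h)
        assert w12 == pytest.approx(0.0, abs=1e-9)  # conditioning on constant changes nothing
        assert w21 is None


class TestPermutationTest:
    def _associated_dataset(self, n=100, seed=0):
        spec = SimulationSpec(
            loci=("A", "B"),
            n_individuals=n,
            haplotype_freqs={("x", "u"): 0.5, ("y", "v"): 0.5},
            seed=seed,
        )
        return sample_population(spec)[0]

    def test_no_permutations_requested_means_no_record(self):
        ds = self._associated_dataset()
        result = compute_ld(ds, "A", "B", n_permutations=0)
        assert result.permutation is None

    def test_perfect_association_minimal_p(self):
        ds = self._associated_dataset(n=100, seed=1)
        rec = ld_permutation_test(ds, "A", "B", n_permutations=200, seed=2)
        assert rec.observed == pytest.approx(1.0)
        assert rec.p_value == pytest.approx(1 / 201)

    def test_seed_reproducibility(self):
        spec = SimulationSpec(
            loci=("A", "B"),
            n_individuals=60,
            allele_freqs=[{"x": 0.5, "y": 0.5}, {"u": 0.5, "v": 0.5}],
            seed=4,
        )
        ds, _ = sample_population(spec)
        a = ld_permutation_test(ds, "A", "B", n_permutations=100, seed=9)
        b = ld_permutation_test(ds, "A", "B", n_permutations=100, seed=9)
        assert a.p_value == b.p_value and a.observed == b.observed


def test_compute_ld_end_to_end_matches_direct_formulas():
    spec = SimulationSpec(
        loci=("A", "B"),
        n_individuals=150,
        allele_freqs=[
            {"01:01": 0.5, "02:01": 0.3, "03:01": 0.2},
            {"01:01": 0.6, "02:01": 0.4},
        ],
        seed=8,
    )
    ds, _ = sample_population(spec)
    result = compute_ld(ds, "A", "B")
    # rebuild the haplotype table from D and the stored marginals, then
    # re-derive every summary through the independent brute-force oracle
    h = result.d + np.outer(result.p, result.q)
    assert abs(result.d.sum()) < 1e-10
    b12, b21 = brute_force_ald(h)
    assert result.ald_1_2 == pytest.approx(b12, abs=1e-12)
    assert result.ald_2_1 == pytest.approx(b21, abs=1e-12)
    d, dp = ld_coefficients(h)
    assert result.dprime == pytest.approx(dprime_overall(dp, result.p, result.q))
    assert result.wn == pytest.approx(wn_overall(d, result.p, result.q))
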