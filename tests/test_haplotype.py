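import io

import numpy as np
import pytest

from popkit.dataio import parse_pop_file
from popkit.haplotype import em_estimate, enumerate_resolutions, estimate_haplotypes
from popkit.simulate import SimulationSpec, sample_population


def _parse(text):
    return parse_pop_file(io.StringIO(text))


UNAMBIGUOUS = """\
name: clean
A_1\tA_2\tB_1\tB_2
A\tA\tB\tB
A\tA\tB\tB
A\tA\tB\tB
a\ta\tb\tb
"""

DOUBLE_HET = "A_1\tA_2\tB_1\tB_2\nA\ta\tB\tb\n"


class TestResolutions:
    def test_fully_homozygous_single_resolution(self):
        res = enumerate_resolutions(_parse(UNAMBIGUOUS), ("A", "B"))
        assert all(np.diff(res.offsets) == 1)

    def test_double_heterozygote_two_resolutions(self):
        res = enumerate_resolutions(_parse(DOUBLE_HET), ("A", "B"))
        assert res.offsets.tolist() == [0, 2]
        pairs = {
            (res.haplotypes[h1], res.haplotypes[h2])
            for h1, h2 in zip(res.pair_h1, res.pair_h2)
        }
        assert {frozenset(p) for p in pairs} == {
            frozenset({("A", "B"), ("a", "b")}),
            frozenset({("A", "b"), ("a", "B")}),
        }

    def test_triple_heterozygote_four_resolutions(self):
        text = "A_1\tA_2\tB_1\tB_2\tC_1\tC_2\nA\ta\tB\tb\tC\tc\n"
        res = enumerate_resolutions(_parse(text), ("A", "B", "C"))
        assert res.offsets.tolist() == [0, 4]

    def test_listwise_deletion_counted(self):
        text = UNAMBIGUOUS.replace("a\ta\tb\tb", "a\ta\t****\tb")
        res = enumerate_resolutions(_parse(text), ("A", "B"))
        assert res.n_individuals == 3
        assert res.n_excluded == 1

    def test_no_complete_individuals_is_an_error(self):
        text = "A_1\tA_2\tB_1\tB_2\nA\tA\t****\t****\n"
        with pytest.raises(ValueError, match="no individuals"):
            enumerate_resolutions(_parse(text), ("A", "B"))

    def test_locus_count_cap(self):
        loci = tuple(f"L{i}" for i in range(9))
        header = "\t".join(f"{l}_{j}" for l in loci for j in (1, 2))
        row = "\t".join("A" for _ in range(18))
        with pytest.raises(ValueError, match="cap"):
            enumerate_resolutions(_parse(header + "\n" + row + "\n"), loci)


class TestEM:
    def test_unambiguous_data_reduces_to_counting(self):
        est = estimate_haplotypes(_parse(UNAMBIGUOUS), ("A", "B"))
        assert est.freqs == {"A~B": pytest.approx(0.75), "a~b": pytest.approx(0.25)}
        assert est.converged and est.n_iterations <= 2

    def test_single_double_het_symmetric_fixed_point(self):
        est = estimate_haplotypes(_parse(DOUBLE_HET), ("A", "B"))
        assert est.freqs == {
            name: pytest.approx(0.25)
            for name in ("A~B", "A~b", "a~B", "a~b")
        }

    def test_frequencies_sum_to_one(self):
        est = estimate_haplotypes(_parse(UNAMBIGUOUS), ("A", "B"))
        assert est.frequencies.sum() == pytest.approx(1.0, abs=1e-10)

    def test_loglik_nondecreasing_over_iterations(self):
        spec = SimulationSpec(
            loci=("A", "B"),
            n_individuals=60,
            allele_freqs=[
                {"01:01": 0.5, "02:01": 0.5},
                {"01:01": 0.4, "02:01": 0.35, "03:01": 0.25},
            ],
            seed=5,
        )
        dataset, _ = sample_population(spec)
        res = enumerate_resolutions(dataset, ("A", "B"))
        # identical deterministic start, increasing iteration budgets
        logliks = [
            em_estimate(res, tol=0.0, max_iter=i).loglik for i in range(1, 25)
        ]
        diffs = np.diff(logliks)
        assert np.all(diffs >= -1e-9)

    def test_order_invariance(self):
        spec = SimulationSpec(
            loci=("A", "B"),
            n_individuals=80,
            allele_freqs=[{"x": 0.6, "y": 0.4}, {"u": 0.7, "v": 0.3}],
            seed=6,
        )
        dataset, _ = sample_population(spec)
        est1 = estimate_haplotypes(dataset, ("A", "B"))
        reversed_ds = dataset.__class__(
            metadata=dataset.metadata,
            loci=dataset.loci,
            individuals=dataset.individuals[::-1],
        )
        est2 = estimate_haplotypes(reversed_ds, ("A", "B"))
        for name, f in est1.freqs.items():
            assert est2.freqs[name] == pytest.approx(f, abs=1e-6)

    def test_parameter_recovery_two_locus(self):
        hap_freqs = {
            ("01:01", "01:01"): 0.35,
            ("01:01", "02:01"): 0.10,
            ("01:01", "03:01"): 0.05,
            ("02:01", "01:01"): 0.05,
            ("02:01", "02:01"): 0.25,
            ("02:01", "03:01"): 0.20,
        }
        spec = SimulationSpec(
            loci=("A", "B"), n_individuals=1000, haplotype_freqs=hap_freqs, seed=99
        )
        dataset, truth = sample_population(spec)
        est = estimate_haplotypes(dataset, ("A", "B"))
        errors = [
            est.freqs.get("~".join(h), 0.0) - f for h, f in hap_freqs.items()
        ]
        rmse = float(np.sqrt(np.mean(np.square(errors))))
        assert rmse < 0.02

    def test_restarts_reproducible_under_seed(self):
        ds = _parse(DOUBLE_HET + "A\ta\tB\tb\nA\tA\tB\tb\n")
        res = enumerate_resolutions(ds, ("A", "B"))
        a = em_estimate(res, n_restarts=4, seed=3)
        b = em_estimate(res, n_restarts=4, seed=3)
        assert np.allclose(a.frequencies, b.frequencies)
        assert a.loglik == b.loglik
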