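import io

import numpy as np
import pytest

from popkit import SimulationSpec, parse_pop_file, sample_population

TWO_LOCUS_POP = """\
name: demo
region: testland
A_1\tA_2\tB_1\tB_2
01:01\t01:01\t02:01\t02:01
01:01\t02:01\t02:01\t03:01
02:01\t02:01\t03:01\t03:01
"""


@pytest.fixture
def two_locus_dataset():
    return parse_pop_file(io.StringIO(TWO_LOCUS_POP))


@pytest.fixture
def hwe_population():
    """400 individuals, 2 loci in HWE, haplotype-level random union of gametes."""
    spec = SimulationSpec(
        loci=("A", "B"),
        n_individuals=400,
        allele_freqs=[
            {"01:01": 0.5, "02:01": 0.3, "03:01": 0.2},
            {"01:01": 0.6, "02:01": 0.4},
        ],
        seed=12345,
    )
    return sample_population(spec)


def random_haplotype_table(rng: np.random.Generator, I: int, J: int) -> np.ndarray:
    """A strictly positive I x J haplotype frequency table summing to 1."""
    h = rng.dirichlet(np.ones(I * J)).reshape(I, J) + 1e-6
    return h / h.sum()
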