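import numpy as np
import pytest
from hypothesis import settings

from candgene.synthpop import SimConfig, simulate_dataset

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


# Printed summary tables of the Dabieshan cattle GDF8 study; these are
# published inputs the pipeline is checked against.
TABLE3 = {
    # locus: (genotype freqs (ref-hom, het, alt-hom), allele freqs, chi2, p, Ho, He, Ne, PIC)
    "g.244C>G": ((0.12, 0.42, 0.46), (0.33, 0.67), 0.29, 0.867, 0.560, 0.440, 1.786, 0.343),
    "g.400G>A": ((0.10, 0.43, 0.47), (0.32, 0.68), 0.06, 0.972, 0.575, 0.425, 1.738, 0.335),
    "g.5070C>A": ((0.44, 0.36, 0.20), (0.62, 0.38), 13.46, 0.001, 0.528, 0.472, 1.892, 0.360),
    "g.5076T>C": ((0.50, 0.34, 0.16), (0.67, 0.33), 13.91, 0.001, 0.557, 0.443, 1.795, 0.345),
    "g.5148A>C": ((0.46, 0.38, 0.16), (0.65, 0.35), 6.00, 0.051, 0.544, 0.456, 1.837, 0.352),
}

TABLE4 = {
    # (locus_a, locus_b): (D', r2)
    ("g.244C>G", "g.400G>A"): (0.943, 0.206),
    ("g.244C>G", "g.5070C>A"): (0.780, 0.191),
    ("g.244C>G", "g.5076T>C"): (0.835, 0.175),
    ("g.244C>G", "g.5148A>C"): (0.815, 0.188),
    ("g.400G>A", "g.5070C>A"): (0.372, 0.038),
    ("g.400G>A", "g.5076T>C"): (0.533, 0.062),
    ("g.400G>A", "g.5148A>C"): (0.572, 0.081),
    ("g.5070C>A", "g.5076T>C"): (0.966, 0.748),
    ("g.5070C>A", "g.5148A>C"): (0.917, 0.758),
    ("g.5076T>C", "g.5148A>C"): (0.959, 0.843),
}

TABLE5 = {
    "CACTA": 0.315,
    "GAACC": 0.238,
    "GGCTA": 0.235,
    "GACTA": 0.058,
    "GGACC": 0.052,
}


@pytest.fixture(scope="session")
def default_dataset():
    """One simulated 380-head herd shared by read-only tests."""
    return simulate_dataset(SimConfig(seed=2024))


@pytest.fixture(scope="session")
def default_genotypes(default_dataset):
    return default_dataset[0].genotypes


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
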