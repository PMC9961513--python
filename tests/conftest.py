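import numpy as np
import pytest

from seedhsi.simulate import Group, SimSpec, make_hypercube, make_spectra


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def two_blob_cube():
    """Noise-free cube with two seed objects and its ground truth (seed 1)."""
    spec = SimSpec(
        groups=(Group(1, "E+", "Trojan", "b1"), Group(1, "E-", "Trojan", "b1")),
        signals={"E+": [(10, 0.02)]},
        n_bands=32,
        rng_seed=1,
    )
    return make_hypercube(spec)


@pytest.fixture(scope="session")
def small_table():
    """Noisy 40-row two-class spectra table for model tests."""
    spec = SimSpec(
        groups=(Group(20, "E+", "Trojan", "b1"), Group(20, "E-", "Trojan", "b1")),
        signals={"E+": [(10, 0.05), (40, 0.04)]},
        scatter_mult=(0.95, 1.05),
        noise_sd=0.004,
        n_bands=64,
        rng_seed=7,
    )
    table, truth = make_spectra(spec)
    return table, truth
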