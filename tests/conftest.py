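import numpy as np
import pytest

from nanodisc.synthetic import ToySpec, planted_benchmark, generate_toy_ensemble


@pytest.fixture(scope="session")
def small_spec():
    """Reduced-size generator settings shared by fast tests."""
    return ToySpec(n_frames=24, n_belt=24, lipid_spacing=11.0, n_carbons=8,
                   n_q=40, noe_count=15, seed=11)


@pytest.fixture(scope="session")
def small_ensemble(small_spec):
    return generate_toy_ensemble(small_spec)


@pytest.fixture(scope="session")
def benchmark():
    """Planted two-cluster benchmark at the reference study conditions."""
    spec = ToySpec(n_frames=80, n_belt=28, lipid_spacing=10.0, n_carbons=10,
                   seed=5)
    return planted_benchmark(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
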