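import numpy as np
import pytest

from nirboost import SimConfig, SpectraSet, simulate
from nirboost.synthetic import Band


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_ds(rng) -> SpectraSet:
    """20 samples x 12 wavelengths with a response, no special structure."""
    wl = np.linspace(1000.0, 1110.0, 12)
    X = rng.normal(size=(20, 12))
    y = rng.uniform(15.0, 28.0, size=20)
    return SpectraSet(wavelengths=wl, X=X, y=y)


@pytest.fixture
def default_sim():
    """Moderate-size draw from the default generative model."""
    ds, truth = simulate(SimConfig(n_samples=120, n_points=200, seed=7))
    return ds, truth


def make_noiseless_config(**overrides) -> SimConfig:
    """Single informative band, zero nuisance: the analytic limit."""
    kwargs = dict(
        n_samples=40,
        n_points=100,
        bands=(Band(center=1450.0, width=60.0, amplitude=1.0, informative=True),),
        baseline_sd=0.0,
        scatter_sd=0.0,
        noise_sd=0.0,
        seed=3,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)
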