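import numpy as np
import pytest

from singleseed import SimulationConfig, simulate_experiment, simulate_poolsplit
from singleseed.normalize import sctransform_like
from singleseed.qc import run_qc


def small_config(rng_seed: int = 7, **overrides) -> SimulationConfig:
    """Scaled-down study conditions shared by the unit tests."""
    kwargs = dict(
        n_genes=1200,
        group1_size=80,
        group2_size=50,
        seeds_per_timepoint=48,
        rng_seed=rng_seed,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def small_experiment():
    adata, truth = simulate_experiment(small_config())
    return adata, truth


@pytest.fixture(scope="session")
def small_filtered(small_experiment):
    adata, truth = small_experiment
    filt, report = run_qc(adata)
    return filt, truth, report


@pytest.fixture(scope="session")
def small_residuals(small_filtered):
    filt, truth, _ = small_filtered
    resid, models = sctransform_like(filt)
    return resid, models, truth


@pytest.fixture(scope="session")
def small_poolsplit():
    return simulate_poolsplit(small_config(), n_aliquots=64, rng_seed=99)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
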