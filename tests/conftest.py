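import numpy as np
import pytest

from dynsort.aggregate import assemble
from dynsort.core import build_grid_geometry
from dynsort.pipeline import PipelineConfig, fit_all_eis
from dynsort.synthetic import gen_amplitude_grid
from dynsort.validation import (
    T_WINDOW,
    _fit_artifact_noiseless,
    make_eis,
    make_neurons,
)


@pytest.fixture(scope="session")
def array6():
    return build_grid_geometry(6, 6, 60.0)


@pytest.fixture(scope="session")
def cfg6():
    return PipelineConfig(artifact_radius=150.0, latency_range=(0, 10))


@pytest.fixture(scope="session")
def eis6(array6):
    specs = make_neurons(array6, 4, seed=0, peak_range=(40.0, 90.0))
    return make_eis(array6, specs, seed=100, T=32)


@pytest.fixture(scope="session")
def ei_fit6(eis6, cfg6):
    return fit_all_eis(eis6, cfg6)


@pytest.fixture(scope="session")
def artifact6(array6, cfg6):
    stim = 14  # interior electrode
    return _fit_artifact_noiseless(
        array6, stim, cfg6, gen_amplitude_grid(6, 0.1, 1.0), T=T_WINDOW
    )


@pytest.fixture(scope="session")
def agg6(ei_fit6, artifact6, array6):
    return assemble(ei_fit6.models, artifact6, array6.n_electrodes)


@pytest.fixture(scope="session")
def u_a6(artifact6):
    return 1.0 * artifact6.template.shifted(0, T_WINDOW)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
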