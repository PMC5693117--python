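import numpy as np
import pytest

from samdyn import ModelParameters, ModelState


@pytest.fixture(scope="session")
def wt_params() -> ModelParameters:
    """Calibrated wild-type parameters."""
    return ModelParameters()


@pytest.fixture()
def wt_init() -> ModelState:
    """Wild-type homeostatic initial state (per cell layer)."""
    return ModelState(C=40.0, P=160.0)


@pytest.fixture(scope="session")
def wt_run_60d(wt_params):
    """One long calibrated wild-type run, shared across read-only tests."""
    from samdyn import simulate
    return simulate(wt_params, t_end=60 * 24.0, dt_out=24.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
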