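import numpy as np
import pytest

from txcascade.circuits import registry, training_ids, test_ids
from txcascade.params import default_parameters, with_weak_tet
from txcascade.simulate import GenerationSpec, generate_dose_response


@pytest.fixture(scope="session")
def reg():
    return registry()


@pytest.fixture(scope="session")
def nbm_params():
    return with_weak_tet(default_parameters("NBM_training"))


@pytest.fixture(scope="session")
def bm_params():
    return with_weak_tet(default_parameters("BM_training"))


@pytest.fixture(scope="session")
def nbm_training_noiseless():
    """Noise-free training-set dose-response data at the packaged truth."""
    spec = GenerationSpec(seed=11, model="NBM", truth_column="NBM_training",
                          circuits=training_ids(), cv=0.0)
    return generate_dose_response(spec)


@pytest.fixture(scope="session")
def nbm_training_noisy():
    spec = GenerationSpec(seed=101, model="NBM", truth_column="NBM_training",
                          circuits=training_ids(), cv=0.10)
    return generate_dose_response(spec)


@pytest.fixture(scope="session")
def bm_training_noiseless():
    spec = GenerationSpec(seed=12, model="BM", truth_column="BM_training",
                          circuits=training_ids(monitor=True) + ["Mon_rg"], cv=0.0)
    return generate_dose_response(spec)


@pytest.fixture(scope="session")
def bm_collection_noisy():
    """Full burden-model collection (plain + monitor + monitor culture), 10% CV."""
    circuits = (
        training_ids() + test_ids()
        + training_ids(monitor=True) + test_ids(monitor=True)
        + ["Mon_rg"]
    )
    spec = GenerationSpec(seed=202, model="BM", truth_column="BM_training",
                          circuits=circuits, cv=0.10)
    return generate_dose_response(spec)


@pytest.fixture(scope="session")
def hsl_grid():
    from txcascade.simulate import default_hsl_grid

    return default_hsl_grid()


@pytest.fixture(scope="session")
def growth_table():
    from txcascade.circuits import build_circuit_collection
    from txcascade.simulate import default_growth_rates

    return default_growth_rates(build_circuit_collection(True, True))


def assert_allclose_rel(actual, expected, rel, msg=""):
    actual, expected = np.asarray(actual, float), np.asarray(expected, float)
    err = np.max(np.abs(actual - expected) / np.maximum(np.abs(expected), 1e-300))
    assert err <= rel, f"{msg} relative error {err:.3g} > {rel}"
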