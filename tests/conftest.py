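import pytest
from hypothesis import settings as hyp_settings

from hfcea import CostEffectivenessModel, load_base_case
from hfcea.deterministic import evaluate
from hfcea.psa import run_psa

hyp_settings.register_profile("ci", derandomize=True, max_examples=50)
hyp_settings.load_profile("ci")


@pytest.fixture(scope="session")
def base_inputs():
    return load_base_case()


@pytest.fixture(scope="session")
def base_model(base_inputs):
    return CostEffectivenessModel(base_inputs)


@pytest.fixture(scope="session")
def base_run(base_inputs):
    """Full-horizon deterministic evaluation of the packaged base case."""
    return evaluate(base_inputs)


@pytest.fixture(scope="session")
def base_run_90(base_inputs):
    return evaluate(base_inputs, horizon_days=90)


@pytest.fixture(scope="session")
def psa_1000(base_inputs):
    """One full-size PSA shared by the convergence and acceptance checks."""
    return run_psa(base_inputs, n=1000, seed=20220101)
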