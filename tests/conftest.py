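import numpy as np
import pytest

from survoi import build_case_dataset, fit_all_families


@pytest.fixture(scope="session")
def increasing_arms():
    """Both arms of the increasing-hazard case study (deterministic)."""
    return build_case_dataset("increasing")


@pytest.fixture(scope="session")
def decreasing_arms():
    return build_case_dataset("decreasing")


@pytest.fixture(scope="session")
def increasing_model_sets(increasing_arms):
    """All four families fitted to both increasing-hazard arms."""
    return tuple(fit_all_families(arm) for arm in increasing_arms)


@pytest.fixture(scope="session")
def decreasing_model_sets(decreasing_arms):
    return tuple(fit_all_families(arm) for arm in decreasing_arms)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
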