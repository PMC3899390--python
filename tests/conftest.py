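import warnings

import pytest

from camobreak.censored import estimate_cells
from camobreak.inference import count_errors
from camobreak.observer import preset_effect_profiles, simulate_experiment


@pytest.fixture(scope="session")
def chromatic_observer():
    return preset_effect_profiles("chromatic_like")


@pytest.fixture(scope="session")
def small_trials(chromatic_observer):
    """10 subjects x 4 blocks under the chromatic-like profile."""
    return simulate_experiment(chromatic_observer, n_subjects=10, master_seed=11)


@pytest.fixture(scope="session")
def small_cells(small_trials):
    return estimate_cells(small_trials)


@pytest.fixture(scope="session")
def small_errors(small_trials):
    return count_errors(small_trials)


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*[Cc]onvergence.*")
        warnings.filterwarnings("ignore", message=".*boundary.*")
        yield
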