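import numpy as np
import pytest

from ra_mtc import datasets, trial_data


@pytest.fixture(scope="session")
def trials():
    return datasets.anti_tnf_trials()


@pytest.fixture(scope="session")
def trials_imputed(trials):
    imputed, _ = trial_data.impute_missing_sd(trials)
    return imputed


@pytest.fixture(scope="session")
def haq_trials(trials_imputed):
    return trial_data.filter_trials(trials_imputed, "haq")


@pytest.fixture(scope="session")
def haq_contrasts(haq_trials):
    return [c for t in haq_trials for c in trial_data.build_contrasts(t, "haq")]


@pytest.fixture(scope="session")
def derived_ref():
    return datasets.derived_outcomes()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
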