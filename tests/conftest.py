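import warnings

import pytest

from voicestroop import default_config, score_cohort, simulate_cohort


@pytest.fixture(autouse=True)
def _quiet_mixedlm():
    """MixedLM boundary warnings on small synthetic fits are expected noise."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", module="statsmodels")
        yield


@pytest.fixture(scope="session")
def small_cohort():
    """A 12+12 participant cohort at default calibration, shared across tests."""
    cfg = default_config(424242)
    cfg.n_nonpatients = 12
    cfg.n_patients = 12
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_scores(small_cohort):
    groups = small_cohort.participants.set_index("participant_id")["group"]
    scores, log = score_cohort(
        small_cohort.schedules_frame(), small_cohort.events_frame(), groups
    )
    return scores, log
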