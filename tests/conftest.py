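import pytest
from hypothesis import settings

import tqtpipe as tq

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


SMALL_DESIGN = tq.TrialDesign(n_per_sequence=(4, 4, 2, 8))


@pytest.fixture(scope="session")
def small_trial() -> tq.SimulatedTrial:
    """An 18-subject trial under the default study conditions."""
    return tq.simulate_default_trial(seed=20, design=SMALL_DESIGN)


@pytest.fixture(scope="session")
def small_dataset(small_trial):
    """C-QTc dataset built from the small trial via the full chain."""
    agg = tq.aggregate_triplicates(small_trial.ecg)
    corr = tq.fit_correction(agg)
    series = tq.baseline_and_delta(agg, corr.exponent)
    return tq.build_cqt_dataset(series, small_trial.pk)


@pytest.fixture(scope="session")
def default_trial() -> tq.SimulatedTrial:
    """One full-size (63-subject) trial under the study conditions."""
    return tq.simulate_default_trial(seed=7)
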