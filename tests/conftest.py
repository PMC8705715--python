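import datetime

import numpy as np
import pytest

from hrvguide.hrv import DailyReading
from hrvguide.simulate import TrialConfig, simulate_trial

START = datetime.date(2021, 3, 1)


def make_readings(scores, participant_id="P1", start=START):
    """Consecutive daily readings with the given hrv_daily scores.

    None entries are missing days (no reading that date).
    """
    out = []
    for i, score in enumerate(scores):
        if score is None:
            continue
        out.append(DailyReading(participant_id, start + datetime.timedelta(days=i),
                                rmssd_ms=float(np.exp(score / 2.0))))
    return out


@pytest.fixture(scope="session")
def small_trial():
    """One simulated trial, shared across read-only tests."""
    return simulate_trial(TrialConfig(n_per_arm=8, seed=20210301))


@pytest.fixture(scope="session")
def null_trial():
    """A trial with no training effect on the daily score."""
    return simulate_trial(TrialConfig.null(n_per_arm=8, seed=4242))
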