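import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from neurotopo import EpochSet, build_gng_schedule, build_pavlovian_schedule

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def pavlovian_schedule():
    return build_pavlovian_schedule(seed=7)


@pytest.fixture(scope="session")
def gng_schedule():
    return build_gng_schedule(seed=5)


@pytest.fixture()
def small_epochs():
    """Ten 4-electrode epochs with metadata covering all selection criteria."""
    rng = np.random.default_rng(11)
    data = rng.normal(0.0, 5.0, size=(10, 4, 20))
    meta = pd.DataFrame({
        "trial_type": ["NoGo", "Go", "NoGo", "NoGo", "Go",
                       "NoGo", "NoGo", "Go", "NoGo", "NoGo"],
        "correct":    [True, True, True, False, False,
                       True, True, True, False, True],
        "liking":     [80, 90, 65, 70, 62, 60, 95, 40, 75, 30],
        "trained_nogo": [True, False, True, True, False,
                         True, False, False, True, True],
    })
    return EpochSet(data, sampling_rate=100.0, onset_index=5, metadata=meta)
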