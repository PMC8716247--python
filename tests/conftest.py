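import numpy as np
import pytest
from hypothesis import settings

import erdkit

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fast_config():
    """Small but fully representative generator config (reduced sampling
    rate/channels/trials keep the suite fast)."""
    return erdkit.GeneratorConfig(
        sampling_rate=250.0, n_channels=4, n_trials_per_condition=12, seed=7
    )


@pytest.fixture(scope="session")
def subject(fast_config):
    return erdkit.generate_subject(fast_config)


@pytest.fixture(scope="session")
def strong_contrast():
    """Two-class set with a -6 dB vs 0 dB ERD contrast: separable by
    construction."""
    cfg = erdkit.GeneratorConfig(
        sampling_rate=250.0,
        n_channels=8,
        n_trials_per_condition=60,
        alpha_peak=10.0,
        beta_peak=19.0,
        seed=3,
        erd_depth_db={
            "deep": {"alpha": -6.0, "beta": -6.0},
            "none": {"alpha": 0.0, "beta": 0.0},
        },
        erd_depth_jitter_shared_db=0.0,
        erd_depth_jitter_cond_db=0.0,
    )
    return erdkit.generate_subject(cfg)


def make_trials(data, fs=250.0, time_origin=0.0, labels=None, channels=None):
    """TrialSet from a raw array, for synthetic-free unit tests."""
    data = np.asarray(data, dtype=float)
    n_trials, n_channels, _ = data.shape
    return erdkit.TrialSet(
        data=data,
        sampling_rate=fs,
        channel_labels=channels or [f"ch{i}" for i in range(n_channels)],
        condition_labels=np.array(labels if labels is not None else ["A"] * n_trials,
                                  dtype=object),
        subject_id="T1",
        time_origin=time_origin,
    )
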