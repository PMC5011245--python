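import numpy as np
import pytest
from hypothesis import settings

from coadapt.preprocessing import (
    RawSegment,
    bandpass,
    car_rereference,
    drop_channel,
    extract_windows,
)
from coadapt.session import SessionConfig
from coadapt.synthetic import SyntheticUser, SyntheticUserSpec

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

RIGHT, LEFT = "right", "left"
FS = 128.0


class ScriptedSource:
    """Deterministic EEG stand-in for session-engine tests.

    Each class drives a different dominant channel with an in-band
    sinusoid, so CSP/SVM decode it perfectly and every decision is
    predictable.  ``fixed_class`` makes the output ignore the requested cue
    (a "stubborn" user that always imagines the same hand).
    """

    sample_rate = FS

    def __init__(self, n_channels: int = 4, fixed_class: str | None = None):
        self.n_channels = n_channels
        self.fixed_class = fixed_class

    def trial(self, cue: str, duration_s: float) -> RawSegment:
        cls = self.fixed_class or cue
        n = int(round(duration_s * FS))
        t = np.arange(n) / FS
        data = np.zeros((self.n_channels + 1, n))  # scalp channels + REF
        for ch in range(self.n_channels + 1):
            # in-band deterministic background, distinct per channel, so the
            # channels stay independent after CAR-with-reference
            data[ch] = 0.2 * np.sin(2 * np.pi * (9.0 + 2.3 * ch) * t + 0.7 * ch)
        dom = 0 if cls == RIGHT else 1
        data[dom] += 2.0 * np.sin(2 * np.pi * 12.0 * t)
        names = [f"CH{c}" for c in range(self.n_channels)] + ["REF"]
        return RawSegment(data=data, sample_rate=FS, channel_names=names)


def preprocess(seg: RawSegment, config: SessionConfig | None = None) -> RawSegment:
    """The engine's preprocessing chain, for direct (non-session) tests."""
    c = config or SessionConfig()
    out = car_rereference(seg)
    if c.reference_channel:
        out = drop_channel(out, c.reference_channel)
    return bandpass(out, c.band_low_hz, c.band_high_hz)


def labeled_windows(spec: SyntheticUserSpec, n_trials: int, trial_s: float = 10.0):
    """Generate n_trials alternating-cue trials, preprocess, and window them."""
    user = SyntheticUser(spec, FS)
    wins = []
    for i in range(n_trials):
        cue = RIGHT if i % 2 == 0 else LEFT
        seg = preprocess(user.trial(cue, trial_s))
        wins.extend(extract_windows(seg, 2.0, 0.5, label=cue, trial_id=i))
    return wins


def windows_to_arrays(wins):
    X = np.stack([w.data for w in wins])
    y = np.array([w.label for w in wins])
    return X, y


@pytest.fixture(scope="session")
def skilled_windows():
    """Separable two-class window batch (deep ERD, moderate noise)."""
    return labeled_windows(SyntheticUserSpec(erd_depth=0.8, seed=42), n_trials=24)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
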