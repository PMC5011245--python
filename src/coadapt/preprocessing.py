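"""Re-referencing, band-pass filtering and sliding-window segmentation.

Continuous multichannel EEG enters the decoder as 2-s "portions" extracted
every 0.5 s from each cue trial.  Before segmentation the signal is
re-referenced to the common average (CAR) and band-pass filtered to the
mu/beta range (8-30 Hz by default), which carries the event-related
desynchronization the spatial filters exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _sig

__all__ = [
    "RawSegment",
    "EegWindow",
    "car_rereference",
    "drop_channel",
    "bandpass",
    "extract_windows",
    "n_windows",
]


@dataclass
class RawSegment:
    """A continuous (channels x samples) chunk of EEG in microvolts.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
    sample_rate : float
        Sampling frequency in Hz.
    channel_names : list of str, optional
    t0 : float
        Time of the first sample, in seconds from trial onset.
    """

    data: np.ndarray
    sample_rate: float
    channel_names: list[str] = field(default_factory=list)
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a (channels x samples) matrix")
        if self.data.shape[1] < 1:
            raise ValueError("segment must contain at least one sample")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.channel_names and len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass
class EegWindow:
    """One classification portion: a (channels x win_samples) slice of a trial.

    ``offset_s`` is the time of the window *end* within the trial, so the
    first 2-s window of a trial has ``offset_s == 2.0``.
    """

    data: np.ndarray
    label: str | None = None
    trial_id: int = 0
    offset_s: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("window data must be a (channels x samples) matrix")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def car_rereference(segment: RawSegment) -> RawSegment:
    """Subtract the instantaneous mean across channels (common average reference).

    The output channel mean is exactly zero at every sample.  The operation
    is linear and idempotent.  Requires at least two channels; CAR of a
    single channel would zero it out and is rejected as a user error.
    """
    if segment.n_channels < 2:
        raise ValueError("common average reference requires at least 2 channels")
    data = segment.data - segment.data.mean(axis=0, keepdims=True)
    return replace(segment, data=data)


def drop_channel(segment: RawSegment, name: str) -> RawSegment:
    """Remove one named channel (e.g. a recorded reference electrode).

    Plain CAR leaves the all-ones vector in the null space of the channel
    covariance, which makes CSP ill-posed.  Recording setups avoid this by
    including the reference electrode's signal in the averaging and then
    analysing only the scalp channels, which stay linearly independent;
    dropping the reference channel *after* :func:`car_rereference`
    reproduces that.  A missing name returns the segment unchanged.
    """
    if not segment.channel_names or name not in segment.channel_names:
        return segment
    idx = segment.channel_names.index(name)
    return RawSegment(
        data=np.delete(segment.data, idx, axis=0),
        sample_rate=segment.sample_rate,
        channel_names=[c for c in segment.channel_names if c != name],
        t0=segment.t0,
    )


def bandpass(
    segment: RawSegment,
    low_hz: float = 8.0,
    high_hz: float = 30.0,
    order: int = 4,
    zero_phase: bool = True,
) -> RawSegment:
    """Band-pass filter each channel with a Butterworth filter.

    Parameters
    ----------
    low_hz, high_hz : float
        Band edges; must satisfy 0 < low < high < Nyquist.
    order : int
        Butterworth order (of the one-pass filter; the zero-phase variant
        applies it forward and backward, doubling the effective order).
    zero_phase : bool
        If True (default) use ``sosfiltfilt`` — appropriate for offline
        analysis and replay.  Set False for a causal forward-only pass when
        simulating strict online operation.
    """
    nyq = segment.sample_rate / 2.0
    if not (0.0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band edges must satisfy 0 < low < high < Nyquist ({nyq} Hz); "
            f"got ({low_hz}, {high_hz})"
        )
    sos = _sig.butter(order, [low_hz, high_hz], btype="bandpass", output="sos", fs=segment.sample_rate)
    if zero_phase:
        data = _sig.sosfiltfilt(sos, segment.data, axis=1)
    else:
        data = _sig.sosfilt(sos, segment.data, axis=1)
    return replace(segment, data=data)


def n_windows(duration_s: float, window_s: float, step_s: float, first_at_s: float | None = None) -> int:
    """Number of windows ending at ``first_at_s, first_at_s + step_s, ...``
    within a trial of ``duration_s`` seconds: ``1 + floor((T - first) / step)``,
    or 0 for trials shorter than the window."""
    if first_at_s is None:
        first_at_s = window_s
    if duration_s < first_at_s - 1e-9:
        return 0
    return 1 + int(np.floor((duration_s - first_at_s) / step_s + 1e-9))


def extract_windows(
    trial: RawSegment,
    window_s: float = 2.0,
    step_s: float = 0.5,
    first_at_s: float | None = None,
    label: str | None = None,
    trial_id: int = 0,
) -> list[EegWindow]:
    """Slice a trial into overlapping classification windows.

    Windows are ``window_s`` long and end at ``first_at_s``,
    ``first_at_s + step_s``, ... up to the trial duration (half-open sample
    alignment ``[end - w, end)``, 0-based indices).  A 10-s trial with 2-s
    windows every 0.5 s yields 17 windows.  Trials shorter than the window
    yield an empty list.
    """
    if step_s <= 0:
        raise ValueError("step_s must be positive")
    if first_at_s is None:
        first_at_s = window_s
    if first_at_s < window_s:
        raise ValueError("first_at_s must be >= window_s")
    win_n = int(round(window_s * trial.sample_rate))
    count = n_windows(trial.duration_s, window_s, step_s, first_at_s)
    out: list[EegWindow] = []
    for k in range(count):
        end_s = first_at_s + k * step_s
        end_i = int(round(end_s * trial.sample_rate))
        out.append(
            EegWindow(
                data=trial.data[:, end_i - win_n : end_i],
                label=label,
                trial_id=trial_id,
                offset_s=end_s,
            )
        )
    return out
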