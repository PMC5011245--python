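"""Synthetic two-class motor-imagery EEG and a simulated closed-loop user.

The generator emulates the physiology the decoder exploits: band-limited mu
(~10 Hz) and beta (~20 Hz) oscillations from two lateralized sensorimotor
sources (C3-like and C4-like), mixed to an 11-channel montage, with
class-dependent *contralateral* amplitude attenuation (ERD) of tunable
depth.  Right-hand imagery attenuates the left-hemisphere source and vice
versa.  Spatially correlated 1/f background noise, slow nonstationarity
(topography drift), within-session "learning" (growing ERD depth) and
optional broadband artifact bursts are available to stress the adaptive
pipeline.

Everything is deterministic given the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
from scipy import signal as _sig

from .csp import LEFT, RIGHT
from .preprocessing import RawSegment

__all__ = ["SyntheticUserSpec", "ArtifactSpec", "SyntheticUser", "generate_trial", "simulate_closed_loop"]


@dataclass
class ArtifactSpec:
    """Broadband high-frequency bursts (muscle-artifact-like)."""

    duration_s: float = 0.3
    amplitude: float = 10.0  # multiple of the rhythm RMS
    low_hz: float = 20.0
    high_hz: float = 60.0


@dataclass
class SyntheticUserSpec:
    """Parameters of the simulated EEG source / user.

    erd_depth
        Fractional amplitude attenuation of the contralateral SMR source
        during imagery, in [0, 1].  0 makes the classes indistinguishable;
        0.8 is an easily decodable "skilled" user.
    noise_level
        Background-to-rhythm channel power ratio (1.0 = equal power).
    drift
        Lateral migration of the SMR source topographies, in channel-index
        units per trial — a slow spatial nonstationarity.
    learning_rate
        Additive increase of erd_depth per completed U repetition,
        emulating a user that improves with feedback training.
    artifact_rate
        Expected artifact bursts per minute (Poisson).
    """

    n_channels: int = 11
    erd_depth: float = 0.5
    mu_hz: float = 10.0
    beta_hz: float = 20.0
    mu_amp: float = 1.0
    beta_amp: float = 0.6
    noise_level: float = 1.0
    sensor_noise: float = 0.05  # per-channel white noise power, relative to rhythm power
    envelope_tau_s: float = 3.0  # correlation time of the slow rhythm amplitude envelope
    envelope_depth: float = 0.5  # log-amplitude sd of the envelope (0 = stationary rhythm)
    trial_gain_sd: float = 0.5  # per-trial log-normal amplitude gain sd of each SMR source
    drift: float = 0.0
    learning_rate: float = 0.0
    artifact_rate: float = 0.0
    artifact: ArtifactSpec | None = None
    include_reference: bool = True  # append an ear-reference-like channel "REF"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValueError("erd_depth must be in [0, 1]")
        if self.noise_level < 0:
            raise ValueError("noise_level must be non-negative")
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")


def _gauss_topo(n_channels: int, center: float, width: float = 1.2) -> np.ndarray:
    """Smooth unimodal topography over the channel axis, unit norm."""
    x = np.arange(n_channels, dtype=float)
    t = np.exp(-0.5 * ((x - center) / width) ** 2)
    return t / np.linalg.norm(t)


def _narrowband(rng: np.random.Generator, n: int, fs: float, lo: float, hi: float) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise (order-4 Butterworth)."""
    x = rng.standard_normal(n + int(2 * fs))  # pad to wash out filter transient
    sos = _sig.butter(4, [lo, hi], btype="bandpass", output="sos", fs=fs)
    y = _sig.sosfilt(sos, x)[int(2 * fs) :]
    s = y.std()
    return y / s if s > 0 else y


def _pink(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f-shaped noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec /= np.sqrt(f)
    y = np.fft.irfft(spec, n)
    s = y.std()
    return y / s if s > 0 else y


class SyntheticUser:
    """Stateful simulated user: an on-demand source of labeled EEG trials.

    Holds its own RNG (seeded from the spec), a trial counter that drives
    topography drift, and a current ERD depth that grows with
    ``advance_learning`` when a learning rate is configured.
    """

    def __init__(self, spec: SyntheticUserSpec, sample_rate: float = 128.0) -> None:
        self.spec = spec
        self.sample_rate = float(sample_rate)
        self.rng = np.random.default_rng(spec.seed)
        self.trial_count = 0
        self.erd_depth = spec.erd_depth
        n = spec.n_channels
        # fixed smooth background topographies (part of the "head", not the trial)
        bg_rng = np.random.default_rng(spec.seed + 1)
        self._bg_topos = []
        for _ in range(4):
            v = bg_rng.standard_normal(n)
            v = np.convolve(v, np.ones(3) / 3.0, mode="same")
            self._bg_topos.append(v / np.linalg.norm(v))
        self._base_left_center = 0.25 * (n - 1)   # C3-like, left hemisphere
        self._base_right_center = 0.75 * (n - 1)  # C4-like, right hemisphere

    # -- topographies ------------------------------------------------------
    def smr_topographies(self) -> tuple[np.ndarray, np.ndarray]:
        """Current (drifted) left- and right-hemisphere source topographies."""
        n = self.spec.n_channels
        shift = self.spec.drift * self.trial_count
        left = _gauss_topo(n, self._base_left_center + shift)
        right = _gauss_topo(n, self._base_right_center + shift)
        return left, right

    # -- generation --------------------------------------------------------
    def trial(self, cue: str, duration_s: float) -> RawSegment:
        """One labeled cue trial of raw (unfiltered, un-referenced) EEG."""
        seg = generate_trial(
            _dc_replace(self.spec, erd_depth=self.erd_depth),
            cue,
            duration_s,
            self.sample_rate,
            rng=self.rng,
            trial_index=self.trial_count,
            topographies=self.smr_topographies(),
            bg_topographies=self._bg_topos,
        )
        self.trial_count += 1
        return seg

    def advance_learning(self) -> None:
        """Hook called after each completed U repetition."""
        if self.spec.learning_rate:
            self.erd_depth = float(min(1.0, self.erd_depth + self.spec.learning_rate))


def generate_trial(
    spec: SyntheticUserSpec,
    cue: str,
    duration_s: float,
    sample_rate: float = 128.0,
    rng: np.random.Generator | None = None,
    trial_index: int = 0,
    topographies: tuple[np.ndarray, np.ndarray] | None = None,
    bg_topographies: list[np.ndarray] | None = None,
) -> RawSegment:
    """Generate one cue trial of synthetic multichannel EEG.

    The signal is the sum of (i) two lateralized SMR sources (mu + beta
    narrowband noise), with the source contralateral to ``cue`` attenuated
    by ``erd_depth``; (ii) spatially mixed pink background noise scaled to
    ``noise_level`` relative to the *unattenuated* rhythm power, so the
    background carries no class information; and (iii) optional broadband
    artifact bursts.
    """
    if cue not in (RIGHT, LEFT):
        raise ValueError(f"cue must be {RIGHT!r} or {LEFT!r}")
    if rng is None:
        rng = np.random.default_rng(spec.seed + 104729 * trial_index)
    fs = float(sample_rate)
    n = int(round(duration_s * fs))
    nch = spec.n_channels
    if topographies is None:
        shift = spec.drift * trial_index
        topographies = (
            _gauss_topo(nch, 0.25 * (nch - 1) + shift),
            _gauss_topo(nch, 0.75 * (nch - 1) + shift),
        )
    topo_left_hemi, topo_right_hemi = topographies

    def envelope() -> np.ndarray:
        # waxing/waning of the rhythm: log-normal amplitude with ~tau_s
        # correlation time, so nearby windows of a trial share their power
        if spec.envelope_depth <= 0 or spec.envelope_tau_s <= 0:
            return np.ones(n)
        cutoff = min(1.0 / spec.envelope_tau_s, 0.45 * fs)
        sos = _sig.butter(2, cutoff, btype="lowpass", output="sos", fs=fs)
        pad = int(4 * spec.envelope_tau_s * fs)
        z = _sig.sosfilt(sos, rng.standard_normal(n + pad))[pad:]
        s = z.std()
        if s > 0:
            z /= s
        return np.exp(spec.envelope_depth * z - 0.5 * spec.envelope_depth**2)

    def smr_source() -> np.ndarray:
        # trial-to-trial SMR power variability: each source draws one
        # log-normal gain per trial, so windows of a trial share their fate
        gain = np.exp(spec.trial_gain_sd * rng.standard_normal() - 0.5 * spec.trial_gain_sd**2)
        mu = spec.mu_amp * _narrowband(rng, n, fs, spec.mu_hz - 1.5, spec.mu_hz + 1.5)
        beta = spec.beta_amp * _narrowband(rng, n, fs, spec.beta_hz - 3.0, spec.beta_hz + 3.0)
        return gain * envelope() * (mu + beta)

    s_left_hemi = smr_source()
    s_right_hemi = smr_source()
    # contralateral ERD: right-hand imagery suppresses the left hemisphere
    gain_lh = 1.0 - spec.erd_depth if cue == RIGHT else 1.0
    gain_rh = 1.0 - spec.erd_depth if cue == LEFT else 1.0
    rhythms_ref = np.outer(topo_left_hemi, s_left_hemi) + np.outer(topo_right_hemi, s_right_hemi)
    data = np.outer(topo_left_hemi, gain_lh * s_left_hemi) + np.outer(
        topo_right_hemi, gain_rh * s_right_hemi
    )

    rhythm_power = float(np.mean(rhythms_ref**2))
    if spec.noise_level > 0:
        if bg_topographies is None:
            bg_rng = np.random.default_rng(spec.seed + 1)
            bg_topographies = []
            for _ in range(4):
                v = bg_rng.standard_normal(nch)
                v = np.convolve(v, np.ones(3) / 3.0, mode="same")
                bg_topographies.append(v / np.linalg.norm(v))
        noise = np.zeros((nch, n))
        for topo in bg_topographies:
            noise += np.outer(topo, _pink(rng, n))
        np_power = float(np.mean(noise**2))
        if np_power > 0:
            noise *= np.sqrt(spec.noise_level * rhythm_power / np_power)
        data = data + noise

    if spec.sensor_noise > 0:
        # uncorrelated amplifier noise keeps the channel covariance full rank
        data = data + np.sqrt(spec.sensor_noise * rhythm_power) * rng.standard_normal((nch, n))

    if spec.artifact_rate > 0:
        art = spec.artifact or ArtifactSpec()
        k = rng.poisson(spec.artifact_rate * duration_s / 60.0)
        rms = np.sqrt(rhythm_power)
        dur_n = max(4, int(round(art.duration_s * fs)))
        for _ in range(k):
            if dur_n >= n:
                break
            start = rng.integers(0, n - dur_n)
            hi = min(art.high_hz, fs / 2 - 1)
            burst = _narrowband(rng, dur_n, fs, art.low_hz, hi)
            burst *= np.hanning(dur_n)
            weights = np.abs(rng.standard_normal(nch))
            weights /= weights.max()
            data[:, start : start + dur_n] += art.amplitude * rms * np.outer(weights, burst)

    names = [f"CH{i:02d}" for i in range(nch)]
    if spec.include_reference:
        # ear-lobe-like reference: background + amplifier noise, no SMR content.
        # Including it in the common average keeps the scalp channels
        # linearly independent after CAR (plain CAR alone is rank-deficient).
        ref = _pink(rng, n) * np.sqrt(max(rhythm_power, 1e-12))
        ref = ref + np.sqrt(max(spec.sensor_noise, 0.01) * rhythm_power) * rng.standard_normal(n)
        data = np.vstack([data, ref])
        names = names + ["REF"]
    return RawSegment(data=data, sample_rate=fs, channel_names=names)


def simulate_closed_loop(spec: SyntheticUserSpec, config=None):
    """Run a full flexible training session driven by a synthetic user.

    Thin wrapper: builds a :class:`SyntheticUser` from ``spec`` and hands it
    to the session engine as the EEG source.  Returns the finished
    :class:`~coadapt.session.SessionState`.
    """
    from .session import SessionConfig, run_session

    if config is None:
        config = SessionConfig()
    user = SyntheticUser(spec, sample_rate=config.sample_rate)
    return run_session(config, user)
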