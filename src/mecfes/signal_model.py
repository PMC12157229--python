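"""Synthetic myoelectric signal (MES) generation.

Surface EMG recorded next to a transcutaneous stimulator contains four
additive components, and each downstream processing stage exists to deal
with one of them:

* volitional EMG — band-limited stochastic activity whose local RMS scales
  with the user's voluntary drive;
* mains interference — a sinusoid at the power-grid frequency;
* movement artifacts — step-like shifts of the electrode half-cell potential
  with slow exponential recovery;
* stimulation artifacts — a fast biphasic transient at each pulse plus a
  delayed M-wave (the compound muscle action potential evoked by the pulse).

This module generates all four so the firmware chain can be exercised and
verified without any recordings.  All amplitudes are in mV, times in
seconds, currents in mA.  Every random draw descends deterministically from
``NoiseModel.rng_seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy import signal as sps

from .errors import ConfigurationError

__all__ = [
    "StimEvent",
    "MesTrace",
    "ActivationProfile",
    "NoiseModel",
    "ArtifactModel",
    "generate_volitional_mes",
    "add_mains_interference",
    "draw_movement_events",
    "add_movement_artifacts",
    "superimpose_stim_artifacts",
    "generate_full_mes",
]

# sub-seed ids so each additive component draws from an independent stream
_SUBSEED_VOLITIONAL = 0
_SUBSEED_MOVEMENT = 1


@dataclass(frozen=True)
class StimEvent:
    """A single stimulation pulse onset annotated on a trace."""

    time_s: float
    channel: int
    current_ma: float


@dataclass
class MesTrace:
    """Uniformly sampled multi-channel myoelectric signal.

    ``samples`` has shape ``(n_channels, n_samples)`` in mV.  Stimulation
    pulse onsets that fall inside the trace are kept as annotations so the
    DSP chain can blank around them.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    stim_events: list[StimEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ConfigurationError(f"fs must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace samples must be finite")
        end = self.t0 + self.n_samples / self.fs
        for ev in self.stim_events:
            if not (self.t0 <= ev.time_s < end):
                raise ValueError(
                    f"stim event at t={ev.time_s:g} s outside trace span "
                    f"[{self.t0:g}, {end:g})"
                )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def copy(self) -> "MesTrace":
        return MesTrace(
            self.samples.copy(), self.fs, self.t0, list(self.stim_events)
        )

    def sample_index(self, time_s: float) -> int:
        """Nearest sample index for an absolute time."""
        return int(round((time_s - self.t0) * self.fs))


class ActivationProfile:
    """Volitional drive a(t) in [0, 1] per channel.

    Wraps a callable ``t -> (n_channels, len(t))``; values are clipped to
    [0, 1], matching the definition of activation as a fraction of full
    voluntary effort.
    """

    def __init__(self, fn: Callable[[np.ndarray], np.ndarray], n_channels: int = 2):
        self._fn = fn
        self.n_channels = int(n_channels)

    def __call__(self, t: np.ndarray | float) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        a = np.asarray(self._fn(t), dtype=float)
        a = np.broadcast_to(a, (self.n_channels, t.size)).copy()
        return np.clip(a, 0.0, 1.0)

    @classmethod
    def constant(cls, levels: float | Sequence[float], n_channels: int = 2):
        lv = np.atleast_1d(np.asarray(levels, dtype=float))
        if lv.size == 1:
            lv = np.repeat(lv, n_channels)
        return cls(lambda t: np.repeat(lv[:, None], t.size, axis=1),
                   n_channels=lv.size)

    @classmethod
    def boxcar(cls, t_on: float, t_off: float,
               levels: float | Sequence[float] = 1.0, n_channels: int = 2):
        lv = np.atleast_1d(np.asarray(levels, dtype=float))
        if lv.size == 1:
            lv = np.repeat(lv, n_channels)
        return cls(
            lambda t: lv[:, None] * ((t >= t_on) & (t < t_off))[None, :],
            n_channels=lv.size,
        )


class NoiseModel(BaseModel):
    """Amplitudes and rates of the non-stimulation signal components."""

    emg_band_hz: tuple[float, float] = (20.0, 450.0)
    emg_rms_at_full_activation_mv: float = 0.5
    mains_freq_hz: float = 50.0
    mains_amp_mv: float = 0.1
    movement_artifact_rate_hz: float = 0.1
    movement_artifact_amp_mv: float = 2.0
    movement_recovery_tau_s: float = 0.5
    rng_seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        lo, hi = self.emg_band_hz
        if not (0 < lo < hi):
            raise ValueError(f"emg_band_hz must satisfy 0 < low < high, got {self.emg_band_hz}")
        for name in ("emg_rms_at_full_activation_mv", "mains_amp_mv",
                     "movement_artifact_amp_mv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.movement_artifact_rate_hz < 0:
            raise ValueError("movement_artifact_rate_hz must be >= 0")
        if self.movement_recovery_tau_s <= 0:
            raise ValueError("movement_recovery_tau_s must be > 0")
        return self


class ArtifactModel(BaseModel):
    """Stimulation-synchronous contamination of the recording.

    The direct artifact is an instantaneous biphasic transient proportional
    to the pulse current.  The M-wave is a delayed, damped oscillation whose
    amplitude follows a recruitment-shaped (clipped logistic) function of
    current: zero at 0 mA, saturating at ``mwave_amp_max_mv``.
    """

    direct_artifact_amp_per_ma: float = 0.2
    mwave_amp_max_mv: float = 1.5
    mwave_i50_ma: float = 15.0
    mwave_slope_ma: float = 3.0
    mwave_latency_s: float = 0.008
    mwave_tau_s: float = 0.010
    mwave_freq_hz: float = 80.0

    @model_validator(mode="after")
    def _check(self):
        if self.direct_artifact_amp_per_ma < 0 or self.mwave_amp_max_mv < 0:
            raise ValueError("artifact amplitudes must be >= 0")
        if self.mwave_latency_s < 0 or self.mwave_tau_s <= 0:
            raise ValueError("mwave_latency_s >= 0 and mwave_tau_s > 0 required")
        return self

    def mwave_amp(self, current_ma: float | np.ndarray) -> np.ndarray | float:
        """Recruitment-shaped M-wave amplitude (mV), exactly 0 at 0 mA."""
        i = np.asarray(current_ma, dtype=float)
        s0 = 1.0 / (1.0 + math.exp(self.mwave_i50_ma / self.mwave_slope_ma))
        s = 1.0 / (1.0 + np.exp(-(i - self.mwave_i50_ma) / self.mwave_slope_ma))
        out = self.mwave_amp_max_mv * np.clip((s - s0) / (1.0 - s0), 0.0, 1.0)
        return float(out) if np.isscalar(current_ma) else out

    def decays_within(self, period_s: float, fraction: float = 0.01) -> bool:
        """True if the M-wave envelope falls below `fraction` of its peak
        before the next stimulation period."""
        remaining = period_s - self.mwave_latency_s
        return remaining > 0 and math.exp(-remaining / self.mwave_tau_s) < fraction


def _rng(seed: int, component: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), component]))


def generate_volitional_mes(
    profile: ActivationProfile,
    noise: NoiseModel,
    duration_s: float,
    fs: float,
    t0: float = 0.0,
) -> MesTrace:
    """Band-limited Gaussian surrogate of volitional surface EMG.

    White Gaussian noise is band-passed (4th-order Butterworth over
    ``emg_band_hz``), normalised per channel to unit whole-trace RMS, and
    amplitude-modulated by ``activation(t) * emg_rms_at_full_activation_mv``.
    With constant full activation the whole-trace RMS therefore equals the
    configured full-activation RMS exactly.
    """
    if duration_s <= 0:
        raise ConfigurationError("duration_s must be positive")
    lo, hi = noise.emg_band_hz
    if fs < 2 * hi:
        raise ConfigurationError(
            f"fs={fs:g} Hz cannot represent the EMG band upper corner {hi:g} Hz"
        )
    n = int(round(duration_s * fs))
    t = t0 + np.arange(n) / fs
    rng = _rng(noise.rng_seed, _SUBSEED_VOLITIONAL)
    white = rng.standard_normal((profile.n_channels, n))
    sos = sps.butter(4, (lo, hi), btype="bandpass", fs=fs, output="sos")
    band = sps.sosfilt(sos, white, axis=-1)
    rms = np.sqrt(np.mean(band**2, axis=-1, keepdims=True))
    rms[rms == 0] = 1.0
    carrier = band / rms
    samples = profile(t) * noise.emg_rms_at_full_activation_mv * carrier
    return MesTrace(samples, fs=fs, t0=t0)


def add_mains_interference(trace: MesTrace, noise: NoiseModel) -> MesTrace:
    """Add a mains sinusoid to every channel (input left unmodified)."""
    if noise.mains_freq_hz >= trace.fs / 2:
        raise ConfigurationError(
            f"mains_freq_hz={noise.mains_freq_hz:g} is not below fs/2={trace.fs / 2:g}"
        )
    out = trace.copy()
    out.samples += noise.mains_amp_mv * np.sin(
        2 * np.pi * noise.mains_freq_hz * (trace.times - trace.t0)
    )
    return out


def draw_movement_events(noise: NoiseModel, duration_s: float,
                         t0: float = 0.0) -> list[tuple[float, float]]:
    """Seeded Poisson draw of movement-artifact events.

    Returns ``[(time_s, signed_amp_mv), ...]``: event count Poisson at
    ``movement_artifact_rate_hz``, times uniform over the span, signs
    equiprobable.
    """
    rng = _rng(noise.rng_seed, _SUBSEED_MOVEMENT)
    n_ev = rng.poisson(noise.movement_artifact_rate_hz * duration_s)
    times = t0 + rng.uniform(0.0, duration_s, size=n_ev)
    signs = rng.choice((-1.0, 1.0), size=n_ev)
    return list(zip(times.tolist(),
                    (signs * noise.movement_artifact_amp_mv).tolist()))


def add_movement_artifacts(
    trace: MesTrace,
    noise: NoiseModel,
    events: Sequence[tuple[float, float]] | None = None,
) -> MesTrace:
    """Superimpose half-cell-potential steps with exponential recovery.

    Event times are a Poisson process at ``movement_artifact_rate_hz``,
    signs random, amplitude ``movement_artifact_amp_mv``; each event adds
    ``a * exp(-(t - t_e)/tau)`` for ``t >= t_e`` to all channels.  Pass
    ``events`` as ``[(time_s, signed_amp_mv), ...]`` to force a specific
    realisation (used by tests against the closed form).
    """
    out = trace.copy()
    if events is None:
        events = draw_movement_events(noise, trace.duration_s, trace.t0)
    t = trace.times
    tau = noise.movement_recovery_tau_s
    for te, amp in events:
        dt = t - te
        out.samples += np.where(dt >= 0, amp * np.exp(-np.maximum(dt, 0) / tau), 0.0)
    return out


def superimpose_stim_artifacts(trace: MesTrace, schedule, artifact: ArtifactModel) -> MesTrace:
    """Add pulse-synchronous contamination and annotate the events.

    At each pulse onset of ``schedule`` (a :class:`~mecfes.stim_engine.PulseSchedule`
    or any object with ``.events``): (a) a two-sample biphasic transient of
    amplitude ``direct_artifact_amp_per_ma * current`` on the recording
    channel with the same index as the stimulation channel, and (b) an
    M-wave — a damped sinusoid starting after ``mwave_latency_s`` with time
    constant ``mwave_tau_s`` and recruitment-shaped amplitude.
    """
    out = trace.copy()
    n = out.n_samples
    end = trace.t0 + n / trace.fs
    for ev in schedule.events:
        if not (trace.t0 <= ev.time_s < end):
            raise ValueError(
                f"pulse at t={ev.time_s:g} s outside trace span [{trace.t0:g}, {end:g})"
            )
        ch = ev.channel % out.n_channels
        k = trace.sample_index(ev.time_s)
        amp = artifact.direct_artifact_amp_per_ma * ev.amplitude_ma
        if k < n:
            out.samples[ch, k] += amp
        if k + 1 < n:
            out.samples[ch, k + 1] -= amp
        m_amp = artifact.mwave_amp(ev.amplitude_ma)
        if m_amp > 0:
            k0 = trace.sample_index(ev.time_s + artifact.mwave_latency_s)
            k1 = min(n, k0 + int(round(8 * artifact.mwave_tau_s * trace.fs)))
            if k0 < n:
                u = (np.arange(k0, k1) - (ev.time_s + artifact.mwave_latency_s - trace.t0) * trace.fs) / trace.fs
                u = np.maximum(u, 0.0)
                out.samples[ch, k0:k1] += m_amp * np.exp(-u / artifact.mwave_tau_s) * np.sin(
                    2 * np.pi * artifact.mwave_freq_hz * u
                )
        out.stim_events.append(StimEvent(ev.time_s, ev.channel, ev.amplitude_ma))
    out.stim_events.sort(key=lambda e: e.time_s)
    return out


def generate_full_mes(
    profile: ActivationProfile,
    noise: NoiseModel,
    duration_s: float,
    fs: float,
    schedule=None,
    artifact: ArtifactModel | None = None,
    t0: float = 0.0,
) -> MesTrace:
    """Compose all four components (linear superposition, shared seed)."""
    trace = generate_volitional_mes(profile, noise, duration_s, fs, t0=t0)
    trace = add_mains_interference(trace, noise)
    trace = add_movement_artifacts(trace, noise)
    if schedule is not None and artifact is not None:
        trace = superimpose_stim_artifacts(trace, schedule, artifact)
    return trace
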