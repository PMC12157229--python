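"""Firmware signal-processing chain: blanking, comb filter, windowed RMS,
smoothing and the proportional control law.

The chain turns raw MES into a per-period stimulation command:

1. **Blanking** — samples in a window after each pulse onset are zeroed so
   direct artifacts and M-waves cannot enter the envelope estimate.
2. **Comb filter** — ``y[n] = x[n] - x[n-N]`` with N one stimulation period.
   Its nulls sit at DC and every multiple of 1/T; because T = 60 ms is a
   subharmonic of the 50 Hz grid (3 cycles per period), mains and any
   period-synchronous artifact residue cancel exactly.
3. **Windowed RMS** — one envelope value V per period, computed over the
   non-blanked samples only.
4. **Exponential smoothing** of V.
5. **Control law** — per channel, the offset Off (involuntary background)
   is subtracted, the result rectified, and mixed through a signed gain
   matrix:  I_j = sum_i max(V_i - Off_i, 0) * G_ij.  Positive cross gains
   implement synergies, negative ones inhibition.  The command is clamped
   to [0, current_limit] and DAC-quantised.

Pipeline order is blanking -> comb -> RMS -> smoothing -> control law; the
comb therefore sees blanked (still period-synchronous) data, so periodic
contamination cancels even where blanking windows repeat.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, model_validator

from .errors import ConfigurationError
from .signal_model import MesTrace
from .stim_engine import PulseSchedule, StimCommand, StimParams, quantize_current

__all__ = [
    "ControlParams",
    "Envelope",
    "apply_blanking",
    "blanking_mask",
    "comb_filter",
    "windowed_rms",
    "smooth_envelope",
    "control_drive",
    "control_law",
    "FirmwarePipeline",
    "run_chain",
    "process_period",
]


class ControlParams(BaseModel):
    """Per-channel offsets, signed gain matrix, blanking and smoothing."""

    off_mv: tuple[float, ...] = (0.05, 0.05)
    gain_ma_per_mv: tuple[tuple[float, ...], ...] = ((60.0, 0.0), (0.0, 60.0))
    blank_ms: float = 20.0
    smooth_tau_s: float = 0.2

    @property
    def gain_matrix(self) -> np.ndarray:
        """G with G[i, j] = gain of input channel i onto output channel j."""
        return np.asarray(self.gain_ma_per_mv, dtype=float)

    @property
    def offsets(self) -> np.ndarray:
        return np.asarray(self.off_mv, dtype=float)

    @model_validator(mode="after")
    def _check(self):
        if any(o < 0 for o in self.off_mv):
            raise ValueError("offsets must be >= 0")
        if self.smooth_tau_s <= 0:
            raise ValueError("smooth_tau_s must be > 0")
        if self.blank_ms < 0:
            raise ValueError("blank_ms must be >= 0")
        g = self.gain_matrix
        if g.ndim != 2 or g.shape[0] != len(self.off_mv):
            raise ValueError("gain matrix rows must match number of input channels")
        return self


@dataclass
class Envelope:
    """Per-period volitional control estimate V (mV) per channel."""

    values: np.ndarray          # (n_channels, n_windows), >= 0
    window_times_s: np.ndarray  # window start times
    period_s: float

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.window_times_s = np.asarray(self.window_times_s, dtype=float)


def blanking_mask(n_samples: int, fs: float, t0: float,
                  schedule: PulseSchedule, blank_ms: float) -> np.ndarray:
    """Boolean mask, True where a sample falls in a post-pulse blanking window."""
    mask = np.zeros(n_samples, dtype=bool)
    nb = int(round(blank_ms * 1e-3 * fs))
    for ev in schedule.events:
        k = int(round((ev.time_s - t0) * fs))
        if k >= n_samples or k + nb <= 0:
            continue
        mask[max(k, 0):min(k + nb, n_samples)] = True
    return mask


def apply_blanking(trace: MesTrace, schedule: PulseSchedule, blank_ms: float) -> MesTrace:
    """Zero all channels within ``blank_ms`` after every pulse onset."""
    out = trace.copy()
    mask = blanking_mask(trace.n_samples, trace.fs, trace.t0, schedule, blank_ms)
    out.samples[:, mask] = 0.0
    return out


def comb_filter(trace: MesTrace, period_ms: float) -> MesTrace:
    """Feed-forward comb at one stimulation period: ``y[n] = x[n] - x[n-N]``.

    The first N output samples are zero by convention (no history).  Exact
    nulls at DC and at every multiple of 1/T.
    """
    n_delay = int(round(period_ms * 1e-3 * trace.fs))
    if n_delay < 1:
        raise ConfigurationError(f"comb delay of {period_ms:g} ms is < 1 sample at fs={trace.fs:g}")
    if n_delay >= trace.n_samples:
        raise ValueError(
            f"trace of {trace.n_samples} samples shorter than comb delay {n_delay}"
        )
    out = trace.copy()
    out.samples[:, :n_delay] = 0.0
    out.samples[:, n_delay:] = trace.samples[:, n_delay:] - trace.samples[:, :-n_delay]
    return out


def windowed_rms(trace: MesTrace, schedule: PulseSchedule, blank_ms: float,
                 period_ms: float = 60.0) -> Envelope:
    """RMS per stimulation period over the non-blanked samples.

    Windows tile the trace from ``t0`` in steps of one period (only complete
    periods are kept).  Blanked samples are excluded from both the sum and
    the count; a fully blanked window yields 0 with a warning.
    """
    n_win_samp = int(round(period_ms * 1e-3 * trace.fs))
    n_windows = trace.n_samples // n_win_samp
    mask = blanking_mask(trace.n_samples, trace.fs, trace.t0, schedule, blank_ms)
    values = np.zeros((trace.n_channels, n_windows))
    for w in range(n_windows):
        sl = slice(w * n_win_samp, (w + 1) * n_win_samp)
        keep = ~mask[sl]
        if not keep.any():
            warnings.warn(f"window {w} fully blanked; envelope set to 0", stacklevel=2)
            continue
        values[:, w] = np.sqrt(np.mean(trace.samples[:, sl][:, keep] ** 2, axis=-1))
    times = trace.t0 + np.arange(n_windows) * n_win_samp / trace.fs
    return Envelope(values, times, n_win_samp / trace.fs)


def smooth_envelope(env: Envelope, smooth_tau_s: float) -> Envelope:
    """First-order exponential smoothing across successive period values.

    Coefficient ``a = exp(-T/tau)``; the recursion is initialised at the
    first raw value, so a constant sequence is a fixed point.
    """
    if smooth_tau_s <= 0:
        raise ConfigurationError("smooth_tau_s must be > 0")
    a = math.exp(-env.period_s / smooth_tau_s)
    out = np.empty_like(env.values)
    out[:, 0] = env.values[:, 0]
    for k in range(1, env.values.shape[1]):
        out[:, k] = a * out[:, k - 1] + (1 - a) * env.values[:, k]
    return Envelope(out, env.window_times_s.copy(), env.period_s)


def control_drive(v_mv: np.ndarray, params: ControlParams) -> np.ndarray:
    """Rectified, gain-mixed drive before clamping and quantisation (mA).

    ``d_i = max(V_i - Off_i, 0)``; ``out_j = sum_i d_i * G_ij``.  The
    rectification precedes the (possibly negative) gains so inhibition acts
    on genuine supra-offset activity only.
    """
    v = np.atleast_1d(np.asarray(v_mv, dtype=float))
    d = np.clip(v - params.offsets, 0.0, None)
    return d @ params.gain_matrix


def control_law(v_mv: np.ndarray, params: ControlParams, stim: StimParams,
                quantize: bool = True) -> StimCommand:
    """Full control law: drive, clamp to [0, current_limit], DAC-quantise."""
    raw = control_drive(v_mv, params)
    clamped = np.clip(raw, 0.0, stim.current_limit_ma)
    if quantize:
        clamped = np.array([quantize_current(c, stim) for c in clamped])
    return StimCommand(clamped)


@dataclass
class PeriodOutput:
    """One pipeline step: raw and smoothed envelope plus the command."""

    v_raw_mv: np.ndarray
    v_smooth_mv: np.ndarray
    command: StimCommand


class FirmwarePipeline:
    """Stateful per-period processing: blank -> comb -> RMS -> smooth -> law.

    Holds the one-period comb history and the smoother state between calls,
    mirroring the firmware's real-time operation.  The first period's comb
    output is zero (no history yet), matching :func:`comb_filter`'s
    zero-padding convention.
    """

    def __init__(self, cparams: ControlParams, sparams: StimParams, fs: float):
        self.cparams = cparams
        self.sparams = sparams
        self.fs = fs
        self.n_period = int(round(sparams.period_ms * 1e-3 * fs))
        if cparams.blank_ms >= sparams.period_ms:
            raise ConfigurationError(
                f"blank_ms={cparams.blank_ms:g} must be < period_ms={sparams.period_ms:g}"
            )
        self.reset()

    def reset(self) -> None:
        self._history: np.ndarray | None = None
        self._smooth: np.ndarray | None = None

    def process_period(self, window: np.ndarray,
                       event_offsets_s: list[tuple[float, int]] | None = None
                       ) -> PeriodOutput:
        """Process one period of samples.

        ``window`` is ``(n_channels, n_period)`` mV; ``event_offsets_s``
        lists pulse onsets (offset within the window, channel).
        """
        x = np.atleast_2d(np.asarray(window, dtype=float))
        if x.shape[1] != self.n_period:
            raise ValueError(f"window must have {self.n_period} samples, got {x.shape[1]}")
        mask = np.zeros(self.n_period, dtype=bool)
        nb = int(round(self.cparams.blank_ms * 1e-3 * self.fs))
        for off, _ch in event_offsets_s or []:
            k = int(round(off * self.fs))
            if 0 <= k < self.n_period:
                mask[k:min(k + nb, self.n_period)] = True
        blanked = x.copy()
        blanked[:, mask] = 0.0
        comb = np.zeros_like(blanked) if self._history is None else blanked - self._history
        self._history = blanked
        keep = ~mask
        if keep.any():
            v_raw = np.sqrt(np.mean(comb[:, keep] ** 2, axis=-1))
        else:
            warnings.warn("period fully blanked; envelope set to 0", stacklevel=2)
            v_raw = np.zeros(x.shape[0])
        a = math.exp(-(self.n_period / self.fs) / self.cparams.smooth_tau_s)
        self._smooth = v_raw if self._smooth is None else a * self._smooth + (1 - a) * v_raw
        cmd = control_law(self._smooth, self.cparams, self.sparams)
        return PeriodOutput(v_raw, self._smooth.copy(), cmd)


def process_period(window: np.ndarray, event_offsets_s, cparams: ControlParams,
                   sparams: StimParams, fs: float,
                   pipeline: FirmwarePipeline | None = None) -> PeriodOutput:
    """Single-shot wrapper around :class:`FirmwarePipeline` (stateless use)."""
    pipe = pipeline or FirmwarePipeline(cparams, sparams, fs)
    return pipe.process_period(window, event_offsets_s)


@dataclass
class ChainResult:
    envelope_raw: Envelope
    envelope_smooth: Envelope
    commands_ma: np.ndarray  # (n_windows, n_channels)


def run_chain(trace: MesTrace, schedule: PulseSchedule,
              cparams: ControlParams, sparams: StimParams) -> ChainResult:
    """Run the full chain over a trace, one stimulation period at a time."""
    pipe = FirmwarePipeline(cparams, sparams, trace.fs)
    n = pipe.n_period
    n_windows = trace.n_samples // n
    period_s = n / trace.fs
    raw = []
    smooth = []
    commands = []
    for w in range(n_windows):
        w_start = trace.t0 + w * period_s
        offsets = [(ev.time_s - w_start, ev.channel) for ev in schedule.events
                   if w_start <= ev.time_s < w_start + period_s]
        out = pipe.process_period(trace.samples[:, w * n:(w + 1) * n], offsets)
        raw.append(out.v_raw_mv)
        smooth.append(out.v_smooth_mv)
        commands.append(out.command.currents_ma)
    times = trace.t0 + np.arange(n_windows) * period_s
    return ChainResult(
        Envelope(np.array(raw).T, times, period_s),
        Envelope(np.array(smooth).T, times, period_s),
        np.array(commands),
    )
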