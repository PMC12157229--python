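"""Charge-balanced doublet stimulation: DAC quantisation, waveform
construction and pulse scheduling.

The stimulator delivers biphasic current pulses of phase width PW = 300 µs
repeated every T = 60 ms as *doublets* — two closely spaced pulses per
period, a pattern that produces tetanic force at a low mean rate and leaves
a long artifact-free window for EMG sampling between periods.  Current is
commanded through a 12-bit DAC spanning 0–100 mA (24 µA steps) with a
software safety limit, 30 mA by default.  Exact charge balance per doublet
is enforced by construction: every pulse has two phases of equal width and
amplitude and opposite sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, model_validator

from .errors import ResolutionError, SchedulingError

__all__ = [
    "StimParams",
    "StimCommand",
    "PulseEvent",
    "PulseSchedule",
    "dac_step",
    "quantize_current",
    "build_doublet_waveform",
    "schedule_pulses",
    "periodic_commands",
    "max_effective_current",
]


class StimParams(BaseModel):
    """Stimulation waveform, timing and output-stage parameters."""

    pw_us: float = 300.0                 # single phase width
    period_ms: float = 60.0              # doublet repetition period T
    doublet_gap_ms: float = 5.0          # onset-to-onset gap inside a doublet
    channel_phase_offset_ms: float = 30.0  # stagger of channel 2 vs channel 1
    dac_bits: int = 12
    full_scale_ma: float = 100.0
    current_limit_ma: float = 30.0
    compliance_voltage_v: float = 320.0

    @property
    def dac_step_ma(self) -> float:
        return self.full_scale_ma / 2**self.dac_bits

    @property
    def pulse_span_s(self) -> float:
        """Duration of one biphasic pulse (two phases)."""
        return 2 * self.pw_us * 1e-6

    @model_validator(mode="after")
    def _check(self):
        if self.pw_us <= 0 or self.period_ms <= 0:
            raise ValueError("pw_us and period_ms must be positive")
        if self.dac_bits < 1:
            raise ValueError("dac_bits must be >= 1")
        if not (0 < self.current_limit_ma <= self.full_scale_ma):
            raise ValueError("require 0 < current_limit_ma <= full_scale_ma")
        # all four pulses of one period (both channels) must fit without overlap
        onsets = _period_pulse_onsets_s(self)
        span = self.pulse_span_s
        t_s = self.period_ms * 1e-3
        both = sorted(onsets + [(t + t_s, ch) for t, ch in onsets])
        for (a, _), (b, _) in zip(both, both[1:]):
            if b < a + span:
                raise ValueError(
                    "pulse timing parameters produce overlapping pulses "
                    f"(onsets {a * 1e3:g} ms and {b * 1e3:g} ms, span {span * 1e3:g} ms)"
                )
        return self


def _period_pulse_onsets_s(params: StimParams) -> list[tuple[float, int]]:
    """Pulse onsets (s, channel) inside one period, channel 1 then channel 2."""
    gap = params.doublet_gap_ms * 1e-3
    off = params.channel_phase_offset_ms * 1e-3
    return [(0.0, 0), (gap, 0), (off, 1), (off + gap, 1)]


@dataclass(frozen=True)
class StimCommand:
    """Desired per-channel current for one stimulation period (mA)."""

    currents_ma: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "currents_ma",
                           np.atleast_1d(np.asarray(self.currents_ma, dtype=float)))


@dataclass(frozen=True)
class PulseEvent:
    """One biphasic pulse: two phases of width ``pw_us``, signs ``polarity``."""

    time_s: float
    channel: int
    amplitude_ma: float
    pw_us: float
    polarity: tuple[int, int] = (-1, 1)   # cathodic-first convention

    @property
    def net_charge_uc(self) -> float:
        """Net charge in µC; zero by construction for equal-width phases."""
        return self.amplitude_ma * self.pw_us * 1e-3 * sum(self.polarity) * 1e-3


@dataclass
class PulseSchedule:
    """Time-sorted list of pulse events across both channels."""

    events: list[PulseEvent] = field(default_factory=list)

    def __post_init__(self):
        self.events = sorted(self.events, key=lambda e: e.time_s)

    def times(self, channel: int | None = None) -> np.ndarray:
        return np.array([e.time_s for e in self.events
                         if channel is None or e.channel == channel])

    def doublet_onsets(self, channel: int) -> np.ndarray:
        """Onset of the first pulse of each doublet on a channel."""
        t = self.times(channel)
        return t[::2]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": [e.time_s for e in self.events],
                "channel": [e.channel for e in self.events],
                "amplitude_ma": [e.amplitude_ma for e in self.events],
                "phase_us": [e.pw_us for e in self.events],
            }
        )


def dac_step(params: StimParams) -> float:
    """Current resolution of the output DAC in mA (full scale / 2^bits)."""
    return params.dac_step_ma


def quantize_current(desired_ma: float, params: StimParams) -> float:
    """Round a current command to the DAC grid and apply the safety limit.

    Round-to-nearest onto multiples of the DAC step; if the rounded value
    exceeds ``current_limit_ma`` the result is the largest step multiple not
    exceeding the limit, so the limit is never crossed.
    """
    if desired_ma < 0:
        raise ValueError(f"current command must be >= 0, got {desired_ma:g} mA")
    step = params.dac_step_ma
    k = int(np.floor(desired_ma / step + 0.5))
    value = k * step
    if value > params.current_limit_ma:
        value = int(np.floor(params.current_limit_ma / step)) * step
    return value


def max_effective_current(params: StimParams, load_resistance_ohm: float) -> float:
    """Compliance-limited current (mA) into a resistive load.

    The high-voltage stage saturates at ``compliance_voltage_v``; into a
    load R the deliverable current is min(limit, V/R).
    """
    if load_resistance_ohm <= 0:
        raise ValueError("load_resistance_ohm must be positive")
    return min(params.current_limit_ma,
               params.compliance_voltage_v / load_resistance_ohm * 1e3)


def build_doublet_waveform(
    current_ma: float, params: StimParams, fs_out: float
) -> tuple[np.ndarray, np.ndarray]:
    """Sample one period of the doublet waveform.

    Returns ``(t, i)``: the time axis (s) and current (mA) over one period,
    containing two biphasic pulses (first phase cathodic).  The per-period
    integral is exactly zero because each phase occupies the same integer
    number of samples.
    """
    n_phase = int(round(params.pw_us * 1e-6 * fs_out))
    if n_phase < 4:
        raise ResolutionError(
            f"fs_out={fs_out:g} Hz gives {n_phase} samples per {params.pw_us:g} µs "
            "phase; at least 4 are required"
        )
    n = int(round(params.period_ms * 1e-3 * fs_out))
    w = np.zeros(n)
    for onset_s, ch in _period_pulse_onsets_s(params):
        if ch != 0:
            continue
        k = int(round(onset_s * fs_out))
        w[k:k + n_phase] = -current_ma
        w[k + n_phase:k + 2 * n_phase] = current_ma
    return np.arange(n) / fs_out, w


def periodic_commands(current_ma: float | Sequence[float],
                      duration_s: float, params: StimParams) -> list[StimCommand]:
    """Constant-current command sequence covering ``duration_s``."""
    n_periods = int(np.floor(duration_s * 1e3 / params.period_ms))
    c = np.atleast_1d(np.asarray(current_ma, dtype=float))
    if c.size == 1:
        c = np.repeat(c, 2)
    return [StimCommand(c.copy()) for _ in range(n_periods)]


def schedule_pulses(commands: Iterable[StimCommand], params: StimParams) -> PulseSchedule:
    """Lay out doublets on the time-multiplexed two-channel grid.

    Channel 1's doublet starts at ``k*T``, channel 2's at
    ``k*T + channel_phase_offset``; each doublet is two biphasic pulses
    ``doublet_gap`` apart.  Commands must already be limited (an amplitude
    above ``current_limit_ma`` raises); zero-amplitude events are kept so
    the schedule length encodes the horizon.
    """
    onsets = _period_pulse_onsets_s(params)
    t_s = params.period_ms * 1e-3
    events: list[PulseEvent] = []
    for k, cmd in enumerate(commands):
        for onset, ch in onsets:
            if ch >= cmd.currents_ma.size:
                continue
            amp = float(cmd.currents_ma[ch])
            if amp < 0 or amp > params.current_limit_ma + 1e-12:
                raise ValueError(
                    f"command {amp:g} mA outside [0, {params.current_limit_ma:g}] "
                    "— quantize/limit commands before scheduling"
                )
            events.append(PulseEvent(k * t_s + onset, ch, amp, params.pw_us))
    sched = PulseSchedule(events)
    span = params.pulse_span_s
    t = sched.times()
    if np.any(np.diff(t) < span - 1e-12):
        raise SchedulingError("scheduled pulses overlap in time")
    return sched
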