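"""Closed-loop neuromuscular simulation, watchdog safety and latch-up
stability analysis.

Myoelectric control of stimulation is intrinsically a positive-feedback
loop: voluntary EMG raises the stimulation current, and stimulation leaves
residual contamination in the measured envelope (artifact and M-wave energy
surviving blanking and comb filtering), which raises the current further.
If the small-signal loop product

    G_eff = gain (mA/mV) x residual contamination (mV/mA)

exceeds one, a perturbation grows until the command clamps at the current
limit — *latch-up*: sustained stimulation regardless of intent, possibly
as a full on-off oscillation once the comb removes the DC component.  A
watchdog must detect prolonged maximum stimulation and force the output
off.

The loop here operates at the envelope level, one update per stimulation
period, with a one-period transport delay in the feedback path (the pulses
of period k contaminate the envelope of period k).  This keeps the
stability dichotomy closed-form checkable.  A sample-level mode that runs
the full signal generator and firmware pipeline inside the loop is provided
for integration testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from pydantic import BaseModel, model_validator

from .dsp_chain import ControlParams, FirmwarePipeline, control_law
from .errors import ConfigurationError, SweepNotFoundError
from .signal_model import ActivationProfile, ArtifactModel, MesTrace, NoiseModel, generate_volitional_mes, add_mains_interference
from .stim_engine import PulseEvent, PulseSchedule, StimParams, _period_pulse_onsets_s

__all__ = [
    "PlantModel",
    "WatchdogConfig",
    "LoopState",
    "SimResult",
    "recruitment_response",
    "step_loop",
    "watchdog_update",
    "loop_gain",
    "find_critical_gain",
    "run_simulation",
    "run_from_snapshot",
    "run_sample_level_simulation",
]


class PlantModel(BaseModel):
    """Muscle plant and feedback-path coupling.

    ``recruitment`` is a clipped logistic in current: exactly 0 at 0 mA,
    rising around ``recruitment_i50_ma`` with width ``recruitment_slope_ma``
    and saturating at 1.  ``residual_artifact_per_ma`` is the envelope-level
    contamination (mV per mA of stimulation) surviving blanking and comb
    filtering — the quantity that closes the positive-feedback loop.
    """

    recruitment_i50_ma: float = 15.0
    recruitment_slope_ma: float = 2.0
    residual_artifact_per_ma: float = 0.005
    force_scale_n: float = 20.0
    noise_floor_mv: float = 0.01

    @model_validator(mode="after")
    def _check(self):
        if self.recruitment_slope_ma <= 0:
            raise ValueError("recruitment_slope_ma must be > 0")
        if self.residual_artifact_per_ma < 0:
            raise ValueError("residual_artifact_per_ma must be >= 0")
        if self.noise_floor_mv < 0:
            raise ValueError("noise_floor_mv must be >= 0")
        return self


class WatchdogConfig(BaseModel):
    """Trip conditions for the prolonged-maximum-stimulation watchdog."""

    max_fraction: float = 0.95
    max_duration_s: float = 5.0
    rearm_envelope_mv: float = 0.05

    @model_validator(mode="after")
    def _check(self):
        if not (0 < self.max_fraction <= 1):
            raise ValueError("max_fraction must be in (0, 1]")
        if self.max_duration_s <= 0:
            raise ValueError("max_duration_s must be > 0")
        return self


def recruitment_response(current_ma: float | np.ndarray, plant: PlantModel):
    """Evoked activation in [0, 1] for a stimulation current.

    Logistic sigmoid shifted and rescaled so recruitment(0) = 0 exactly:
    ``r(I) = clip((s(I) - s(0)) / (1 - s(0)), 0, 1)`` with
    ``s(I) = 1/(1 + exp(-(I - i50)/slope))``.
    """
    i = np.asarray(current_ma, dtype=float)
    if np.any(i < 0):
        raise ValueError("current must be >= 0")
    s0 = 1.0 / (1.0 + math.exp(plant.recruitment_i50_ma / plant.recruitment_slope_ma))
    s = 1.0 / (1.0 + np.exp(-(i - plant.recruitment_i50_ma) / plant.recruitment_slope_ma))
    r = np.clip((s - s0) / (1.0 - s0), 0.0, 1.0)
    return float(r) if np.isscalar(current_ma) else r


@dataclass
class LoopState:
    """Per-period loop state (per-channel arrays)."""

    time_s: float
    v_meas_mv: np.ndarray
    v_smooth_mv: np.ndarray
    i_ma: np.ndarray
    wd_timer_s: np.ndarray
    tripped: np.ndarray
    trip_count: int = 0

    @classmethod
    def initial(cls, n_channels: int = 2) -> "LoopState":
        z = np.zeros(n_channels)
        return cls(0.0, z.copy(), z.copy(), z.copy(), z.copy(),
                   np.zeros(n_channels, dtype=bool))


def watchdog_update(state: LoopState, cfg: WatchdogConfig, stim: StimParams,
                    dt_s: float) -> LoopState:
    """Accumulate time at maximum output; trip, latch and re-arm.

    The timer advances while ``I >= max_fraction * current_limit`` and
    resets otherwise; reaching ``max_duration_s`` trips the channel,
    forcing I = 0.  A tripped channel re-arms only once its measured
    envelope falls below ``rearm_envelope_mv`` (latched, no chatter).
    Tripping also clears the channel's smoother state, so stimulation
    restarts from zero after a re-arm instead of re-entering latch-up from
    the remembered envelope.
    """
    thresh = cfg.max_fraction * stim.current_limit_ma
    at_max = state.i_ma >= thresh
    timer = np.where(at_max, state.wd_timer_s + dt_s, 0.0)
    newly = (~state.tripped) & (timer >= cfg.max_duration_s)
    tripped = state.tripped | newly
    # latched re-arm: only a quiet envelope releases the trip
    rearm = tripped & (state.v_meas_mv < cfg.rearm_envelope_mv)
    tripped = tripped & ~rearm
    i = np.where(tripped | newly, 0.0, state.i_ma)
    timer = np.where(tripped | newly, 0.0, timer)
    v_s = np.where(tripped | newly, 0.0, state.v_smooth_mv)
    return replace(state, i_ma=i, wd_timer_s=timer, tripped=tripped,
                   v_smooth_mv=v_s,
                   trip_count=state.trip_count + int(newly.sum()))


def step_loop(
    state: LoopState,
    volitional_mv: np.ndarray,
    control: ControlParams,
    stim: StimParams,
    plant: PlantModel,
    watchdog: WatchdogConfig | None = None,
    *,
    noise_mv: np.ndarray | None = None,
    quantize: bool = True,
    smooth: bool = True,
) -> LoopState:
    """One stimulation-period update of the envelope-level loop.

    measured envelope = volitional + residual_artifact_per_ma * I_prev
    (+ noise); the command follows from the control law; the watchdog (if
    configured) then gates the output.  Tripped channels output 0 until
    re-armed.
    """
    dt = stim.period_ms * 1e-3
    vol = np.atleast_1d(np.asarray(volitional_mv, dtype=float))
    v = vol + plant.residual_artifact_per_ma * state.i_ma
    if noise_mv is not None:
        v = v + noise_mv
    v = np.clip(v, 0.0, None)
    if smooth:
        a = math.exp(-dt / control.smooth_tau_s)
        v_s = a * state.v_smooth_mv + (1 - a) * v
    else:
        v_s = v
    cmd = control_law(v_s, control, stim, quantize=quantize)
    i = np.where(state.tripped, 0.0, cmd.currents_ma)
    new = replace(state, time_s=state.time_s + dt, v_meas_mv=v,
                  v_smooth_mv=v_s, i_ma=i)
    if watchdog is not None:
        new = watchdog_update(new, watchdog, stim, dt)
    return new


def loop_gain(control: ControlParams, plant: PlantModel) -> np.ndarray:
    """Per-channel small-signal loop product G_eff = G_jj x residual.

    Valid above the offsets and below the clamps; the envelope smoother is
    excluded because its DC gain is one and cannot change the stability
    boundary.
    """
    g = np.diag(control.gain_matrix)
    return g * plant.residual_artifact_per_ma


def _impulse_unstable(product: float, control: ControlParams, stim: StimParams,
                      plant: PlantModel, duration_s: float, kick_mv: float) -> bool:
    """Does a small kick grow to sustained near-limit output at this product?

    Linearised analysis: offsets zeroed (the operating point sits above
    them), smoothing and quantisation off.  'Unstable' means the channel-1
    output reaches and holds >= 95% of the current limit.
    """
    base = float(loop_gain(control, plant)[0])
    if base <= 0:
        raise ConfigurationError("no feedback path: loop gain is zero")
    scale = product / base
    g = control.gain_matrix * scale
    lin = control.model_copy(update={
        "gain_ma_per_mv": tuple(tuple(row) for row in g),
        "off_mv": tuple(0.0 for _ in control.off_mv),
    })
    n_steps = int(duration_s / (stim.period_ms * 1e-3))
    state = LoopState.initial(len(control.off_mv))
    thresh = 0.95 * stim.current_limit_ma
    hold = 0
    for k in range(n_steps):
        vol = np.zeros(len(control.off_mv))
        if k == 0:
            vol[0] = kick_mv
        state = step_loop(state, vol, lin, stim, plant,
                          quantize=False, smooth=False)
        hold = hold + 1 if state.i_ma[0] >= thresh else 0
    return hold >= 5


def find_critical_gain(
    control: ControlParams,
    stim: StimParams,
    plant: PlantModel,
    sweep: tuple[float, float] = (0.5, 1.5),
    resolution: float = 0.01,
    duration_s: float = 120.0,
    kick_mv: float = 0.01,
) -> float:
    """Locate the loop-gain product at the stability boundary by bisection.

    Returns the smallest product in ``sweep`` for which a small perturbation
    grows to sustained near-limit output instead of decaying.  With the
    linearised plant this is 1 within the sweep resolution — the
    loop-gain-exceeds-unity latch-up criterion.
    """
    lo, hi = sweep
    if _impulse_unstable(lo, control, stim, plant, duration_s, kick_mv):
        raise SweepNotFoundError(f"already unstable at sweep lower bound {lo:g}")
    if not _impulse_unstable(hi, control, stim, plant, duration_s, kick_mv):
        raise SweepNotFoundError(f"still stable at sweep upper bound {hi:g}")
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if _impulse_unstable(mid, control, stim, plant, duration_s, kick_mv):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


@dataclass
class SimResult:
    """Closed-loop run: per-period series, safety events and provenance."""

    times_s: np.ndarray
    v_meas_mv: np.ndarray      # (n_periods, n_channels)
    v_smooth_mv: np.ndarray
    i_ma: np.ndarray
    force_n: np.ndarray
    trip_events: list[tuple[float, int]] = field(default_factory=list)
    oscillation: np.ndarray = field(default_factory=lambda: np.zeros(2, dtype=bool))
    seed: int = 0
    config: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        cols = {"time_s": self.times_s}
        for ch in range(self.i_ma.shape[1]):
            cols[f"v_meas_ch{ch + 1}_mV"] = self.v_meas_mv[:, ch]
            cols[f"v_smooth_ch{ch + 1}_mV"] = self.v_smooth_mv[:, ch]
            cols[f"i_ch{ch + 1}_mA"] = self.i_ma[:, ch]
            cols[f"force_ch{ch + 1}_N"] = self.force_n[:, ch]
        return pd.DataFrame(cols)

    def summary(self) -> dict:
        return {
            "n_periods": int(self.times_s.size),
            "trip_events": [{"time_s": t, "channel": ch} for t, ch in self.trip_events],
            "n_trips": len(self.trip_events),
            "oscillation": [bool(b) for b in self.oscillation],
            "peak_i_ma": [float(x) for x in self.i_ma.max(axis=0)],
            "seed": self.seed,
        }


def _detect_oscillation(i_ma: np.ndarray, limit_ma: float, min_cycles: int = 3) -> np.ndarray:
    """Flag channels cycling fully between near-zero and near-limit output."""
    flags = np.zeros(i_ma.shape[1], dtype=bool)
    for ch in range(i_ma.shape[1]):
        x = i_ma[:, ch]
        states = []
        for v in x:
            s = "H" if v >= 0.9 * limit_ma else ("L" if v <= 0.1 * limit_ma else None)
            if s is not None and (not states or states[-1] != s):
                states.append(s)
        transitions = max(len(states) - 1, 0)
        flags[ch] = transitions >= 2 * min_cycles
    return flags


def run_simulation(
    duration_s: float,
    profile: ActivationProfile,
    control: ControlParams,
    stim: StimParams,
    plant: PlantModel,
    watchdog: WatchdogConfig | None = None,
    *,
    emg_rms_mv: float = 0.5,
    seed: int = 0,
    quantize: bool = True,
    smooth: bool = True,
    noise: bool = True,
) -> SimResult:
    """Envelope-level closed-loop run.

    The volitional envelope each period is ``activation(t) * emg_rms_mv``
    plus (optionally) Gaussian measurement noise at the plant's noise
    floor.  Deterministic given ``seed`` and the config snapshot stored in
    the result.
    """
    dt = stim.period_ms * 1e-3
    n_steps = int(duration_s / dt)
    n_ch = len(control.off_mv)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
    state = LoopState.initial(n_ch)
    times = (np.arange(n_steps) + 1) * dt
    v_meas = np.zeros((n_steps, n_ch))
    v_smooth = np.zeros((n_steps, n_ch))
    i_ma = np.zeros((n_steps, n_ch))
    trips: list[tuple[float, int]] = []
    for k in range(n_steps):
        vol = profile(np.array([k * dt]))[:, 0] * emg_rms_mv
        nz = rng.standard_normal(n_ch) * plant.noise_floor_mv if noise else None
        prev_tripped = state.tripped.copy()
        state = step_loop(state, vol, control, stim, plant, watchdog,
                          noise_mv=nz, quantize=quantize, smooth=smooth)
        for ch in np.nonzero(state.tripped & ~prev_tripped)[0]:
            trips.append((state.time_s, int(ch)))
        v_meas[k] = state.v_meas_mv
        v_smooth[k] = state.v_smooth_mv
        i_ma[k] = state.i_ma
    force = recruitment_response(np.clip(i_ma, 0, None), plant) * plant.force_scale_n
    cfg = {
        "duration_s": duration_s,
        "control": control.model_dump(),
        "stim": stim.model_dump(),
        "plant": plant.model_dump(),
        "watchdog": watchdog.model_dump() if watchdog else None,
        "emg_rms_mv": emg_rms_mv,
        "quantize": quantize,
        "smooth": smooth,
        "noise": noise,
        "seed": int(seed),
    }
    return SimResult(times, v_meas, v_smooth, i_ma, force, trips,
                     _detect_oscillation(i_ma, stim.current_limit_ma), int(seed), cfg)


def run_from_snapshot(snapshot: dict, profile: ActivationProfile) -> SimResult:
    """Re-run a simulation bit-exactly from a result's config snapshot."""
    wd = snapshot["watchdog"]
    return run_simulation(
        snapshot["duration_s"], profile,
        ControlParams(**snapshot["control"]),
        StimParams(**snapshot["stim"]),
        PlantModel(**snapshot["plant"]),
        WatchdogConfig(**wd) if wd else None,
        emg_rms_mv=snapshot["emg_rms_mv"], seed=snapshot["seed"],
        quantize=snapshot["quantize"], smooth=snapshot["smooth"],
        noise=snapshot["noise"],
    )


def run_sample_level_simulation(
    duration_s: float,
    profile: ActivationProfile,
    noise_model: NoiseModel,
    artifact: ArtifactModel,
    control: ControlParams,
    stim: StimParams,
    plant: PlantModel,
    watchdog: WatchdogConfig | None = None,
    *,
    fs: float = 1000.0,
    seed: int | None = None,
    include_mains: bool = True,
) -> SimResult:
    """End-to-end loop at the sample level.

    The volitional MES (plus mains) is pre-generated; each period the
    command computed from period k-1 schedules the pulses of period k,
    whose direct artifact and M-wave are injected into the raw samples
    before the firmware pipeline processes them.  With a zero artifact
    model this reduces exactly to the open-loop chain on the volitional
    trace.
    """
    nm = noise_model if seed is None else noise_model.model_copy(update={"rng_seed": int(seed)})
    trace = generate_volitional_mes(profile, nm, duration_s, fs)
    if include_mains and nm.mains_amp_mv > 0:
        trace = add_mains_interference(trace, nm)
    pipe = FirmwarePipeline(control, stim, fs)
    n = pipe.n_period
    n_windows = trace.n_samples // n
    period_s = n / fs
    n_ch = trace.n_channels
    contam = np.zeros_like(trace.samples)
    onsets = _period_pulse_onsets_s(stim)
    state = LoopState.initial(n_ch)
    v_raw = np.zeros((n_windows, n_ch))
    v_smooth = np.zeros((n_windows, n_ch))
    i_ma = np.zeros((n_windows, n_ch))
    trips: list[tuple[float, int]] = []
    prev_cmd = np.zeros(n_ch)
    for w in range(n_windows):
        w_start = w * period_s
        # pulses of this period carry the command from the previous one
        offsets = []
        for onset, ch in onsets:
            amp = float(prev_cmd[ch]) if ch < n_ch else 0.0
            t_ev = w_start + onset
            offsets.append((onset, ch))
            if amp > 0:
                _inject_artifact(contam, trace, t_ev, ch, amp, artifact)
        window = trace.samples[:, w * n:(w + 1) * n] + contam[:, w * n:(w + 1) * n]
        out = pipe.process_period(window, offsets)
        cmd = np.where(state.tripped, 0.0, out.command.currents_ma)
        state = replace(state, time_s=(w + 1) * period_s, v_meas_mv=out.v_raw_mv,
                        v_smooth_mv=out.v_smooth_mv, i_ma=cmd)
        if watchdog is not None:
            prev_tripped = state.tripped.copy()
            state = watchdog_update(state, watchdog, stim, period_s)
            for ch in np.nonzero(state.tripped & ~prev_tripped)[0]:
                trips.append((state.time_s, int(ch)))
        v_raw[w] = out.v_raw_mv
        v_smooth[w] = out.v_smooth_mv
        i_ma[w] = state.i_ma
        prev_cmd = state.i_ma
    force = recruitment_response(np.clip(i_ma, 0, None), plant) * plant.force_scale_n
    times = (np.arange(n_windows) + 1) * period_s
    return SimResult(times, v_raw, v_smooth, i_ma, force, trips,
                     _detect_oscillation(i_ma, stim.current_limit_ma),
                     nm.rng_seed, {"mode": "sample_level"})


def _inject_artifact(contam: np.ndarray, trace: MesTrace, time_s: float,
                     channel: int, amp_ma: float, artifact: ArtifactModel) -> None:
    """Add one pulse's direct transient and M-wave into a contamination buffer."""
    n = contam.shape[1]
    ch = channel % contam.shape[0]
    k = trace.sample_index(time_s)
    a = artifact.direct_artifact_amp_per_ma * amp_ma
    if 0 <= k < n:
        contam[ch, k] += a
    if 0 <= k + 1 < n:
        contam[ch, k + 1] -= a
    m_amp = artifact.mwave_amp(amp_ma)
    if m_amp > 0:
        k0 = trace.sample_index(time_s + artifact.mwave_latency_s)
        k1 = min(n, k0 + int(round(8 * artifact.mwave_tau_s * trace.fs)))
        if k0 < n:
            u = (np.arange(k0, k1) - (time_s + artifact.mwave_latency_s - trace.t0) * trace.fs) / trace.fs
            u = np.maximum(u, 0.0)
            contam[ch, k0:k1] += m_amp * np.exp(-u / artifact.mwave_tau_s) * np.sin(
                2 * np.pi * artifact.mwave_freq_hz * u)
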