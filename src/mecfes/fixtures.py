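"""Deterministic seeded fixture bundles used by the test suite and docs.

Each fixture writes a config JSON (plus trace/event CSVs where relevant)
into a directory; all randomness flows from the config seed so re-running
reproduces the files bit-exactly.
"""

from __future__ import annotations

from pathlib import Path

from .config import RunConfig, save_config
from .io import write_events_csv, write_trace_csv
from .signal_model import ActivationProfile, generate_full_mes
from .stim_engine import periodic_commands, schedule_pulses

__all__ = ["FIXTURES", "make_fixture"]


def _silent(cfg: RunConfig, out: Path) -> None:
    """Zero activation, no mains: the full pipeline must output zero."""
    cfg = cfg.model_copy(deep=True)
    cfg.noise.mains_amp_mv = 0.0
    cfg.noise.movement_artifact_rate_hz = 0.0
    save_config(cfg, out / "config.json")
    trace = generate_full_mes(ActivationProfile.constant(0.0), cfg.noise,
                              cfg.duration_s, cfg.fs)
    write_trace_csv(out / "trace.csv", trace)


def _mains_only(cfg: RunConfig, out: Path) -> None:
    """Pure 50 Hz interference; the comb filter must null it exactly."""
    cfg = cfg.model_copy(deep=True)
    cfg.noise.emg_rms_at_full_activation_mv = 0.0
    cfg.noise.mains_amp_mv = 1.0
    cfg.noise.movement_artifact_rate_hz = 0.0
    save_config(cfg, out / "config.json")
    trace = generate_full_mes(ActivationProfile.constant(0.0), cfg.noise,
                              cfg.duration_s, cfg.fs)
    write_trace_csv(out / "trace.csv", trace)


def _stable_loop(cfg: RunConfig, out: Path) -> None:
    """Loop-gain product 0.5: perturbations decay."""
    cfg = cfg.model_copy(deep=True)
    cfg.plant.residual_artifact_per_ma = 0.5 / cfg.control.gain_ma_per_mv[0][0]
    save_config(cfg, out / "config.json")


def _latchup_loop(cfg: RunConfig, out: Path) -> None:
    """Loop-gain product 1.5: a perturbation grows until the watchdog trips."""
    cfg = cfg.model_copy(deep=True)
    cfg.plant.residual_artifact_per_ma = 1.5 / cfg.control.gain_ma_per_mv[0][0]
    save_config(cfg, out / "config.json")


def _kinematics_default(cfg: RunConfig, out: Path) -> None:
    """Default anthropometric forearm model."""
    save_config(cfg, out / "config.json")


def _with_stim(cfg: RunConfig, out: Path) -> None:
    """Half-activation EMG with a 15 mA stimulation train and artifacts."""
    cfg = cfg.model_copy(deep=True)
    save_config(cfg, out / "config.json")
    sched = schedule_pulses(periodic_commands(15.0, cfg.duration_s, cfg.stim), cfg.stim)
    trace = generate_full_mes(ActivationProfile.constant(0.5), cfg.noise,
                              cfg.duration_s, cfg.fs,
                              schedule=sched, artifact=cfg.artifact)
    write_trace_csv(out / "trace.csv", trace)
    write_events_csv(out / "events.csv", sched)


FIXTURES = {
    "silent": _silent,
    "mains_only": _mains_only,
    "stable_loop": _stable_loop,
    "latchup_loop": _latchup_loop,
    "kinematics_default": _kinematics_default,
    "with_stim": _with_stim,
}


def make_fixture(name: str, out_dir: str | Path, seed: int = 0,
                 duration_s: float = 2.0) -> Path:
    """Write the named fixture bundle; returns its directory."""
    if name not in FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(sorted(FIXTURES))}"
        )
    out = Path(out_dir) / name
    out.mkdir(parents=True, exist_ok=True)
    cfg = RunConfig(seed=seed, duration_s=duration_s)
    cfg.noise.rng_seed = seed
    FIXTURES[name](cfg, out)
    return out
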