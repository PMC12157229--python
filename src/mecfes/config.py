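"""Validated run configuration: one JSON block per parameter group.

``RunConfig`` nests every model the package uses; an empty JSON object
yields the full default configuration, and cross-field constraints that no
single block can check (blanking vs. period, Nyquist vs. EMG band) are
enforced here.
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, Field, model_validator

from .closed_loop import PlantModel, WatchdogConfig
from .dsp_chain import ControlParams
from .elap_kinematics import ForearmModel
from .signal_model import ArtifactModel, NoiseModel
from .stim_engine import StimParams

__all__ = ["RunConfig", "load_config", "save_config"]


class RunConfig(BaseModel):
    noise: NoiseModel = Field(default_factory=NoiseModel)
    artifact: ArtifactModel = Field(default_factory=ArtifactModel)
    stim: StimParams = Field(default_factory=StimParams)
    control: ControlParams = Field(default_factory=ControlParams)
    plant: PlantModel = Field(default_factory=PlantModel)
    watchdog: WatchdogConfig = Field(default_factory=WatchdogConfig)
    forearm: ForearmModel = Field(default_factory=ForearmModel)
    seed: int = 0
    duration_s: float = 10.0
    fs: float = 1000.0

    @model_validator(mode="after")
    def _cross_field(self):
        if self.control.blank_ms >= self.stim.period_ms:
            raise ValueError(
                f"control.blank_ms={self.control.blank_ms:g} must be < "
                f"stim.period_ms={self.stim.period_ms:g}"
            )
        if self.fs < 2 * self.noise.emg_band_hz[1]:
            raise ValueError(
                f"fs={self.fs:g} below Nyquist for EMG band upper corner "
                f"{self.noise.emg_band_hz[1]:g} Hz"
            )
        if self.noise.mains_freq_hz >= self.fs / 2:
            raise ValueError(
                f"noise.mains_freq_hz={self.noise.mains_freq_hz:g} must be < fs/2"
            )
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        return self


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON config; missing blocks get defaults."""
    text = Path(path).read_text()
    return RunConfig.model_validate(json.loads(text) if text.strip() else {})


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(cfg.model_dump_json(indent=2))
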