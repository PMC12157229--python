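"""Forearm pronation-supination kinematics of the two-part electrode
applicator.

The applicator is a proximal ring (PP) below the elbow and a distal ring
(DP) at the wrist, joined by four rigid bars in ball-and-socket hinges.
During pronation/supination the radius rotates about the ulna, so the
distal segment does not turn about the forearm's central axis: its rotation
centre sits roughly one-quarter of the wrist height posterior and
one-quarter of the wrist width external (lateral) to the section centre.
The model captures this as a single-axis approximation: for a rotation
angle theta, PP anchors rotate about the central axis and DP anchors rotate
by the same angle about the offset axis.  The relative bar motion — and
hence the DP-PP distance change and the socket travel the bars need — comes
entirely from the eccentricity between the two axes.

Conventions: x = external/lateral, y = anterior (posterior negative),
z = proximal-to-distal along the forearm axis, lengths in mm, angles in
degrees.  The PP section is a circle of the measured circumference; the DP
section is an ellipse with the wrist width and height as its axes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, model_validator

__all__ = [
    "ForearmModel",
    "BarLinkage",
    "attachment_trajectory",
    "bar_vectors",
    "bar_lengths",
    "dp_pp_distance_variation",
    "required_bar_travel",
    "parametric_dimensions",
    "sweep_table",
]


class ForearmModel(BaseModel):
    """Anthropometric parameters and rotation-axis geometry."""

    separation_mm: float = 180.0          # axial DP-PP distance
    forearm_length_mm: float = 250.0
    pp_circumference_mm: float = 250.0    # typical range 200-300
    dp_wrist_circumference_mm: float = 170.0
    wrist_height_mm: float = 40.0
    wrist_width_mm: float = 60.0
    dp_offset_fraction: float = 0.25      # quarter posterior / quarter external
    rotation_range_deg: tuple[float, float] = (0.0, 110.0)
    bar_anchor_angles_deg: tuple[float, ...] = (45.0, 135.0, 225.0, 315.0)

    @property
    def pp_radius_mm(self) -> float:
        return self.pp_circumference_mm / (2 * np.pi)

    @property
    def dp_semi_axes_mm(self) -> tuple[float, float]:
        """(external, anterior) semi-axes of the elliptical DP section."""
        return self.wrist_width_mm / 2, self.wrist_height_mm / 2

    @property
    def dp_center_offset_mm(self) -> np.ndarray:
        """DP rotation centre: quarter-width external, quarter-height posterior."""
        return np.array([self.wrist_width_mm * self.dp_offset_fraction,
                         -self.wrist_height_mm * self.dp_offset_fraction])

    @model_validator(mode="after")
    def _check(self):
        for name in ("separation_mm", "forearm_length_mm", "pp_circumference_mm",
                     "dp_wrist_circumference_mm", "wrist_height_mm", "wrist_width_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.separation_mm > self.forearm_length_mm:
            raise ValueError(
                f"separation_mm={self.separation_mm:g} exceeds "
                f"forearm_length_mm={self.forearm_length_mm:g}"
            )
        lo, hi = self.rotation_range_deg
        if not (0 <= lo < hi <= 180):
            raise ValueError("rotation_range_deg must lie within [0, 180]")
        a, b = self.dp_semi_axes_mm
        ox, oy = self.dp_center_offset_mm
        if (ox / a) ** 2 + (oy / b) ** 2 >= 1:
            raise ValueError("DP rotation centre falls outside the DP cross-section")
        return self


def _rot2(angle_deg: float) -> np.ndarray:
    th = np.deg2rad(angle_deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, -s], [s, c]])


def _pp_anchors_xy(model: ForearmModel) -> np.ndarray:
    phi = np.deg2rad(np.asarray(model.bar_anchor_angles_deg))
    return model.pp_radius_mm * np.column_stack([np.cos(phi), np.sin(phi)])


def _dp_anchors_xy(model: ForearmModel) -> np.ndarray:
    a, b = model.dp_semi_axes_mm
    phi = np.deg2rad(np.asarray(model.bar_anchor_angles_deg))
    return np.column_stack([a * np.cos(phi), b * np.sin(phi)])


def attachment_trajectory(model: ForearmModel, angle_deg: float) -> dict[str, np.ndarray]:
    """Bar anchor coordinates at a pronation/supination angle.

    PP anchors (z = 0) rotate about the central axis; DP anchors
    (z = separation) rotate about the offset axis.  Returns ``{"pp": (n, 3),
    "dp": (n, 3)}``.
    """
    lo, hi = model.rotation_range_deg
    if not (lo <= angle_deg <= hi):
        raise ValueError(f"angle {angle_deg:g} outside rotation range [{lo:g}, {hi:g}]")
    r = _rot2(angle_deg)
    pp = _pp_anchors_xy(model) @ r.T
    c = model.dp_center_offset_mm
    dp = (_dp_anchors_xy(model) - c) @ r.T + c
    n = pp.shape[0]
    pp3 = np.column_stack([pp, np.zeros(n)])
    dp3 = np.column_stack([dp, np.full(n, model.separation_mm)])
    return {"pp": pp3, "dp": dp3}


def bar_vectors(model: ForearmModel, angle_deg: float) -> np.ndarray:
    """Vectors from each PP anchor to its DP anchor at the given angle."""
    pts = attachment_trajectory(model, angle_deg)
    return pts["dp"] - pts["pp"]


def bar_lengths(model: ForearmModel, angle_deg: float) -> np.ndarray:
    return np.linalg.norm(bar_vectors(model, angle_deg), axis=1)


@dataclass(frozen=True)
class BarLinkage:
    """Reference-configuration bar geometry (anchors and lengths)."""

    pp_anchors_mm: np.ndarray
    dp_anchors_mm: np.ndarray
    lengths_mm: np.ndarray

    @classmethod
    def from_model(cls, model: ForearmModel) -> "BarLinkage":
        lo = model.rotation_range_deg[0]
        pts = attachment_trajectory(model, lo)
        return cls(pts["pp"], pts["dp"],
                   np.linalg.norm(pts["dp"] - pts["pp"], axis=1))


def _sweep_angles(model: ForearmModel, step_deg: float,
                  hi: float | None = None) -> np.ndarray:
    lo = model.rotation_range_deg[0]
    hi = model.rotation_range_deg[1] if hi is None else hi
    n = int(np.ceil((hi - lo) / step_deg)) + 1
    return np.linspace(lo, hi, n)


def dp_pp_distance_variation(model: ForearmModel, step_deg: float = 1.0) -> float:
    """Maximum peak-to-peak change of any bar's anchor-to-anchor distance
    (mm) over the full rotation range, swept at <= ``step_deg``."""
    angles = _sweep_angles(model, step_deg)
    lengths = np.array([bar_lengths(model, a) for a in angles])
    return float(np.max(lengths.max(axis=0) - lengths.min(axis=0)))


def required_bar_travel(model: ForearmModel, max_rotation_deg: float,
                        step_deg: float = 1.0) -> float:
    """Largest socket deflection (degrees) any bar needs for rotations up to
    ``max_rotation_deg``: the angle between a bar's direction at angle theta
    and its reference direction at the start of the rotation range."""
    if not (0 <= max_rotation_deg <= 180):
        raise ValueError("max_rotation_deg must lie in [0, 180]")
    lo = model.rotation_range_deg[0]
    ref = bar_vectors(model, lo)
    ref_unit = ref / np.linalg.norm(ref, axis=1, keepdims=True)
    worst = 0.0
    for a in _sweep_angles(model, step_deg, hi=max(lo, max_rotation_deg)):
        v = bar_vectors(model, a)
        v_unit = v / np.linalg.norm(v, axis=1, keepdims=True)
        cosang = np.clip(np.sum(v_unit * ref_unit, axis=1), -1.0, 1.0)
        worst = max(worst, float(np.degrees(np.arccos(cosang)).max()))
    return worst


_ANATOMICAL_RANGES = {
    "pp_circumference_mm": (200.0, 300.0),
    "dp_wrist_circumference_mm": (130.0, 220.0),
    "wrist_height_mm": (30.0, 60.0),
    "wrist_width_mm": (40.0, 80.0),
    "forearm_length_mm": (180.0, 300.0),
    "separation_mm": (100.0, 250.0),
}


def parametric_dimensions(measurements: dict[str, float] | None = None) -> ForearmModel:
    """Build a validated model from named measurements (mm).

    Missing values fall back to the defaults.  Values outside typical adult
    anatomical ranges raise a warning (not an error); inconsistent values
    (e.g. separation longer than the forearm) raise a validation error.
    """
    measurements = dict(measurements or {})
    for name, value in measurements.items():
        if value is not None and value <= 0:
            raise ValueError(f"{name} must be positive, got {value:g}")
        rng = _ANATOMICAL_RANGES.get(name)
        if rng and not (rng[0] <= value <= rng[1]):
            warnings.warn(
                f"{name}={value:g} mm outside typical anatomical range "
                f"[{rng[0]:g}, {rng[1]:g}] mm", stacklevel=2,
            )
    return ForearmModel(**measurements)


def sweep_table(model: ForearmModel, step_deg: float = 1.0) -> pd.DataFrame:
    """Angle-by-angle bar distances and deflections (for CSV export)."""
    lo = model.rotation_range_deg[0]
    ref = bar_vectors(model, lo)
    ref_unit = ref / np.linalg.norm(ref, axis=1, keepdims=True)
    rows = []
    for a in _sweep_angles(model, step_deg):
        v = bar_vectors(model, a)
        lens = np.linalg.norm(v, axis=1)
        v_unit = v / lens[:, None]
        defl = np.degrees(np.arccos(np.clip(np.sum(v_unit * ref_unit, axis=1), -1, 1)))
        for b in range(v.shape[0]):
            rows.append({"angle_deg": a, "bar": b,
                         "distance_mm": lens[b], "deflection_deg": defl[b]})
    return pd.DataFrame(rows)
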