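"""Volume measurement and accuracy/repeatability statistics.

Definitions used throughout:

* volume of a binary mask = number of voxels whose centers lie inside the
  volume of interest (VOI), times spacing^3;
* coefficient of variation (CV) = 100 * sample SD / mean of the repeated
  measurements (sample SD, n-1 denominator, configurable);
* systematic error = mean measured volume - control volume; relative
  systematic error = 100 * systematic error / control volume.

Control volumes for cylindrical defects are pi r^2 h; ``pi_mode`` lets the
report reproduce the 2-decimal convention (pi = 3.14) used by the bench
protocol this package emulates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import UndefinedStatisticError
from .grid import VoxelGrid


def measure_volume(mask: VoxelGrid, voi="all", axis: int = 0) -> float:
    """Volume (mm^3) of a binary mask inside a VOI.

    ``voi`` is either ``"all"`` or a half-open physical range
    ``(lo_mm, hi_mm)`` along ``axis``; a voxel counts iff its center
    satisfies ``lo <= c < hi``.  An empty VOI yields zero with a warning.
    """
    data = np.moveaxis(np.asarray(mask.data, dtype=bool), axis, 0)
    if voi == "all" or voi is None:
        count = int(data.sum())
    else:
        lo, hi = float(voi[0]), float(voi[1])
        coords = mask.coords(axis)
        sel = (coords >= lo) & (coords < hi)
        if not sel.any():
            warnings.warn(f"VOI [{lo}, {hi}) mm selects no slices", stacklevel=2)
            return 0.0
        count = int(data[sel].sum())
    return count * mask.voxel_volume


def _round_half_up(x: float, ndigits: int = 2) -> float:
    scale = 10**ndigits
    return math.floor(x * scale + 0.5) / scale


def control_volume_cylinder(
    diameter: float, height: float, pi_mode: str = "full"
) -> float:
    """Analytic cylinder volume pi (d/2)^2 h.

    ``pi_mode="paper_2dp"`` uses pi truncated to 3.14 and rounds the result
    half-up to two decimals, reproducing printed bench-protocol controls
    (e.g. 98.13 mm^3 for d = 5, h = 5); ``"full"`` returns the
    full-precision value.
    """
    if diameter <= 0 or height <= 0:
        raise ValueError("diameter and height must be positive")
    if pi_mode == "full":
        return math.pi * (diameter / 2.0) ** 2 * height
    if pi_mode == "paper_2dp":
        return _round_half_up(3.14 * (diameter / 2.0) ** 2 * height, 2)
    raise ValueError(f"unknown pi_mode {pi_mode!r}")


def coefficient_of_variation(values, ddof: int = 1) -> float:
    """CV in percent: 100 * sample SD / mean."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise UndefinedStatisticError("CV needs at least two values")
    mean = values.mean()
    if mean == 0:
        raise UndefinedStatisticError("CV undefined for zero mean")
    return float(100.0 * values.std(ddof=ddof) / mean)


def cv_from_mean_sd(mean: float, sd: float) -> float:
    """CV in percent from an already-computed mean and SD."""
    if mean == 0:
        raise UndefinedStatisticError("CV undefined for zero mean")
    return 100.0 * sd / mean


def systematic_error(test_mean: float, control: float) -> tuple[float, float]:
    """(absolute, relative-percent) systematic error of a test mean."""
    if control == 0:
        raise ValueError("control volume must be non-zero")
    err = test_mean - control
    return err, 100.0 * err / control


def merge_angle_measurements(per_angle_volumes: dict) -> tuple[list, dict]:
    """Pool repeat volumes measured at several mounting angles.

    Returns the concatenation (repeat order preserved within each angle)
    plus the per-angle means kept for the angle-insensitivity check.
    """
    if not per_angle_volumes:
        raise ValueError("need at least one angle")
    pooled = []
    per_angle_means = {}
    for angle in sorted(per_angle_volumes):
        vols = list(per_angle_volumes[angle])
        pooled.extend(vols)
        per_angle_means[angle] = float(np.mean(vols))
    return pooled, per_angle_means


@dataclass
class MeasurementReport:
    """Per-phantom, per-method summary of repeated volume measurements."""

    phantom: str
    method: str  # "mci" | "manual"
    volumes: list
    control_volume: float
    mean: float = field(init=False)
    sd: float = field(init=False)
    min: float = field(init=False)
    max: float = field(init=False)
    cv: float = field(init=False)
    systematic_error: float = field(init=False)
    relative_systematic_error: float = field(init=False)
    per_angle_means: Optional[dict] = None
    ddof: int = 1

    def __post_init__(self):
        vols = np.asarray(self.volumes, dtype=float)
        if vols.size < 1:
            raise UndefinedStatisticError("report needs at least one volume")
        self.mean = float(vols.mean())
        self.sd = float(vols.std(ddof=self.ddof)) if vols.size > 1 else 0.0
        self.min = float(vols.min())
        self.max = float(vols.max())
        self.cv = cv_from_mean_sd(self.mean, self.sd)
        self.systematic_error, self.relative_systematic_error = systematic_error(
            self.mean, self.control_volume
        )
        self._check()

    def _check(self) -> None:
        assert self.min <= self.mean <= self.max
        assert math.isclose(self.cv, 100.0 * self.sd / self.mean, rel_tol=1e-9)
        assert math.isclose(
            self.systematic_error, self.mean - self.control_volume, rel_tol=1e-9,
            abs_tol=1e-12,
        )

    def to_row(self) -> dict:
        """One table row, volumes rounded to two decimals as in exports."""
        return {
            "phantom": self.phantom,
            "method": self.method,
            "n": len(self.volumes),
            "mean": round(self.mean, 2),
            "sd": round(self.sd, 2),
            "min": round(self.min, 2),
            "max": round(self.max, 2),
            "cv_pct": round(self.cv, 2),
            "control": round(self.control_volume, 2),
            "systematic_error": round(self.systematic_error, 2),
            "relative_systematic_error_pct": round(self.relative_systematic_error, 2),
        }


def reports_to_frame(reports) -> pd.DataFrame:
    """Stack reports into a tidy DataFrame (one row per phantom x method)."""
    return pd.DataFrame([r.to_row() for r in reports])
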