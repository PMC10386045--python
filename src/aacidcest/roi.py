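"""ROI summary statistics, time courses, percent change and ΔpH conversion.

Mirrors the figure-level analysis of an AACID study: region means with SEM
error bars, percent change of post-injection AACID versus baseline, its
conversion to a pH change through the linear calibration, and tumor volume
from a segmentation mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mapping import CalibrationParams, ParametricMap

__all__ = [
    "ROISet",
    "ROITimecourse",
    "roi_stats",
    "percent_change",
    "delta_ph",
    "tumor_volume",
    "build_timecourse",
    "threshold_mask",
]


@dataclass
class ROISet:
    """Named boolean voxel masks on a stated grid."""

    masks: dict[str, np.ndarray]
    voxel_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.masks = {k: np.asarray(v, dtype=bool) for k, v in self.masks.items()}
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError("all masks must share one grid")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    @property
    def names(self) -> list[str]:
        return list(self.masks)


@dataclass
class ROITimecourse:
    """Per-timepoint ROI statistics with percent change versus baseline."""

    roi: str
    timepoints: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    sem: np.ndarray
    n: np.ndarray
    pct_change: np.ndarray = field(default=None)  # vs first timepoint

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi": self.roi,
                "time": self.timepoints,
                "mean": self.mean,
                "sd": self.sd,
                "sem": self.sem,
                "n": self.n,
                "pct_change": self.pct_change,
            }
        )


def roi_stats(pmap: ParametricMap, mask: np.ndarray) -> tuple[float, float, float, int]:
    """(mean, SD, SEM, n_valid) of map values over valid voxels in *mask*.

    SD is the sample standard deviation (ddof=1; 0 for a single voxel) and
    SEM = SD/√n.  Raises if the mask contains no valid voxel.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != pmap.values.shape:
        raise ValueError("mask grid does not match map grid")
    sel = mask & pmap.valid
    n = int(sel.sum())
    if n == 0:
        raise ValueError("mask contains no valid voxels")
    v = pmap.values[sel]
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if n > 1 else 0.0
    return mean, sd, sd / np.sqrt(n), n


def percent_change(pre_mean: float, post_mean: float) -> float:
    """100·(post − pre)/pre; raises on a zero baseline."""
    if pre_mean == 0:
        raise ValueError("percent change undefined for zero baseline")
    return 100.0 * (post_mean - pre_mean) / pre_mean


def delta_ph(
    aacid_pre: float, aacid_post: float, cal: CalibrationParams | None = None
) -> float:
    """pH change implied by an AACID change through the linear calibration.

    ΔpH = slope·ΔAACID; with the default slope −4, a +0.0775 AACID change
    maps to a 0.31 pH decrease.
    """
    cal = cal if cal is not None else CalibrationParams()
    return cal.slope * (aacid_post - aacid_pre)


def tumor_volume(mask: np.ndarray, voxel_mm: tuple[float, float, float]) -> float:
    """Mask volume in mm³ = voxel count × voxel volume."""
    if voxel_mm is None or len(voxel_mm) != 3:
        raise ValueError("voxel dimensions (dx, dy, dz) in mm are required")
    return float(np.count_nonzero(mask)) * float(np.prod(voxel_mm))


def build_timecourse(
    maps: dict[float, ParametricMap], mask: np.ndarray, roi_name: str = "roi"
) -> ROITimecourse:
    """ROI statistics at each timepoint, ordered, with percent change vs t₀.

    *maps* maps timepoint (minutes or days) to a parametric map; at least
    two distinct timepoints are required.
    """
    times = np.asarray(sorted(maps), dtype=float)
    if times.size < 2:
        raise ValueError("a timecourse needs at least two timepoints")
    if np.unique(times).size != times.size:
        raise ValueError("duplicate timepoints")
    stats = [roi_stats(maps[t], mask) for t in times]
    mean = np.array([s[0] for s in stats])
    sd = np.array([s[1] for s in stats])
    sem = np.array([s[2] for s in stats])
    n = np.array([s[3] for s in stats])
    pct = np.array([percent_change(mean[0], m) for m in mean])
    return ROITimecourse(roi_name, times, mean, sd, sem, n, pct)


def threshold_mask(image: np.ndarray, threshold: float, above: bool = True) -> np.ndarray:
    """Demonstration-only mask tool: threshold a label/anatomical image.

    Phantom truth masks are the intended ROI source; this exists so the ROI
    machinery can be exercised on an image without ground truth.
    """
    image = np.asarray(image, dtype=float)
    return image > threshold if above else image < threshold
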