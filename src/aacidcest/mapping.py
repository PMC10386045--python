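"""AACID statistic and pH calibration, pixel-wise parametric maps.

AACID (amine/amide concentration-independent detection) is the ratiometric
CEST statistic

    AACID = Mz(3.5) · (Mz(6.0) − Mz(2.75)) / [ Mz(2.75) · (Mz(6.0) − Mz(3.5)) ]

built from the B0-corrected Z-spectrum at the amide (3.5 ppm) and amine
(2.75 ppm) resonances with 6.0 ppm as reference point.  It is inversely
related to intracellular pH and converts to pH through the linear
mouse-brain calibration pH = −4·AACID + 12.8.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stack import ZSpectrumStack
from .zspec import AACID_SAMPLE_PPM, B0Map, ContinuousSpectrum, DomainError, fit_spline

__all__ = [
    "InvalidVoxelError",
    "AACIDSamples",
    "CalibrationParams",
    "ParametricMap",
    "sample_mz",
    "compute_aacid",
    "aacid_to_ph",
    "make_maps",
]


class InvalidVoxelError(ValueError):
    """The AACID ratio is undefined at this voxel (degenerate denominator)."""


@dataclass(frozen=True)
class AACIDSamples:
    """The three Mz readouts entering the AACID ratio."""

    mz_amine: float  # z at 2.75 ppm
    mz_amide: float  # z at 3.5 ppm
    mz_ref: float  # z at 6.0 ppm

    def __post_init__(self) -> None:
        for v in (self.mz_amine, self.mz_amide, self.mz_ref):
            if not np.isfinite(v) or not 0.0 <= v <= 1.5:
                raise ValueError("Mz samples must be finite and in [0, 1.5]")


@dataclass(frozen=True)
class CalibrationParams:
    """Linear AACID→pH calibration (mouse brain): pH = slope·AACID + intercept."""

    slope: float = -4.0
    intercept: float = 12.8

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("calibration slope must be nonzero")


@dataclass
class ParametricMap:
    """Per-voxel scalar map with validity mask; NaN marks invalid voxels."""

    values: np.ndarray
    valid: np.ndarray
    voxel_mm: tuple[float, float, float] = (0.4, 0.4, 2.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and validity grids differ")
        if not np.all(np.isfinite(self.values[self.valid])):
            raise ValueError("valid voxels must be finite")


def sample_mz(spectrum: ContinuousSpectrum, ppm: float) -> float:
    """Mz readout: the 1-Hz-grid value nearest *ppm* (DomainError outside)."""
    return spectrum.sample(ppm)


def compute_aacid(s: AACIDSamples) -> float:
    """Evaluate the AACID ratio; raises InvalidVoxelError when degenerate."""
    denom = s.mz_amine * (s.mz_ref - s.mz_amide)
    if s.mz_amine == 0 or s.mz_ref == s.mz_amide or denom == 0:
        raise InvalidVoxelError("AACID denominator is zero")
    return s.mz_amide * (s.mz_ref - s.mz_amine) / denom


def aacid_to_ph(aacid: float, cal: CalibrationParams | None = None) -> float:
    """pH from AACID via the linear calibration (exact affine map)."""
    cal = cal if cal is not None else CalibrationParams()
    return cal.slope * aacid + cal.intercept


def make_maps(
    cest: ZSpectrumStack,
    b0map: B0Map | None = None,
    cal: CalibrationParams | None = None,
    smoothing: float | str | None = "gcv",
) -> tuple[ParametricMap, ParametricMap]:
    """Pixel-wise AACID and pH maps from a normalized, averaged CEST stack.

    Each voxel's spectrum is spline-fit, B0-shifted with the voxel's WASSR
    shift (when a B0 map is given), read out at 2.75/3.5/6.0 ppm on the
    1-Hz grid, and pushed through the AACID ratio and the calibration.
    Degenerate or out-of-domain voxels are flagged invalid (NaN sentinel),
    never raised.
    """
    if not cest.normalized:
        raise ValueError("CEST stack must be normalized before mapping")
    cal = cal if cal is not None else CalibrationParams()
    nx, ny = cest.grid
    aacid = np.full((nx, ny), np.nan)
    valid = np.zeros((nx, ny), dtype=bool)
    for i in range(nx):
        for j in range(ny):
            if not cest.valid[i, j]:
                continue
            if b0map is not None and not b0map.valid[i, j]:
                continue
            shift = float(b0map.shift_ppm[i, j]) if b0map is not None else 0.0
            try:
                cs = fit_spline(cest.offsets_ppm, cest.data[i, j], cest.field_mhz, smoothing)
                cs = cs.shifted(shift)
                lo, hi = cs.domain
                if any(p < lo or p > hi for p in AACID_SAMPLE_PPM):
                    raise DomainError("AACID sample outside corrected domain")
                s = AACIDSamples(
                    mz_amine=sample_mz(cs, 2.75),
                    mz_amide=sample_mz(cs, 3.5),
                    mz_ref=sample_mz(cs, 6.0),
                )
                aacid[i, j] = compute_aacid(s)
                valid[i, j] = True
            except (DomainError, InvalidVoxelError, ValueError):
                continue
    ph = np.where(valid, cal.slope * aacid + cal.intercept, np.nan)
    return (
        ParametricMap(values=aacid, valid=valid, voxel_mm=cest.voxel_mm),
        ParametricMap(values=ph, valid=valid.copy(), voxel_mm=cest.voxel_mm),
    )
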