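"""Z-spectrum processing: normalization, repeat averaging, smoothing-spline
fitting, 1-Hz interpolation and WASSR B0 estimation/correction.

The processing chain is: divide each voxel by its unsaturated reference
signal, average the repeat acquisitions, fit a smoothing spline through the
sampled offsets, resample it on a grid with 1-Hz spacing (1/field_mhz ppm),
and shift each voxel's CEST spectrum by the water-center offset found as the
minimum of its WASSR spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import make_interp_spline, make_smoothing_spline

from .stack import ZSpectrumStack

__all__ = [
    "DomainError",
    "ContinuousSpectrum",
    "B0Map",
    "normalize_by_reference",
    "average_repeats",
    "fit_spline",
    "estimate_b0",
    "estimate_b0_map",
    "apply_b0_correction",
]

#: Sampling points (ppm) the AACID statistic needs; a B0-corrected spectrum
#: must still cover these.
AACID_SAMPLE_PPM = (2.75, 3.5, 6.0)


class DomainError(ValueError):
    """Evaluation requested outside a spectrum's valid ppm domain."""


@dataclass
class ContinuousSpectrum:
    """Evaluable Z-spectrum with a native 1-Hz resolution grid.

    Wraps a spline over a stated ppm domain; ``shift_ppm`` realizes B0
    correction lazily: evaluating at ω reads the underlying spline at
    ω + shift, and the stated domain is contracted accordingly.
    """

    spline: object
    domain: tuple[float, float]
    field_mhz: float
    shift_ppm: float = 0.0

    def __post_init__(self) -> None:
        if self.domain[1] <= self.domain[0]:
            raise ValueError("empty spectrum domain")
        self._grid = None
        self._grid_values = None

    @property
    def resolution_ppm(self) -> float:
        """1 Hz expressed in ppm at this field."""
        return 1.0 / self.field_mhz

    def __call__(self, ppm):
        ppm = np.asarray(ppm, dtype=float)
        lo, hi = self.domain
        if np.any(ppm < lo - 1e-12) or np.any(ppm > hi + 1e-12):
            raise DomainError(f"evaluation outside spectrum domain [{lo:.4g}, {hi:.4g}] ppm")
        return np.asarray(self.spline(ppm + self.shift_ppm), dtype=float)

    def grid_ppm(self) -> np.ndarray:
        """The 1-Hz grid, endpoints snapped inside the domain."""
        if self._grid is None:
            lo, hi = self.domain
            step = self.resolution_ppm
            n = int(np.floor((hi - lo) / step + 1e-9)) + 1
            self._grid = lo + step * np.arange(n)
        return self._grid

    def grid_values(self) -> np.ndarray:
        if self._grid_values is None:
            self._grid_values = self(self.grid_ppm())
        return self._grid_values

    def sample(self, ppm: float) -> float:
        """Value at the 1-Hz grid point nearest *ppm* (≤ half-step away)."""
        grid = self.grid_ppm()
        lo, hi = self.domain
        if ppm < lo - 1e-12 or ppm > hi + 1e-12:
            raise DomainError(f"{ppm} ppm outside spectrum domain [{lo:.4g}, {hi:.4g}]")
        i = int(np.argmin(np.abs(grid - ppm)))
        return float(self.grid_values()[i])

    def shifted(self, shift_ppm: float) -> "ContinuousSpectrum":
        lo, hi = self.domain
        return ContinuousSpectrum(
            spline=self.spline,
            domain=(lo - shift_ppm, hi - shift_ppm),
            field_mhz=self.field_mhz,
            shift_ppm=self.shift_ppm + shift_ppm,
        )


@dataclass
class B0Map:
    """Per-voxel water-center shift (ppm) with a validity mask."""

    shift_ppm: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.shift_ppm = np.asarray(self.shift_ppm, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.shift_ppm.shape != self.valid.shape:
            raise ValueError("shift and validity grids differ")


def normalize_by_reference(stack: ZSpectrumStack) -> ZSpectrumStack:
    """Divide each voxel by the mean of its reference frames.

    Reference frames are removed from the offsets axis.  Voxels whose
    reference signal is not strictly positive are flagged invalid (their
    spectra set to NaN) rather than raising for the whole stack.
    """
    ref_sel = stack.is_reference_frame
    if not ref_sel.any():
        raise ValueError("stack has no reference frames to normalize by")
    ref = stack.data[:, :, ref_sel].mean(axis=2)
    valid = stack.valid & (ref > 0) & np.isfinite(ref)
    data = stack.data[:, :, ~ref_sel].copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        data /= ref[:, :, None]
    data[~valid] = np.nan
    return ZSpectrumStack(
        data=data,
        offsets_ppm=stack.offsets_ppm[~ref_sel],
        field_mhz=stack.field_mhz,
        voxel_mm=stack.voxel_mm,
        reference_offsets_ppm=np.array([]),
        normalized=True,
        valid=valid,
    )


def average_repeats(stacks: list[ZSpectrumStack]) -> ZSpectrumStack:
    """Voxel-wise arithmetic mean of repeat acquisitions.

    All stacks must share grid, offsets and field; voxels invalid in any
    repeat stay invalid.
    """
    if not stacks:
        raise ValueError("no stacks to average")
    first = stacks[0]
    for s in stacks[1:]:
        if s.grid != first.grid or not np.allclose(s.offsets_ppm, first.offsets_ppm):
            raise ValueError("repeat stacks differ in geometry or offsets")
        if s.field_mhz != first.field_mhz:
            raise ValueError("repeat stacks differ in field strength")
    valid = np.logical_and.reduce([s.valid for s in stacks])
    data = np.mean([s.data for s in stacks], axis=0)
    data[~valid] = np.nan
    return replace(first.copy(), data=data, valid=valid)


def fit_spline(
    offsets_ppm: np.ndarray,
    values: np.ndarray,
    field_mhz: float,
    smoothing: float | str | None = "gcv",
) -> ContinuousSpectrum:
    """Fit a smoothing spline through one voxel's Z-spectrum samples.

    smoothing: "gcv" (default) picks the penalty by generalized
    cross-validation; 0 or "none" interpolates the samples exactly; a
    positive float is used as the penalty directly.  At least 4 distinct,
    strictly monotone offsets are required.
    """
    x = np.asarray(offsets_ppm, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise ValueError("spline fitting needs at least 4 offsets")
    d = np.diff(x)
    if np.all(d < 0):
        x, y = x[::-1], y[::-1]
    elif not np.all(d > 0):
        raise ValueError("offsets must be strictly monotone")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite spectrum values")
    if smoothing in (0, 0.0, "none", None):
        spline = make_interp_spline(x, y, k=3)
    elif smoothing == "gcv":
        spline = make_smoothing_spline(x, y)
    else:
        lam = float(smoothing)
        if lam < 0:
            raise ValueError("smoothing penalty must be >= 0")
        spline = make_smoothing_spline(x, y, lam=lam)
    return ContinuousSpectrum(spline=spline, domain=(float(x[0]), float(x[-1])), field_mhz=field_mhz)


def estimate_b0(
    offsets_ppm: np.ndarray,
    values: np.ndarray,
    field_mhz: float,
    smoothing: float | str | None = "gcv",
    tie_tol: float = 1e-4,
) -> float:
    """Water-center shift (ppm) from one voxel's WASSR spectrum.

    The shift is the argmin of the 1-Hz-interpolated spline over the
    sampled domain; among minima within *tie_tol* of the global minimum the
    one nearest 0 ppm wins.  A minimum attained at the domain boundary means
    the water line is not bracketed: ``DomainError`` is raised so callers
    can flag the voxel invalid.
    """
    cs = fit_spline(offsets_ppm, values, field_mhz, smoothing)
    grid = cs.grid_ppm()
    z = cs.grid_values()
    zmin = z.min()
    candidates = grid[z <= zmin + tie_tol]
    shift = float(candidates[np.argmin(np.abs(candidates))])
    i_min = int(np.argmin(z))
    if i_min == 0 or i_min == z.size - 1:
        raise DomainError("WASSR minimum at domain boundary; shift not bracketed")
    return shift


def estimate_b0_map(
    wassr: ZSpectrumStack, smoothing: float | str | None = "gcv"
) -> B0Map:
    """Pixel-by-pixel WASSR B0 estimation over a normalized stack."""
    nx, ny = wassr.grid
    shift = np.full((nx, ny), np.nan)
    valid = np.zeros((nx, ny), dtype=bool)
    for i in range(nx):
        for j in range(ny):
            if not wassr.valid[i, j]:
                continue
            try:
                shift[i, j] = estimate_b0(
                    wassr.offsets_ppm, wassr.data[i, j], wassr.field_mhz, smoothing
                )
                valid[i, j] = True
            except (DomainError, ValueError):
                continue
    return B0Map(shift_ppm=shift, valid=valid)


def apply_b0_correction(
    spectrum: ContinuousSpectrum,
    shift_ppm: float,
    required_ppm: tuple[float, ...] = AACID_SAMPLE_PPM,
) -> ContinuousSpectrum:
    """Frequency-shift a CEST spectrum by the WASSR-estimated water offset.

    A voxel whose water center sits at +Δ ppm has its spectrum read out at
    ω + Δ: corrected(ω) = original(ω + Δ).  Raises ``DomainError`` when any
    required sampling point leaves the contracted domain.
    """
    corrected = spectrum.shifted(shift_ppm)
    lo, hi = corrected.domain
    for p in required_ppm:
        if p < lo or p > hi:
            raise DomainError(
                f"required sample {p} ppm outside corrected domain [{lo:.3g}, {hi:.3g}]"
            )
    return corrected
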