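"""In-memory container for Z-spectrum image stacks.

A stack is a 2-D image grid with one saturation frame per offset along the
last axis.  Raw stacks carry the reference frames (±1000 ppm) at the end of
the frame axis; normalization divides by the per-voxel reference mean and
drops those frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ZSpectrumStack"]


@dataclass
class ZSpectrumStack:
    """Per-voxel saturation signal across offsets.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, n_frames)
        Signal per voxel per saturation frame.
    offsets_ppm : ndarray, shape (n_frames,)
        Saturation offset of each frame (ppm from water); for raw stacks the
        reference offsets appear here too, in acquisition order.
    reference_offsets_ppm : ndarray
        Offsets that are unsaturated reference frames (subset of
        ``offsets_ppm`` for raw stacks, empty once normalized).
    field_mhz : float
        Water resonance frequency (MHz); ppm↔Hz conversion factor.
    voxel_mm : tuple of float
        Voxel dimensions (dx, dy, dz) in mm.
    normalized : bool
        True once divided by the reference signal.
    valid : ndarray of bool, shape (nx, ny)
        Per-voxel validity; normalization and B0 estimation flag voxels
        here instead of raising.
    """

    data: np.ndarray
    offsets_ppm: np.ndarray
    field_mhz: float
    voxel_mm: tuple[float, float, float] = (0.4, 0.4, 2.0)
    reference_offsets_ppm: np.ndarray = field(default_factory=lambda: np.array([]))
    normalized: bool = False
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.offsets_ppm = np.asarray(self.offsets_ppm, dtype=float)
        self.reference_offsets_ppm = np.asarray(self.reference_offsets_ppm, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (nx, ny, n_frames)")
        if self.data.shape[2] != self.offsets_ppm.size:
            raise ValueError(
                f"frame count {self.data.shape[2]} does not match "
                f"{self.offsets_ppm.size} listed offsets"
            )
        if self.valid is None:
            self.valid = np.ones(self.data.shape[:2], dtype=bool)
        if not np.all(np.isfinite(self.data[self.valid])):
            raise ValueError("stack data contain non-finite values in valid voxels")
        if self.normalized:
            v = self.data[self.valid]
            if v.size and (v.min() < 0.0 or v.max() > 1.5):
                raise ValueError("normalized stack values must lie in [0, 1.5]")

    @property
    def grid(self) -> tuple[int, int]:
        return self.data.shape[0], self.data.shape[1]

    @property
    def is_reference_frame(self) -> np.ndarray:
        """Boolean mask over frames marking reference acquisitions."""
        if self.reference_offsets_ppm.size == 0:
            return np.zeros(self.offsets_ppm.size, dtype=bool)
        return np.isin(self.offsets_ppm, self.reference_offsets_ppm)

    def copy(self) -> "ZSpectrumStack":
        return replace(
            self,
            data=self.data.copy(),
            offsets_ppm=self.offsets_ppm.copy(),
            reference_offsets_ppm=self.reference_offsets_ppm.copy(),
            valid=self.valid.copy(),
        )
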