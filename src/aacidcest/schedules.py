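"""Saturation schedules for CEST and WASSR acquisitions.

A schedule is the ordered list of RF saturation offsets (ppm relative to
water) swept during one Z-spectrum acquisition, together with the CW pulse
amplitude/duration and any far off-resonance reference offsets used for
normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SaturationSchedule", "make_offset_schedule", "cest_schedule", "wassr_schedule"]


@dataclass(frozen=True)
class SaturationSchedule:
    """CW saturation sweep: sampled offsets plus reference frames.

    Parameters
    ----------
    offsets_ppm : array of float
        Strictly monotone saturation offsets, ppm relative to water.
    reference_offsets_ppm : array of float
        Far off-resonance offsets (e.g. ±1000 ppm) acquired as unsaturated
        reference images; must lie outside the sampled range.
    b1_amplitude : float
        CW pulse amplitude in μT (≥ 0).
    sat_duration : float
        CW pulse duration in seconds (> 0).
    """

    offsets_ppm: np.ndarray
    reference_offsets_ppm: np.ndarray = field(default_factory=lambda: np.array([]))
    b1_amplitude: float = 1.5
    sat_duration: float = 4.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "offsets_ppm", np.asarray(self.offsets_ppm, dtype=float))
        object.__setattr__(
            self, "reference_offsets_ppm", np.asarray(self.reference_offsets_ppm, dtype=float)
        )
        d = np.diff(self.offsets_ppm)
        if d.size and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("offsets_ppm must be strictly monotone")
        if self.b1_amplitude < 0:
            raise ValueError("b1_amplitude must be >= 0")
        if self.sat_duration <= 0:
            raise ValueError("sat_duration must be > 0")
        if self.offsets_ppm.size:
            lo, hi = self.offsets_ppm.min(), self.offsets_ppm.max()
            for r in self.reference_offsets_ppm:
                if lo <= r <= hi:
                    raise ValueError(f"reference offset {r} ppm lies inside the sampled range")

    @property
    def all_offsets_ppm(self) -> np.ndarray:
        """Sampled offsets followed by reference offsets (acquisition order)."""
        return np.concatenate([self.offsets_ppm, self.reference_offsets_ppm])

    @property
    def n_frames(self) -> int:
        return self.offsets_ppm.size + self.reference_offsets_ppm.size


def make_offset_schedule(
    start_ppm: float,
    stop_ppm: float,
    step_ppm: float,
    reference_offsets: list[float] | None = None,
    b1_amplitude: float = 1.5,
    sat_duration: float = 4.0,
) -> SaturationSchedule:
    """Build a linearly spaced schedule start, start+step, ..., stop inclusive.

    Raises ``ValueError`` for non-positive step or stop < start.
    """
    if step_ppm <= 0:
        raise ValueError("step_ppm must be > 0")
    if stop_ppm < start_ppm:
        raise ValueError("stop_ppm must be >= start_ppm")
    n = int(round((stop_ppm - start_ppm) / step_ppm)) + 1
    offsets = start_ppm + step_ppm * np.arange(n)
    return SaturationSchedule(
        offsets_ppm=offsets,
        reference_offsets_ppm=np.asarray(reference_offsets if reference_offsets else [], dtype=float),
        b1_amplitude=b1_amplitude,
        sat_duration=sat_duration,
    )


def cest_schedule() -> SaturationSchedule:
    """The 9.4 T amide/amine CEST sweep: 1.2–6.6 ppm in 0.1 ppm steps (55
    offsets) plus ±1000 ppm references, 1.5 μT / 4 s CW saturation — 57
    frames in total."""
    return make_offset_schedule(1.2, 6.6, 0.1, [-1000.0, 1000.0], b1_amplitude=1.5, sat_duration=4.0)


def wassr_schedule() -> SaturationSchedule:
    """The 41-point WASSR sweep: −0.6 to +0.6 ppm in 0.03 ppm steps,
    0.2 μT / 100 ms low-power saturation (no reference frames; CEST
    references are reused for normalization)."""
    return make_offset_schedule(-0.6, 0.6, 0.03, [-1000.0, 1000.0], b1_amplitude=0.2, sat_duration=0.1)
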