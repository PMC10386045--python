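"""Synthetic CEST/WASSR phantoms with known pH, B0 and tissue masks.

Stands in for the study's raw scans: a 2-D grid of tissue classes (tumor /
peritumoral / contralateral …), each with its own intracellular pH, is run
through the Bloch-McConnell simulator voxel by voxel.  Each voxel's spectrum
uses that voxel's pH-resolved exchange rates, is frequency-shifted by the
voxel's B0 offset and scaled by its B1 multiplier; reference frames carry
the unsaturated signal and Rician noise is drawn independently per repeat.

B0 fields are smooth low-order polynomial surfaces (plus optional jitter),
capped so the WASSR window always brackets the water minimum, and quantized
to 0.001 ppm — the quantized field is what the data encode and is returned
as ground truth.  Spectra are cached per (tissue class, quantized B0,
quantized B1), which is what makes dense grids affordable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .bloch import bm_evolve
from .pools import PoolSystem, default_pool_system
from .roi import ROISet
from .schedules import SaturationSchedule
from .stack import ZSpectrumStack

__all__ = [
    "TissueClass",
    "PolynomialB0",
    "PhantomSpec",
    "GroundTruth",
    "generate_phantom",
    "add_rician_noise",
    "rician_mean",
    "with_class_ph",
]

B0_QUANT_PPM = 1e-3
B0_CAP_PPM = 0.3
_B1_QUANT = 1e-3

_spectrum_cache: dict = {}


@dataclass(frozen=True)
class TissueClass:
    """Named region with an intracellular pH.

    shape: None fills the background; ("ellipse", cx, cy, rx, ry) and
    ("rect", x0, y0, x1, y1) use fractional grid coordinates in [0, 1].
    """

    name: str
    ph: float
    shape: tuple | None = None
    system: PoolSystem | None = None  # overrides the spec-level pool system

    def __post_init__(self) -> None:
        if not 5.5 <= self.ph <= 8.5:
            raise ValueError("tissue pH must lie in [5.5, 8.5]")

    def mask(self, nx: int, ny: int) -> np.ndarray:
        if self.shape is None:
            return np.ones((nx, ny), dtype=bool)
        kind = self.shape[0]
        x = (np.arange(nx) + 0.5) / nx
        y = (np.arange(ny) + 0.5) / ny
        X, Y = np.meshgrid(x, y, indexing="ij")
        if kind == "ellipse":
            _, cx, cy, rx, ry = self.shape
            return ((X - cx) / rx) ** 2 + ((Y - cy) / ry) ** 2 <= 1.0
        if kind == "rect":
            _, x0, y0, x1, y1 = self.shape
            return (X >= x0) & (X <= x1) & (Y >= y0) & (Y <= y1)
        raise ValueError(f"unknown shape kind {kind!r}")


@dataclass(frozen=True)
class PolynomialB0:
    """Smooth B0 surface: c00 + c10·u + c01·v + c20·u² + c02·v² + c11·uv
    (u, v normalized to [-1, 1]) plus optional per-voxel Gaussian jitter."""

    coeffs: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    jitter_sigma: float = 0.0

    def evaluate(self, nx: int, ny: int, rng: np.random.Generator) -> np.ndarray:
        u = np.linspace(-1, 1, nx)
        v = np.linspace(-1, 1, ny)
        U, V = np.meshgrid(u, v, indexing="ij")
        c = self.coeffs
        b0 = c[0] + c[1] * U + c[2] * V + c[3] * U**2 + c[4] * V**2 + c[5] * U * V
        if self.jitter_sigma > 0:
            b0 = b0 + rng.normal(0.0, self.jitter_sigma, size=b0.shape)
        return b0


@dataclass(frozen=True)
class PhantomSpec:
    """Everything needed to simulate one subject's acquisition."""

    nx: int = 32
    ny: int = 32
    voxel_mm: tuple[float, float, float] = (0.4, 0.4, 2.0)
    classes: tuple[TissueClass, ...] = (
        TissueClass("contralateral", ph=7.0),
        TissueClass("tumor", ph=7.34, shape=("ellipse", 0.35, 0.5, 0.18, 0.22)),
        TissueClass("peritumoral", ph=7.15, shape=("ellipse", 0.72, 0.55, 0.12, 0.15)),
    )
    b0: PolynomialB0 | None = None
    b1_scale: float = 1.0
    noise_sigma: float = 0.0
    seed: int = 0
    system: PoolSystem = field(default_factory=default_pool_system)

    def __post_init__(self) -> None:
        object.__setattr__(self, "classes", tuple(self.classes))
        if self.nx < 1 or self.ny < 1:
            raise ValueError("invalid grid")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        names = [c.name for c in self.classes]
        if len(set(names)) != len(names):
            raise ValueError("tissue class names must be unique")

    def label_map(self) -> np.ndarray:
        """Class index per voxel; explicit shapes must not overlap."""
        label = np.full((self.nx, self.ny), -1, dtype=int)
        for idx, cls in enumerate(self.classes):
            if cls.shape is None:
                label[label < 0] = idx
        painted = np.zeros((self.nx, self.ny), dtype=bool)
        for idx, cls in enumerate(self.classes):
            if cls.shape is None:
                continue
            m = cls.mask(self.nx, self.ny)
            if (m & painted).any():
                raise ValueError(f"tissue region {cls.name!r} overlaps another region")
            painted |= m
            label[m] = idx
        if (label < 0).any():
            raise ValueError("grid not fully covered; add a background class (shape=None)")
        return label


@dataclass
class GroundTruth:
    """What the phantom actually encodes, on the generated grid."""

    ph_map: np.ndarray
    b0_map: np.ndarray
    masks: ROISet
    label_map: np.ndarray


def rician_mean(v: float, sigma: float, n_quad: int = 64) -> float:
    """Mean of sqrt((v+g1)² + g2²), g ~ N(0, σ²), by Gauss-Hermite quadrature.

    Exact-noise oracle used by the tests; equals v for σ = 0.
    """
    if sigma == 0:
        return float(v)
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
    W = np.outer(weights, weights) / (2 * np.pi)
    G1, G2 = np.meshgrid(nodes, nodes, indexing="ij")
    return float(np.sum(W * np.sqrt((v + sigma * G1) ** 2 + (sigma * G2) ** 2)))


def add_rician_noise(
    data: np.ndarray, sigma: float, rng: np.random.Generator | int
) -> np.ndarray:
    """Magnitude-MRI noise: v → sqrt((v+g1)² + g2²), g1,g2 ~ N(0, σ²)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    data = np.asarray(data, dtype=float)
    if sigma == 0:
        return data.copy()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    g1 = rng.normal(0.0, sigma, size=data.shape)
    g2 = rng.normal(0.0, sigma, size=data.shape)
    return np.sqrt((data + g1) ** 2 + g2**2)


def _class_spectrum(
    system: PoolSystem,
    ph: float,
    b0_q: float,
    b1_eff: float,
    schedule: SaturationSchedule,
) -> np.ndarray:
    """Cached noiseless spectrum over all schedule frames (refs included)."""
    offsets = schedule.all_offsets_ppm
    key = (
        system.pools,
        system.field_mhz,
        round(ph, 6),
        round(b0_q / B0_QUANT_PPM),
        round(b1_eff / _B1_QUANT),
        schedule.sat_duration,
        offsets.tobytes(),
    )
    hit = _spectrum_cache.get(key)
    if hit is not None:
        return hit
    z = np.array(
        [bm_evolve(system, w - b0_q, b1_eff, schedule.sat_duration, ph=ph) for w in offsets]
    )
    _spectrum_cache[key] = z
    return z


def generate_phantom(
    spec: PhantomSpec,
    cest_schedule: SaturationSchedule,
    wassr_schedule: SaturationSchedule,
    n_repeats: int = 3,
    noise_seed: int | None = None,
) -> tuple[list[ZSpectrumStack], list[ZSpectrumStack], GroundTruth]:
    """Simulate *n_repeats* CEST and WASSR acquisitions of one phantom.

    The B0 surface is drawn from ``spec.seed`` (so repeated timepoints of
    one subject share their field map); noise streams derive from
    *noise_seed* (default: the spec seed), independently per repeat and
    acquisition.  Same spec and seeds ⇒ bit-identical output.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    label = spec.label_map()
    nx, ny = spec.nx, spec.ny

    b0_rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0]))
    if spec.b0 is None:
        b0 = np.zeros((nx, ny))
    else:
        b0 = spec.b0.evaluate(nx, ny, b0_rng)
    b0 = np.clip(b0, -B0_CAP_PPM, B0_CAP_PPM)
    b0 = np.round(b0 / B0_QUANT_PPM) * B0_QUANT_PPM

    b1 = np.broadcast_to(np.asarray(spec.b1_scale, dtype=float), (nx, ny))
    b1 = np.round(b1 / _B1_QUANT) * _B1_QUANT

    ph_map = np.array([c.ph for c in spec.classes])[label]

    def simulate(schedule: SaturationSchedule) -> np.ndarray:
        out = np.empty((nx, ny, schedule.n_frames))
        for i in range(nx):
            for j in range(ny):
                cls = spec.classes[label[i, j]]
                out[i, j] = _class_spectrum(
                    cls.system if cls.system is not None else spec.system,
                    cls.ph,
                    float(b0[i, j]),
                    schedule.b1_amplitude * float(b1[i, j]),
                    schedule,
                )
        return out

    cest_clean = simulate(cest_schedule)
    wassr_clean = simulate(wassr_schedule)

    ss = np.random.SeedSequence([int(noise_seed if noise_seed is not None else spec.seed), 1])
    streams = [np.random.default_rng(s) for s in ss.spawn(2 * n_repeats)]

    def as_stack(data: np.ndarray, schedule: SaturationSchedule) -> ZSpectrumStack:
        return ZSpectrumStack(
            data=data,
            offsets_ppm=schedule.all_offsets_ppm,
            field_mhz=spec.system.field_mhz,
            voxel_mm=spec.voxel_mm,
            reference_offsets_ppm=schedule.reference_offsets_ppm,
        )

    cest_stacks = [
        as_stack(add_rician_noise(cest_clean, spec.noise_sigma, streams[2 * r]), cest_schedule)
        for r in range(n_repeats)
    ]
    wassr_stacks = [
        as_stack(
            add_rician_noise(wassr_clean, spec.noise_sigma, streams[2 * r + 1]), wassr_schedule
        )
        for r in range(n_repeats)
    ]

    masks = ROISet(
        masks={c.name: label == idx for idx, c in enumerate(spec.classes)},
        voxel_mm=spec.voxel_mm,
    )
    truth = GroundTruth(ph_map=ph_map, b0_map=b0, masks=masks, label_map=label)
    return cest_stacks, wassr_stacks, truth


def simulated_aacid_curve(
    system: PoolSystem,
    ph_values,
    schedule: SaturationSchedule,
    smoothing: float | str | None = 0,
) -> np.ndarray:
    """AACID of the noiseless simulator at each pH, via the standard readout.

    One ideal spectrum per pH (no B0/B1 perturbation, no noise) pushed
    through the same spline/1-Hz/ratio pathway the mapping uses.  This is
    the simulator's own AACID–pH calibration curve; phantom recovery tests
    compare against it rather than against absolute pH.
    """
    from .mapping import AACIDSamples, compute_aacid
    from .zspec import fit_spline

    out = []
    for ph in np.atleast_1d(ph_values):
        z = _class_spectrum(system, float(ph), 0.0, schedule.b1_amplitude, schedule)
        sampled = ~np.isin(schedule.all_offsets_ppm, schedule.reference_offsets_ppm)
        cs = fit_spline(
            schedule.all_offsets_ppm[sampled], z[sampled], system.field_mhz, smoothing
        )
        s = AACIDSamples(
            mz_amine=cs.sample(2.75), mz_amide=cs.sample(3.5), mz_ref=cs.sample(6.0)
        )
        out.append(compute_aacid(s))
    return np.asarray(out)


def with_class_ph(spec: PhantomSpec, ph_by_class: dict[str, float]) -> PhantomSpec:
    """Copy of *spec* with selected class pH values replaced.

    This is how scripted time courses (e.g. a step pH change 20 min after a
    drug injection) are expressed: one spec per timepoint, same seed so the
    subject keeps its B0 field.
    """
    classes = tuple(
        replace(c, ph=ph_by_class.get(c.name, c.ph)) for c in spec.classes
    )
    return replace(spec, classes=classes)
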