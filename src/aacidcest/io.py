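"""File formats: NIfTI stacks/maps with JSON sidecars, YAML phantom and run
configuration, CSV result tables.

The saturation schedule cannot ride in a NIfTI header portably, so every
stack is a 4-D volume (x, y, 1, offset) accompanied by a ``.json`` sidecar
listing ``offsets_ppm``, reference offsets, ``field_mhz`` and the pulse
parameters.  Parametric maps use a NaN sentinel for invalid voxels plus a
``*_valid`` companion mask, stated in their sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .mapping import CalibrationParams, ParametricMap
from .phantom import PhantomSpec, PolynomialB0, TissueClass
from .roi import ROISet
from .stack import ZSpectrumStack
from .zspec import B0Map

__all__ = [
    "read_stack",
    "write_stack",
    "read_map",
    "write_map",
    "write_b0_map",
    "read_roiset",
    "write_roiset",
    "load_phantom_spec",
    "dump_phantom_spec",
    "RunConfig",
    "load_run_config",
]


def _affine(voxel_mm: tuple[float, float, float]) -> np.ndarray:
    return np.diag([voxel_mm[0], voxel_mm[1], voxel_mm[2], 1.0])


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_stack(stack: ZSpectrumStack, path: str | Path) -> Path:
    """Write a stack as 4-D NIfTI plus JSON sidecar; returns the NIfTI path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = stack.data[:, :, None, :]
    nib.save(nib.Nifti1Image(data, _affine(stack.voxel_mm)), str(path))
    sidecar = {
        "offsets_ppm": stack.offsets_ppm.tolist(),
        "reference_offsets_ppm": stack.reference_offsets_ppm.tolist(),
        "field_mhz": stack.field_mhz,
        "voxel_mm": list(stack.voxel_mm),
        "normalized": bool(stack.normalized),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_stack(path: str | Path) -> ZSpectrumStack:
    """Read a stack written by :func:`write_stack`.

    Errors if the sidecar is missing, lacks ``field_mhz``, or lists a
    different number of offsets than the volume has frames.
    """
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing JSON sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for key in ("offsets_ppm", "field_mhz"):
        if key not in meta:
            raise KeyError(f"sidecar {sidecar_path} is missing required field {key!r}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4:
        data = data[:, :, 0, :]
    offsets = np.asarray(meta["offsets_ppm"], dtype=float)
    if data.shape[-1] != offsets.size:
        raise ValueError(
            f"sidecar lists {offsets.size} offsets but volume has {data.shape[-1]} frames"
        )
    valid = np.all(np.isfinite(data), axis=-1)
    data = data.copy()
    data[~valid] = np.nan
    return ZSpectrumStack(
        data=data,
        offsets_ppm=offsets,
        field_mhz=float(meta["field_mhz"]),
        voxel_mm=tuple(meta.get("voxel_mm", (0.4, 0.4, 2.0))),
        reference_offsets_ppm=np.asarray(meta.get("reference_offsets_ppm", []), dtype=float),
        normalized=bool(meta.get("normalized", False)),
        valid=valid,
    )


def write_map(pmap: ParametricMap, path: str | Path, kind: str = "aacid") -> Path:
    """Parametric map as NIfTI (NaN sentinel) + ``*_valid`` mask + sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    values = np.where(pmap.valid, pmap.values, np.nan)
    nib.save(nib.Nifti1Image(values[:, :, None], _affine(pmap.voxel_mm)), str(path))
    stem = path.name.removesuffix(".nii.gz").removesuffix(".nii")
    valid_path = path.with_name(stem + "_valid.nii.gz")
    nib.save(
        nib.Nifti1Image(pmap.valid.astype(np.uint8)[:, :, None], _affine(pmap.voxel_mm)),
        str(valid_path),
    )
    _sidecar_path(path).write_text(
        json.dumps({"kind": kind, "invalid_sentinel": "NaN", "voxel_mm": list(pmap.voxel_mm)})
    )
    return path


def read_map(path: str | Path, voxel_mm: tuple[float, float, float] = (0.4, 0.4, 2.0)) -> ParametricMap:
    path = Path(path)
    img = nib.load(str(path))
    values = np.asarray(img.dataobj, dtype=float)[:, :, 0]
    stem = path.name.removesuffix(".nii.gz").removesuffix(".nii")
    valid_path = path.with_name(stem + "_valid.nii.gz")
    if valid_path.exists():
        valid = np.asarray(nib.load(str(valid_path)).dataobj)[:, :, 0].astype(bool)
    else:
        valid = np.isfinite(values)
    meta_path = _sidecar_path(path)
    if meta_path.exists():
        voxel_mm = tuple(json.loads(meta_path.read_text()).get("voxel_mm", voxel_mm))
    return ParametricMap(values=values, valid=valid, voxel_mm=voxel_mm)


def write_b0_map(b0: B0Map, path: str | Path, voxel_mm=(0.4, 0.4, 2.0)) -> Path:
    pmap = ParametricMap(
        values=np.where(b0.valid, b0.shift_ppm, np.nan), valid=b0.valid, voxel_mm=voxel_mm
    )
    return write_map(pmap, path, kind="b0_shift_ppm")


def write_roiset(rois: ROISet, out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, mask in rois.masks.items():
        p = out_dir / f"mask_{name}.nii.gz"
        nib.save(nib.Nifti1Image(mask.astype(np.uint8)[:, :, None], _affine(rois.voxel_mm)), str(p))
        paths.append(p)
    return paths


def read_roiset(mask_dir: str | Path, voxel_mm=(0.4, 0.4, 2.0)) -> ROISet:
    mask_dir = Path(mask_dir)
    masks = {}
    for p in sorted(mask_dir.glob("mask_*.nii.gz")):
        name = p.name[len("mask_") : -len(".nii.gz")]
        masks[name] = np.asarray(nib.load(str(p)).dataobj)[:, :, 0].astype(bool)
    if not masks:
        raise FileNotFoundError(f"no mask_*.nii.gz files in {mask_dir}")
    return ROISet(masks=masks, voxel_mm=voxel_mm)


# -- YAML phantom / run configuration ---------------------------------------


def dump_phantom_spec(spec: PhantomSpec, path: str | Path) -> Path:
    doc = {
        "grid": {"nx": spec.nx, "ny": spec.ny, "voxel_mm": list(spec.voxel_mm)},
        "classes": [
            {"name": c.name, "ph": c.ph, "shape": list(c.shape) if c.shape else None}
            for c in spec.classes
        ],
        "b0": (
            {"coeffs": list(spec.b0.coeffs), "jitter_sigma": spec.b0.jitter_sigma}
            if spec.b0
            else None
        ),
        "b1_scale": spec.b1_scale,
        "noise_sigma": spec.noise_sigma,
        "seed": spec.seed,
    }
    path = Path(path)
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def load_phantom_spec(path: str | Path) -> PhantomSpec:
    doc = yaml.safe_load(Path(path).read_text())
    grid = doc.get("grid", {})
    classes = tuple(
        TissueClass(
            name=c["name"],
            ph=float(c["ph"]),
            shape=tuple(c["shape"]) if c.get("shape") else None,
        )
        for c in doc["classes"]
    )
    b0 = None
    if doc.get("b0"):
        b0 = PolynomialB0(
            coeffs=tuple(doc["b0"].get("coeffs", ())),
            jitter_sigma=float(doc["b0"].get("jitter_sigma", 0.0)),
        )
    return PhantomSpec(
        nx=int(grid.get("nx", 32)),
        ny=int(grid.get("ny", 32)),
        voxel_mm=tuple(grid.get("voxel_mm", (0.4, 0.4, 2.0))),
        classes=classes,
        b0=b0,
        b1_scale=float(doc.get("b1_scale", 1.0)),
        noise_sigma=float(doc.get("noise_sigma", 0.0)),
        seed=int(doc.get("seed", 0)),
    )


@dataclass
class RunConfig:
    """End-to-end run description; every random operation reads its seed here."""

    phantom: PhantomSpec
    n_repeats: int = 3
    timepoints: dict[float, dict[str, float]] = field(default_factory=dict)
    calibration: CalibrationParams = field(default_factory=CalibrationParams)
    smoothing: float | str | None = "gcv"
    seed: int = 0

    def to_doc(self) -> dict:
        return {
            "phantom": yaml.safe_load(
                yaml.safe_dump(
                    {
                        "grid": {
                            "nx": self.phantom.nx,
                            "ny": self.phantom.ny,
                            "voxel_mm": list(self.phantom.voxel_mm),
                        },
                        "classes": [
                            {
                                "name": c.name,
                                "ph": c.ph,
                                "shape": list(c.shape) if c.shape else None,
                            }
                            for c in self.phantom.classes
                        ],
                        "b0": (
                            {
                                "coeffs": list(self.phantom.b0.coeffs),
                                "jitter_sigma": self.phantom.b0.jitter_sigma,
                            }
                            if self.phantom.b0
                            else None
                        ),
                        "b1_scale": self.phantom.b1_scale,
                        "noise_sigma": self.phantom.noise_sigma,
                        "seed": self.phantom.seed,
                    }
                )
            ),
            "n_repeats": self.n_repeats,
            "timepoints": {float(t): dict(v) for t, v in self.timepoints.items()},
            "calibration": {
                "slope": self.calibration.slope,
                "intercept": self.calibration.intercept,
            },
            "smoothing": self.smoothing,
            "seed": self.seed,
        }


def load_run_config(path: str | Path) -> RunConfig:
    doc = yaml.safe_load(Path(path).read_text())
    if "phantom" not in doc:
        raise KeyError("run config missing 'phantom' section")
    tmp = Path(path).with_suffix(".phantom.tmp.yaml")
    tmp.write_text(yaml.safe_dump(doc["phantom"]))
    try:
        phantom = load_phantom_spec(tmp)
    finally:
        tmp.unlink(missing_ok=True)
    cal = doc.get("calibration", {})
    return RunConfig(
        phantom=phantom,
        n_repeats=int(doc.get("n_repeats", 3)),
        timepoints={
            float(t): {str(k): float(v) for k, v in d.items()}
            for t, d in (doc.get("timepoints") or {}).items()
        },
        calibration=CalibrationParams(
            slope=float(cal.get("slope", -4.0)), intercept=float(cal.get("intercept", 12.8))
        ),
        smoothing=doc.get("smoothing", "gcv"),
        seed=int(doc.get("seed", 0)),
    )
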