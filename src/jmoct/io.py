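"""File formats: HDF5 Jones-matrix containers, scalar volume stacks
(TIFF or NIfTI) with JSON sidecars, ROI masks, stitch layouts and configs.

Round trips are bit-exact: Jones volumes are stored at full complex precision;
scalar volumes are written as float32 stacks (and come back as float32).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import yaml

from .phantom import LayerProperty, PhantomSpec
from .system import SystemProfile
from .volumes import ContrastVolume, JonesVolume, ROIMask
from .mosaic import StitchLayout

__all__ = [
    "save_jones", "load_jones",
    "save_contrast", "load_contrast",
    "save_mask", "load_mask",
    "save_layout", "load_layout",
    "load_config", "dump_config",
    "save_phantom_spec", "load_phantom_spec",
]


# ---------------------------------------------------------------------------
# JonesVolume <-> HDF5

def save_jones(path: str | Path, jones: JonesVolume) -> Path:
    """Write a Jones volume to HDF5 (dataset ``/jones``, shape R×z×x×y×2×2)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("jones", data=jones.data)
        for key, val in jones.system.to_dict().items():
            f.attrs[f"system/{key}"] = val if val is not None else "none"
        f.attrs["provenance"] = jones.provenance
        f.attrs["seed"] = -1 if jones.seed is None else jones.seed
    return path


def load_jones(path: str | Path) -> JonesVolume:
    with h5py.File(path, "r") as f:
        data = f["jones"][()]
        fields = {}
        for key, val in f.attrs.items():
            if key.startswith("system/"):
                name = key.split("/", 1)[1]
                if isinstance(val, bytes):
                    val = val.decode()
                if val == "none" or (isinstance(val, str) and val == "none"):
                    val = None
                fields[name] = val
        for name in ("n_repeats", "depth_pixels", "x_pixels", "y_pixels"):
            fields[name] = int(fields[name])
        seed = int(f.attrs["seed"])
        prov = f.attrs["provenance"]
        if isinstance(prov, bytes):
            prov = prov.decode()
    system = SystemProfile(**{k: v for k, v in fields.items()})
    return JonesVolume(data=data, system=system, provenance=str(prov),
                       seed=None if seed == -1 else seed)


# ---------------------------------------------------------------------------
# scalar volume stacks

def _is_nifti(path: Path) -> bool:
    return path.name.endswith((".nii", ".nii.gz"))


def _write_stack(path: Path, data: np.ndarray) -> None:
    if _is_nifti(path):
        import nibabel as nib
        nib.save(nib.Nifti1Image(np.asarray(data), affine=np.eye(4)), str(path))
    else:
        import tifffile
        tifffile.imwrite(path, np.asarray(data))


def _read_stack(path: Path) -> np.ndarray:
    if _is_nifti(path):
        import nibabel as nib
        return np.asarray(nib.load(str(path)).dataobj)
    import tifffile
    return tifffile.imread(path)


def save_contrast(path: str | Path, volume: ContrastVolume) -> Path:
    """Write a contrast volume as a float32 stack plus a ``.json`` sidecar
    (kind, units, params, valid fraction) and a uint8 validity stack."""
    path = Path(path)
    _write_stack(path, volume.data.astype(np.float32))
    mask_path = _aux_path(path, "_valid")
    _write_stack(mask_path, volume.valid_mask.astype(np.uint8))
    sidecar = {
        "kind": volume.kind,
        "units": volume.units,
        "params": _jsonable(volume.params),
        "valid_fraction": float(volume.valid_mask.mean()),
        "shape": list(volume.shape),
    }
    _aux_path(path, "").with_suffix(".json").write_text(
        json.dumps(sidecar, indent=2))
    return path


def load_contrast(path: str | Path) -> ContrastVolume:
    path = Path(path)
    data = _read_stack(path)
    meta = json.loads(_aux_path(path, "").with_suffix(".json").read_text())
    mask_path = _aux_path(path, "_valid")
    valid = _read_stack(mask_path).astype(bool) if mask_path.exists() else None
    return ContrastVolume(data=data, kind=meta["kind"], units=meta["units"],
                          valid_mask=valid, params=meta.get("params", {}))


def _aux_path(path: Path, suffix: str) -> Path:
    name = path.name
    for ext in (".nii.gz", ".nii", ".tif", ".tiff"):
        if name.endswith(ext):
            return path.with_name(name[: -len(ext)] + suffix + (ext if suffix else ""))
    return path.with_name(path.stem + suffix + path.suffix) if suffix else path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# ROI masks

def save_mask(path: str | Path, mask: ROIMask) -> Path:
    path = Path(path)
    _write_stack(path, mask.mask.astype(np.uint8))
    _aux_path(path, "").with_suffix(".json").write_text(json.dumps(
        {"organ_label": mask.organ_label, "source": mask.source}, indent=2))
    return path


def load_mask(path: str | Path) -> ROIMask:
    path = Path(path)
    data = _read_stack(path).astype(bool)
    meta_path = _aux_path(path, "").with_suffix(".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return ROIMask(mask=data, organ_label=meta.get("organ_label", "other"),
                   source=meta.get("source", str(path)))


# ---------------------------------------------------------------------------
# phantom scene descriptions

def save_phantom_spec(path: str | Path, spec: PhantomSpec) -> Path:
    """Write a phantom as human-editable YAML plus an integer label stack.

    The YAML holds the system profile, seed and per-label optical properties;
    ``label_volume`` is stored as an adjacent TIFF (z, x, y, 0-based labels)
    referenced by relative path.
    """
    path = Path(path)
    stack = path.with_suffix(".labels.tif")
    _write_stack(stack, spec.label_volume.astype(np.int16))
    payload = {
        "name": spec.name,
        "seed": spec.seed,
        "system": spec.system.to_dict(),
        "label_volume": stack.name,
        "properties": {int(lab): asdict(prop)
                       for lab, prop in spec.properties.items()},
    }
    path.write_text(yaml.safe_dump(_jsonable(payload), sort_keys=False))
    return path


def load_phantom_spec(path: str | Path) -> PhantomSpec:
    """Read a phantom scene description written by :func:`save_phantom_spec`
    (or edited by hand; the label stack path is resolved relative to the
    YAML file)."""
    path = Path(path)
    payload = yaml.safe_load(path.read_text())
    labels = _read_stack(path.parent / payload["label_volume"]).astype(np.int16)
    props = {int(lab): LayerProperty(**fields)
             for lab, fields in payload["properties"].items()}
    return PhantomSpec(label_volume=labels, properties=props,
                       system=SystemProfile(**payload["system"]),
                       seed=int(payload.get("seed", 0)),
                       name=payload.get("name", "phantom"))


# ---------------------------------------------------------------------------
# stitch layouts and configs

def save_layout(path: str | Path, layout: StitchLayout) -> Path:
    path = Path(path)
    payload = {
        "refined_offsets": [list(o) for o in layout.refined_offsets],
        "pairwise_scores": {f"{a}-{b}": s
                            for (a, b), s in layout.pairwise_scores.items()},
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def load_layout(path: str | Path) -> StitchLayout:
    payload = json.loads(Path(path).read_text())
    scores = {tuple(int(i) for i in k.split("-")): float(v)
              for k, v in payload.get("pairwise_scores", {}).items()}
    return StitchLayout(
        refined_offsets=[tuple(o) for o in payload["refined_offsets"]],
        pairwise_scores=scores)


def load_config(path: str | Path) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f)
    return cfg or {}


def dump_config(path: str | Path, config: dict) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(_jsonable(config), sort_keys=False))
    return path
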