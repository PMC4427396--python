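"""NIfTI / JSON / YAML input-output helpers.

Maps and image stacks are stored as float32 NIfTI with NaN as the no-data
value; acquisition metadata (inversion or preparation times, protocol,
seed) travels in a JSON sidecar next to the image file.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .maps import ParameterMap

__all__ = [
    "save_map",
    "load_map",
    "save_stack",
    "load_stack",
    "load_config",
    "dump_config",
]


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def save_map(pmap: ParameterMap, path) -> None:
    """Write a ParameterMap as float32 NIfTI plus a JSON sidecar.

    Masked-out pixels are stored as NaN; the sidecar records units and
    metadata.
    """
    path = Path(path)
    data = pmap.with_nodata().astype(np.float32)
    nib.save(nib.Nifti1Image(data, np.eye(4)), str(path))
    sidecar = {"units": pmap.units, "meta": pmap.meta}
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2, default=float))


def load_map(path) -> ParameterMap:
    path = Path(path)
    img = nib.load(str(path))
    values = np.asarray(img.dataobj, dtype=float)
    units, meta = "", {}
    sc = _sidecar_path(path)
    if sc.exists():
        d = json.loads(sc.read_text())
        units = d.get("units", "")
        meta = d.get("meta", {})
    return ParameterMap(values=values, units=units, mask=np.isfinite(values), meta=meta)


def save_stack(stack: np.ndarray, meta: dict, path) -> None:
    """Write an image stack (ny, nx, n_images) + metadata sidecar."""
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(stack, dtype=np.float32), np.eye(4)), str(path))
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, default=float))


def load_stack(path):
    path = Path(path)
    img = nib.load(str(path))
    stack = np.asarray(img.dataobj, dtype=float)
    sc = _sidecar_path(path)
    meta = json.loads(sc.read_text()) if sc.exists() else {}
    return stack, meta


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg


def dump_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
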