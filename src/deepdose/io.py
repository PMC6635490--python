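"""Volume I/O: NIfTI (primary) and MetaImage (secondary) with units sidecars.

Every volume written to disk carries a JSON sidecar recording its units tag
and provenance (stage, seed, config hash).  Reading a dose/activity volume
without a units tag is an error: no unit-less volume can enter a metric.
Data round-trips at float32; geometry (voxel size) round-trips exactly via
the NIfTI affine.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .volumes import Volume


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii", ".mha", ".mhd"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_volume(vol: Volume, path: str | Path) -> Path:
    """Write a volume plus its JSON units/provenance sidecar; returns the path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dtype = np.int16 if vol.units == "label" else np.float32
    data = np.asarray(vol.data, dtype=dtype)
    if path.name.endswith((".mha", ".mhd")):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.transpose(data, (2, 1, 0)))
        img.SetSpacing(tuple(vol.voxel_size))
        sitk.WriteImage(img, str(path))
    else:
        affine = np.diag(list(vol.voxel_size) + [1.0])
        nib.save(nib.Nifti1Image(data, affine), str(path))
    sidecar = {"units": vol.units, "voxel_size_mm": list(vol.voxel_size),
               "provenance": _jsonable(vol.meta)}
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def read_volume(path: str | Path, require_units: bool = True) -> Volume:
    """Read a volume and its sidecar.  Missing units is an error by default."""
    path = Path(path)
    sidecar_file = _sidecar_path(path)
    sidecar = json.loads(sidecar_file.read_text()) if sidecar_file.exists() else {}
    units = sidecar.get("units")
    if units is None:
        if require_units:
            raise ValueError(f"no units sidecar for {path}; refusing to load untagged volume")
        units = "dimensionless"
    if path.name.endswith((".mha", ".mhd")):
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        data = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
        voxel_size = tuple(img.GetSpacing())
    else:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(np.asarray(data, dtype=np.int32 if units == "label" else np.float64),
                  voxel_size, units, sidecar.get("provenance", {}))


def resample_like(vol: Volume, target: Volume, order: int | None = None) -> Volume:
    """Resample onto the target grid: trilinear for HU, nearest for labels."""
    if order is None:
        order = 0 if vol.units == "label" else 1
    # physical-coordinate mapping from target voxel centres to source indices
    coords = np.meshgrid(*[(np.arange(n) + 0.5) * t for n, t in
                           zip(target.shape, target.voxel_size)], indexing="ij")
    idx = [c / s - 0.5 for c, s in zip(coords, vol.voxel_size)]
    data = ndimage.map_coordinates(vol.data.astype(float), np.array(idx), order=order,
                                   mode="nearest")
    if vol.units == "label":
        data = data.astype(np.int32)
    return Volume(data, target.voxel_size, vol.units,
                  {**vol.meta, "resampled_to": target.shape})


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed fan-out from one global seed (< 2^31)."""
    return (int(global_seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(_jsonable(config), sort_keys=True).encode()).hexdigest()[:12]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
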