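"""Volume, landmark and report I/O.

Formats: NIfTI-1 (.nii/.nii.gz) via nibabel, MetaImage (.mha/.mhd) via
SimpleITK, landmark CSV (header ``x,y,z``, 0-based voxel coordinates),
JSON reports, YAML configs.  In-memory arrays are indexed (x, y, z);
deformation fields and descriptor stacks travel as 4D volumes with the
component/channel axis last.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import SimpleITK as sitk
import yaml

from .errors import LandmarkParseError, UnsupportedFormatError
from .pipeline import LandmarkSet, RegistrationConfig
from .transform import DeformationField

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_META_SUFFIXES = (".mha", ".mhd")


@dataclass
class VolumeRecord:
    """A scalar volume plus the geometry needed to round-trip it."""

    data: np.ndarray
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None
    source_path: str | None = None


def _suffix(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return ".nii.gz"
    return path.suffix.lower()


def read_volume(path) -> VolumeRecord:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suf = _suffix(path)
    if suf in _NIFTI_SUFFIXES:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata())
        zooms = img.header.get_zooms()[:3]
        return VolumeRecord(
            data=data,
            voxel_spacing=tuple(float(z) for z in zooms),
            affine=np.asarray(img.affine),
            source_path=str(path),
        )
    if suf in _META_SUFFIXES:
        img = sitk.ReadImage(str(path))
        arr = sitk.GetArrayFromImage(img)  # (z, y, x [, c])
        data = np.moveaxis(arr, (0, 1, 2), (2, 1, 0)) if arr.ndim >= 3 else arr
        spacing = img.GetSpacing()[:3]
        return VolumeRecord(
            data=np.asarray(data, dtype=float),
            voxel_spacing=tuple(float(s) for s in spacing),
            affine=None,
            source_path=str(path),
        )
    raise UnsupportedFormatError(f"unsupported volume format: {path.name}")


def write_volume(record: VolumeRecord, path) -> None:
    path = Path(path)
    suf = _suffix(path)
    data = np.asarray(record.data)
    if suf in _NIFTI_SUFFIXES:
        affine = record.affine
        if affine is None:
            affine = np.diag(list(record.voxel_spacing) + [1.0])
        img = nib.Nifti1Image(data, affine)
        img.header.set_zooms(record.voxel_spacing + (1.0,) * (data.ndim - 3)
                             if data.ndim > 3 else record.voxel_spacing)
        nib.save(img, str(path))
        return
    if suf in _META_SUFFIXES:
        arr = np.moveaxis(data, (0, 1, 2), (2, 1, 0)) if data.ndim >= 3 else data
        img = sitk.GetImageFromArray(np.ascontiguousarray(arr))
        img.SetSpacing(tuple(record.voxel_spacing))
        sitk.WriteImage(img, str(path))
        return
    raise UnsupportedFormatError(f"unsupported volume format: {path.name}")


def read_field(path) -> DeformationField:
    """Read a deformation field stored as a 4D volume (x, y, z, component)."""
    rec = read_volume(path)
    if rec.data.ndim != 4 or rec.data.shape[3] != 3:
        raise UnsupportedFormatError(
            f"expected a 4D field with 3 components, got shape {rec.data.shape}"
        )
    return DeformationField(displacements=np.asarray(rec.data, dtype=float))


def write_field(field: DeformationField, path, voxel_spacing=(1.0, 1.0, 1.0)) -> None:
    write_volume(VolumeRecord(data=field.displacements, voxel_spacing=tuple(voxel_spacing)), path)


def read_landmarks(path) -> LandmarkSet:
    """Read landmarks from CSV with header x,y,z (0-based voxel coordinates)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text().strip().splitlines()
    if not text:
        raise LandmarkParseError("empty landmark file", line=1)
    header = [c.strip().lower() for c in text[0].split(",")]
    if header[:3] != ["x", "y", "z"]:
        raise LandmarkParseError(f"expected header 'x,y,z', got {text[0]!r}", line=1)
    pts = []
    for lineno, line in enumerate(text[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) < 3:
            raise LandmarkParseError(f"expected 3 columns, got {len(parts)}", line=lineno)
        try:
            pts.append([float(p) for p in parts[:3]])
        except ValueError as exc:
            raise LandmarkParseError(f"bad coordinate: {exc}", line=lineno) from exc
    if not pts:
        raise LandmarkParseError("no landmark rows", line=2)
    return LandmarkSet(points=np.asarray(pts, dtype=float))


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    df = pd.DataFrame(landmarks.points, columns=["x", "y", "z"])
    df.to_csv(path, index=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def write_report(report: dict, path) -> None:
    """Write a registration/evaluation report as JSON."""
    Path(path).write_text(json.dumps(_jsonable(report), indent=2))


def read_config(path) -> RegistrationConfig:
    """Read a flat YAML mapping of RegistrationConfig fields."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    valid = {f.name for f in dataclasses.fields(RegistrationConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise UnsupportedFormatError(f"unknown config keys: {sorted(unknown)}")
    if "patch_shape" in raw:
        raw["patch_shape"] = tuple(raw["patch_shape"])
    if "search_offsets" in raw:
        raw["search_offsets"] = tuple(tuple(r) for r in raw["search_offsets"])
    return RegistrationConfig(**raw)
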