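"""NIfTI / JSON / CSV format glue.

Every writer copies its reader's affine unchanged; echo series are stored
as complex 4-D NIfTI with a JSON sidecar holding the TE list, field
strength, fat spectrum, seed and noise level.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import AcquisitionParams, DeformationField, EchoSeries, QuantitativeMaps, RoiMask

__all__ = [
    "save_volume", "load_volume", "save_echo_series", "load_echo_series",
    "save_maps", "load_maps", "save_mask", "load_mask",
    "save_deformation_field", "load_deformation_field",
]

MAP_NAMES = ("ff", "t2star", "fieldmap", "water", "fat", "fit_ok")


def save_volume(values: np.ndarray, path, affine: np.ndarray | None = None) -> None:
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(values), affine), str(path))


def load_volume(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def save_echo_series(echoes: EchoSeries, path, seed: int | None = None) -> None:
    """Write a 4-D complex NIfTI plus a ``.json`` sidecar."""
    path = Path(path)
    nib.save(nib.Nifti1Image(echoes.data.astype(np.complex64), echoes.affine), str(path))
    sidecar = {
        "te": list(map(float, echoes.te)),
        "acquisition": echoes.acq.to_dict(),
        "seed": seed,
    }
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_echo_series(path) -> EchoSeries:
    path = Path(path)
    img = nib.load(str(path))
    sidecar = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    acq = AcquisitionParams.from_dict(sidecar["acquisition"])
    return EchoSeries(data=np.asarray(img.dataobj).astype(complex),
                      te=np.array(sidecar["te"]), acq=acq, affine=img.affine)


def save_maps(maps: QuantitativeMaps, outdir, prefix: str = "") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in MAP_NAMES:
        arr = getattr(maps, name)
        if arr.dtype == bool:
            arr = arr.astype(np.uint8)
        save_volume(arr, outdir / f"{prefix}{name}.nii.gz", maps.affine)


def load_maps(outdir, prefix: str = "") -> QuantitativeMaps:
    outdir = Path(outdir)
    arrays = {}
    affine = None
    for name in MAP_NAMES:
        arr, affine = load_volume(outdir / f"{prefix}{name}.nii.gz")
        arrays[name] = arr.astype(bool) if name == "fit_ok" else np.asarray(arr, dtype=float)
    return QuantitativeMaps(affine=affine, **arrays)


def save_mask(mask: RoiMask, path) -> None:
    path = Path(path)
    save_volume(mask.values.astype(np.float32), path, mask.affine)
    meta = {"voxel_volume": mask.voxel_volume, "label": mask.label}
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_mask(path) -> RoiMask:
    path = Path(path)
    values, affine = load_volume(path)
    meta = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    return RoiMask(values=np.asarray(values, dtype=float), affine=affine, **meta)


def save_deformation_field(field: DeformationField, path) -> None:
    save_volume(field.displacements.astype(np.float32), path, field.affine)


def load_deformation_field(path) -> DeformationField:
    disp, affine = load_volume(path)
    return DeformationField(displacements=np.asarray(disp, dtype=float), affine=affine)
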