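"""Mask/map resampling through dense deformation fields, and the in-plane
neighborhood smoothing applied before voxel-wise comparison.

Registration itself is out of scope: deformation fields are consumed in the
pulling (target-grid) convention common to registration toolboxes — the
output voxel at world position x samples the input image at
x + displacement(x), displacements in mm.  A helper generates smooth
synthetic fields (and their numerical inverses) for testing.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import ndimage

from .core import DeformationField, RoiMask

__all__ = [
    "transform_volume", "transform_mask", "neighborhood_mean",
    "make_synthetic_field", "invert_field",
]


def _check_compatible(affine_a: np.ndarray, shape_a, field: DeformationField) -> None:
    if tuple(shape_a) != field.shape or not np.allclose(affine_a, field.affine, atol=1e-6):
        raise ValueError(
            "incompatible grids: input affine\n"
            f"{affine_a}\n(shape {tuple(shape_a)}) vs field affine\n"
            f"{field.affine}\n(shape {field.shape})"
        )


def transform_volume(values: np.ndarray, affine: np.ndarray,
                     field: DeformationField, order: int = 1,
                     mode: str = "constant", cval: float = 0.0) -> np.ndarray:
    """Resample a volume through a displacement field (trilinear by default).

    The identity field reproduces the input exactly, and integer-voxel
    translations are lattice-preserving (no interpolation blur).
    """
    _check_compatible(affine, values.shape, field)
    idx = np.indices(field.shape, dtype=float)  # (3, x, y, z)
    world = np.einsum("ij,j...->i...", field.affine[:3, :3], idx) + field.affine[:3, 3, None, None, None]
    world = world + np.moveaxis(field.displacements, -1, 0)
    inv = np.linalg.inv(affine)
    src = np.einsum("ij,j...->i...", inv[:3, :3], world) + inv[:3, 3, None, None, None]
    return ndimage.map_coordinates(values.astype(float), src, order=order,
                                   mode=mode, cval=cval)


def transform_mask(mask: RoiMask, field: DeformationField,
                   binarize_threshold: float | None = None) -> RoiMask:
    """Pull an ROI mask through a deformation field.

    The result is kept as floating-point fractional weights (the default
    analysis mode); pass ``binarize_threshold`` to binarize for
    voxel-counting analyses.
    """
    out = transform_volume(mask.values.astype(float), mask.affine, field)
    out = np.clip(out, 0.0, 1.0)
    if binarize_threshold is not None:
        out = (out >= binarize_threshold).astype(float)
    return replace(mask, values=out, affine=field.affine.copy())


def neighborhood_mean(volume: np.ndarray, k: int = 3, three_d: bool = False) -> np.ndarray:
    """k×k in-plane (or k×k×k with ``three_d``) moving mean, edges replicated.

    Applied identically to both time points before voxel-wise differencing
    to suppress interpolation bias and small registration inconsistencies.
    """
    if k % 2 == 0 or k < 1:
        raise ValueError("neighborhood size k must be odd and positive")
    size = (k, k, k) if three_d else (k, k, 1)
    return ndimage.uniform_filter(volume.astype(float), size=size, mode="nearest")


def make_synthetic_field(shape, affine: np.ndarray | None = None,
                         amplitude_mm: float = 1.5, smoothness: float = 6.0,
                         seed: int = 0) -> DeformationField:
    """Smooth random displacement field for tests and phantoms.

    ``amplitude_mm`` is the RMS displacement per component; ``smoothness``
    the Gaussian correlation length in voxels.
    """
    rng = np.random.default_rng(seed)
    if affine is None:
        affine = np.eye(4)
    disp = np.empty((*shape, 3))
    for c in range(3):
        noise = rng.standard_normal(shape)
        smooth = ndimage.gaussian_filter(noise, sigma=smoothness)
        sd = smooth.std()
        disp[..., c] = amplitude_mm * (smooth / sd if sd > 0 else smooth)
    return DeformationField(displacements=disp, affine=np.asarray(affine, dtype=float))


def invert_field(field: DeformationField, n_iter: int = 30) -> DeformationField:
    """Numerical inverse of a displacement field by fixed-point iteration.

    Solves ``inv(x) = -disp(x + inv(x))`` on the same grid; accurate for
    smooth, small-amplitude fields.
    """
    inv_disp = np.zeros_like(field.displacements)
    for _ in range(n_iter):
        sampled = np.empty_like(inv_disp)
        probe = DeformationField(inv_disp, field.affine)
        for c in range(3):
            sampled[..., c] = transform_volume(field.displacements[..., c],
                                               field.affine, probe, mode="nearest")
        inv_disp = -sampled
    return DeformationField(displacements=inv_disp, affine=field.affine.copy())
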