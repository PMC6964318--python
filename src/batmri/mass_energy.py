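"""FF → lean/fat volume, mass, and metabolizable energy.

A voxel of volume v with fat fraction FF partitions into ``FF·v`` μL of
lipid and ``(1-FF)·v`` μL of lean (water-bound) tissue.  Default
conversion constants: 1 μL of lipid is 0.92 mg and 9.4e-3 kcal; 1 μL of
lean tissue is 1.06 mg and 1.0e-3 kcal.  The signal fat fraction is used
directly as a volume fraction, with no proton-density or T1 correction
(a documented limitation shared with the analysis this reproduces).

Constants always travel in a :class:`CompositionConstants` object so they
can be audited and overridden; they are never hard-coded at call sites.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import RoiMask, ThresholdRange
from .global_analysis import SubjectData, ThresholdGrid, threshold_sweep

__all__ = [
    "CompositionConstants", "VoxelComposition", "voxel_composition",
    "depot_totals", "energy_threshold_grid", "mass_volume_r2",
]


@dataclass(frozen=True)
class CompositionConstants:
    """Density (mg/μL) and metabolizable energy (kcal/μL) of the two
    tissue compartments."""

    fat_density: float = 0.92
    lean_density: float = 1.06
    fat_energy: float = 9.4e-3
    lean_energy: float = 1.0e-3

    def __post_init__(self) -> None:
        if min(asdict(self).values()) <= 0:
            raise ValueError("all composition constants must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


class VoxelComposition(NamedTuple):
    fat_volume: float  # μL
    lean_volume: float  # μL
    fat_mass: float  # mg
    lean_mass: float  # mg
    fat_energy: float  # kcal
    lean_energy: float  # kcal


def voxel_composition(ff, voxel_volume: float,
                      constants: CompositionConstants | None = None) -> VoxelComposition:
    """Partition voxel volume into fat/lean volume, mass and energy.

    ``ff`` is a fraction in [0, 1] (scalar or array; the partition is
    elementwise).
    """
    if constants is None:
        constants = CompositionConstants()
    ff = np.asarray(ff, dtype=float)
    if np.any(ff < 0) or np.any(ff > 1):
        raise ValueError("ff must lie in [0, 1]")
    fat_vol = ff * voxel_volume
    lean_vol = (1.0 - ff) * voxel_volume
    return VoxelComposition(
        fat_volume=fat_vol, lean_volume=lean_vol,
        fat_mass=fat_vol * constants.fat_density,
        lean_mass=lean_vol * constants.lean_density,
        fat_energy=fat_vol * constants.fat_energy,
        lean_energy=lean_vol * constants.lean_energy,
    )


def depot_totals(ff: np.ndarray, roi: RoiMask, range: ThresholdRange,
                 constants: CompositionConstants | None = None,
                 bin_width: float = 0.5) -> pd.DataFrame:
    """Composition table of a depot inside an FF threshold range.

    Returns one row per FF bin plus a ``total`` row, with fat/lean volume
    (μL), mass (g), energy (kcal) and total energy.  Totals equal the
    brute-force per-voxel sum; fat and lean volume partition the analyzed
    volume exactly.
    """
    if constants is None:
        constants = CompositionConstants()
    sel = range.contains(ff * 100.0) & (roi.values > 0)
    w = roi.values[sel]
    ffv = ff[sel]
    if w.size == 0:
        import warnings
        warnings.warn(f"empty segmentation for range {range.lower}-{range.upper}%")
    comp = voxel_composition(ffv, roi.voxel_volume, constants)
    edges = np.arange(range.lower, range.upper + bin_width / 2, bin_width)
    ffp = ffv * 100.0

    def binned(x):
        h, _ = np.histogram(ffp, bins=edges, weights=w * x)
        return h

    df = pd.DataFrame({
        "ff_lower": edges[:-1], "ff_upper": edges[1:],
        "fat_volume_ul": binned(comp.fat_volume),
        "lean_volume_ul": binned(comp.lean_volume),
        "fat_mass_g": binned(comp.fat_mass) / 1000.0,
        "lean_mass_g": binned(comp.lean_mass) / 1000.0,
        "fat_energy_kcal": binned(comp.fat_energy),
        "lean_energy_kcal": binned(comp.lean_energy),
    })
    total = {
        "ff_lower": range.lower, "ff_upper": range.upper,
        "fat_volume_ul": float((w * comp.fat_volume).sum()),
        "lean_volume_ul": float((w * comp.lean_volume).sum()),
        "fat_mass_g": float((w * comp.fat_mass).sum()) / 1000.0,
        "lean_mass_g": float((w * comp.lean_mass).sum()) / 1000.0,
        "fat_energy_kcal": float((w * comp.fat_energy).sum()),
        "lean_energy_kcal": float((w * comp.lean_energy).sum()),
    }
    df = pd.concat([df, pd.DataFrame([total], index=["total"])])
    df["total_energy_kcal"] = df["fat_energy_kcal"] + df["lean_energy_kcal"]
    df.attrs["constants"] = constants.to_dict()
    df.attrs["voxel_volume_ul"] = roi.voxel_volume
    return df


def energy_threshold_grid(subjects: list[SubjectData], step: float = 1.0,
                          lower_min: float = 30.0,
                          constants: CompositionConstants | None = None,
                          ) -> ThresholdGrid:
    """Cohort-mean post-minus-pre total energy for every threshold pair.

    The sign of the change can invert between ranges (losses in the
    high-lipid zone, gains in the leaner zone); the grid makes that
    explicit.
    """
    if constants is None:
        constants = CompositionConstants()
    return threshold_sweep(subjects, "energy", step=step, lower_min=lower_min,
                           fat_energy=constants.fat_energy,
                           lean_energy=constants.lean_energy)


def mass_volume_r2(volumes_ml, masses_g) -> tuple[float, float, float]:
    """OLS regression of per-subject mass on depot volume.

    Returns ``(slope, intercept, r_squared)``.
    """
    volumes_ml = np.asarray(volumes_ml, dtype=float)
    masses_g = np.asarray(masses_g, dtype=float)
    if len(volumes_ml) < 3:
        raise ValueError("at least 3 subjects required")
    if np.std(volumes_ml) == 0:
        raise ValueError("zero variance in volumes")
    res = stats.linregress(volumes_ml, masses_g)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)
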