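"""Shared data containers for the water-fat MRI pipeline.

Conventions used throughout the package:

* volumes are ``numpy`` arrays indexed ``(x, y, z)``; echo series add a
  trailing echo axis;
* echo times are seconds, field maps Hz, T2* milliseconds;
* fat fraction (FF) is a fraction in ``[0, 1]`` in memory and a percent at
  every user-facing interface (thresholds, tables, reports);
* voxel volume is microlitres (μL), depot volumes millilitres (mL).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

GAMMA_HZ_PER_T_PPM = 42.5774806  # proton gyromagnetic ratio, Hz per tesla per ppm
WATER_PPM = 4.70

#: Six-peak triglyceride spectrum: (chemical shift ppm, relative amplitude).
#: Methyl, methylene, alpha-olefinic/carboxyl, diacyl, glycerol, olefinic.
DEFAULT_FAT_PEAKS_PPM: tuple[tuple[float, float], ...] = (
    (0.90, 0.088),
    (1.30, 0.700),
    (2.10, 0.120),
    (2.75, 0.006),
    (4.20, 0.039),
    (5.29, 0.047),
)


def fat_peaks_hz(field_strength: float,
                 peaks_ppm: Sequence[tuple[float, float]] = DEFAULT_FAT_PEAKS_PPM,
                 ) -> tuple[tuple[float, float], ...]:
    """Convert a ppm fat spectrum to frequency offsets from water in Hz."""
    hz_per_ppm = GAMMA_HZ_PER_T_PPM * field_strength
    return tuple(((ppm - WATER_PPM) * hz_per_ppm, amp) for ppm, amp in peaks_ppm)


@dataclass(frozen=True)
class AcquisitionParams:
    """Multi-echo gradient-echo acquisition settings.

    Defaults mirror a 3 T six-point chemical-shift encoded protocol
    (TE1 = 1.98 ms, ΔTE = 1.75 ms).  ``fat_peaks`` holds (offset Hz relative
    to water, relative amplitude) pairs; amplitudes must sum to one.
    ``noise_sd`` is the complex Gaussian noise SD on each channel, relative
    to the peak first-echo magnitude.
    """

    te_first: float = 1.98e-3
    delta_te: float = 1.75e-3
    n_echoes: int = 6
    field_strength: float = 3.0
    fat_peaks: tuple[tuple[float, float], ...] = field(default=None)  # type: ignore[assignment]
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.fat_peaks is None:
            object.__setattr__(self, "fat_peaks", fat_peaks_hz(self.field_strength))
        amps = np.array([a for _, a in self.fat_peaks], dtype=float)
        total = amps.sum()
        if abs(total - 1.0) > 1e-9:
            # normalize once so the stored spectrum satisfies the invariant
            peaks = tuple((f, a / total) for f, a in self.fat_peaks)
            object.__setattr__(self, "fat_peaks", peaks)
        if self.n_echoes < 3:
            raise ValueError("at least 3 echoes are required for water-fat-T2*-field fitting")
        if self.te_first <= 0 or self.delta_te <= 0:
            raise ValueError("echo times must be positive")

    @property
    def te(self) -> np.ndarray:
        """Echo times in seconds."""
        return self.te_first + self.delta_te * np.arange(self.n_echoes)

    def to_dict(self) -> dict:
        return {
            "te_first": self.te_first,
            "delta_te": self.delta_te,
            "n_echoes": self.n_echoes,
            "field_strength": self.field_strength,
            "fat_peaks": [list(p) for p in self.fat_peaks],
            "noise_sd": self.noise_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionParams":
        d = dict(d)
        if d.get("fat_peaks") is not None:
            d["fat_peaks"] = tuple(tuple(p) for p in d["fat_peaks"])
        return cls(**d)


@dataclass
class EchoSeries:
    """Complex multi-echo volume with echo-time metadata."""

    data: np.ndarray  # complex, (x, y, z, echo)
    te: np.ndarray  # seconds, strictly increasing
    acq: AcquisitionParams
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.te = np.asarray(self.te, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("echo data must be 4-D (x, y, z, echo)")
        if self.data.shape[-1] != len(self.te):
            raise ValueError(
                f"echo dimension {self.data.shape[-1]} disagrees with TE list of length {len(self.te)}"
            )
        if np.any(np.diff(self.te) <= 0):
            raise ValueError("echo times must be strictly increasing")
        if self.acq.n_echoes != len(self.te):
            raise ValueError("acquisition n_echoes disagrees with stored TE list")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class QuantitativeMaps:
    """Co-located water, fat, FF, T2* and field maps from one reconstruction.

    ``ff = fat / (fat + water)`` wherever the denominator is positive;
    voxels where the fit failed or the signal vanished carry
    ``fit_ok == False`` and ``ff = nan`` — never a silent zero.
    """

    water: np.ndarray
    fat: np.ndarray
    ff: np.ndarray  # fraction in [0, 1]
    t2star: np.ndarray  # ms
    fieldmap: np.ndarray  # Hz
    fit_ok: np.ndarray  # bool
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))


@dataclass
class RoiMask:
    """Region-of-interest mask with voxel-volume metadata.

    ``values`` are in [0, 1]: binary when drawn, floating-point after a
    nonrigid transformation (fractional voxel weights).
    """

    values: np.ndarray
    voxel_volume: float  # μL
    label: str = "supraclavicular"
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        if self.voxel_volume <= 0:
            raise ValueError("voxel_volume must be positive")
        v = np.asarray(self.values)
        if v.size and (np.nanmin(v) < -1e-9 or np.nanmax(v) > 1 + 1e-9):
            raise ValueError("mask values must lie in [0, 1]")

    def binarized(self, threshold: float = 0.5) -> "RoiMask":
        return replace(self, values=(self.values >= threshold).astype(float))


@dataclass
class DeformationField:
    """Dense displacement field in mm on the target-image grid (pulling
    convention): a target voxel at world position x samples the source image
    at x + displacement(x)."""

    displacements: np.ndarray  # (x, y, z, 3), mm
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        if self.displacements.ndim != 4 or self.displacements.shape[-1] != 3:
            raise ValueError("displacements must be (x, y, z, 3)")
        if not np.all(np.isfinite(self.displacements)):
            raise ValueError("displacement field must be finite everywhere")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.displacements.shape[:3]


@dataclass(frozen=True)
class ThresholdRange:
    """Inclusive FF threshold range in percent, ``lower ≤ FF ≤ upper``."""

    lower: float
    upper: float
    min_lower: float = 0.0  # BAT analyses pass 30.0

    def __post_init__(self) -> None:
        if not (0 <= self.lower < self.upper <= 100):
            raise ValueError(f"invalid FF range {self.lower}-{self.upper}%")
        if self.lower < self.min_lower:
            raise ValueError(
                f"lower threshold {self.lower}% below the analysis minimum {self.min_lower}%"
            )

    def contains(self, ff_percent: np.ndarray) -> np.ndarray:
        return (ff_percent >= self.lower) & (ff_percent <= self.upper)
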