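"""Run configuration: one serializable object holding every knob.

Every pipeline run writes its fully resolved configuration beside its
outputs, so any numeric artifact can be regenerated bit-identically.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .core import AcquisitionParams
from .mass_energy import CompositionConstants
from .phantom import DEFAULT_SHAPE, DEFAULT_VOXEL_VOLUME_UL, ColdEffectParams

ALL_STAGES = ("simulate", "reconstruct", "transform", "analyze-global",
              "mass-energy", "analyze-local", "report")


@dataclass
class RunConfig:
    outdir: str = "batmri_run"
    seed: int = 0
    n_subjects: int = 9
    shape: tuple[int, int, int] = DEFAULT_SHAPE
    voxel_volume: float = DEFAULT_VOXEL_VOLUME_UL
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    cold_effect: ColdEffectParams = field(default_factory=ColdEffectParams)
    constants: CompositionConstants = field(default_factory=CompositionConstants)
    map_source: str = "recon"  # "recon" or "truth"
    lower_min: float = 30.0
    threshold_ranges: tuple[tuple[float, float], ...] = ((30, 100), (50, 100), (70, 100))
    sat_range: tuple[float, float] = (70, 100)
    histogram_bin: float = 0.5
    volume_change_bin: float = 10.0
    sweep_step: float = 1.0
    smoothing_k: int = 3
    cluster_k_max: int = 8
    cluster_cutoff: float = 0.95
    cluster_restarts: int = 10

    def to_dict(self) -> dict:
        d = asdict(self)
        d["shape"] = list(self.shape)
        d["threshold_ranges"] = [list(r) for r in self.threshold_ranges]
        d["sat_range"] = list(self.sat_range)
        d["acquisition"] = self.acquisition.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "shape" in d:
            d["shape"] = tuple(d["shape"])
        if "threshold_ranges" in d:
            d["threshold_ranges"] = tuple(tuple(r) for r in d["threshold_ranges"])
        if "sat_range" in d:
            d["sat_range"] = tuple(d["sat_range"])
        if isinstance(d.get("acquisition"), dict):
            d["acquisition"] = AcquisitionParams.from_dict(d["acquisition"])
        if isinstance(d.get("cold_effect"), dict):
            d["cold_effect"] = ColdEffectParams(**d["cold_effect"])
        if isinstance(d.get("constants"), dict):
            d["constants"] = CompositionConstants(**d["constants"])
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
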