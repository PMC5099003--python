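"""Pipeline configuration: every study constant in one overridable place.

Defaults carry the study conditions: paired 622/594 um carotids with mean
inlet velocities 112.8/153.4 mm/s, a 500 -> 250 um cuff, an 8 Hz cycle at
300 steps exporting every 10th, blood viscosity 3.5 mPa*s and density
1050 kg/m^3, the 1.6 mm upstream plaque extent, the 0.67 log-quantile
threshold multiplier and the 0.005 near-zero floor.  Configurations
round-trip losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .metrics import LOG_QUANTILE_MULTIPLIER
from .synthetic import DisturbanceSpec, FluidProps, VesselSpec


@dataclass
class PipelineConfig:
    """Full configuration for the simulate -> metrics -> analyze pipeline."""

    n_mice: int = 7
    master_seed: int = 0
    plaque_extent_mm: float = 1.6
    floor: float = 0.005
    threshold_multiplier: float = LOG_QUANTILE_MULTIPLIER
    threshold_mode: str = "per_mouse"   # per_mouse | pooled
    ttest_mode: str = "unpaired"        # unpaired | paired
    n_s_bins: int = 40
    n_theta_bins: int = 16
    output_dir: str = "cuffshear_results"
    fluid: FluidProps = field(default_factory=FluidProps)
    instrumented: VesselSpec = field(
        default_factory=VesselSpec.default_instrumented)
    control: VesselSpec = field(default_factory=VesselSpec.default_control)

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("per_mouse", "pooled"):
            raise ValueError("threshold_mode must be 'per_mouse' or 'pooled'")
        if self.ttest_mode not in ("unpaired", "paired"):
            raise ValueError("ttest_mode must be 'unpaired' or 'paired'")
        if self.n_mice < 2:
            raise ValueError("n_mice must be >= 2")
        if self.floor <= 0 or self.plaque_extent_mm <= 0:
            raise ValueError("floor and plaque extent must be positive")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "fluid" in data and isinstance(data["fluid"], dict):
            data["fluid"] = FluidProps(**data["fluid"])
        for key in ("instrumented", "control"):
            if key in data and isinstance(data[key], dict):
                spec = dict(data[key])
                if isinstance(spec.get("disturbance"), dict):
                    spec["disturbance"] = DisturbanceSpec(**spec["disturbance"])
                data[key] = VesselSpec(**spec)
        return cls(**data)

    def save(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_dict(
            yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        )

    def config_hash(self) -> str:
        """Deterministic provenance hash of the full configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
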