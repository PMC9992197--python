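"""Pipeline configuration: a single serializable object covering every
stage, with a stable content hash recorded in all outputs."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .bands import Band, BandScheme
from .exceptions import ConfigurationError
from .simulate import CohortDesign, EffectMap, GROUPS


@dataclass
class PipelineConfig:
    """End-to-end settings for simulate -> preprocess -> invert -> spectra -> stats."""

    design: CohortDesign = field(default_factory=CohortDesign)
    # preprocessing
    notch_base_freq: float = 50.0
    notch_bandwidth: float = 2.0
    segment_duration: float = 30.0
    segment_mad_factor: float = 10.0
    cov_shrinkage: float = 0.1
    # inverse
    lambda2: float = 0.33
    depth_exponent: float = 0.5
    depth_limit: float = 10.0
    # spectra
    welch_window_s: float = 5.0
    welch_overlap: float = 0.5
    roi_reduction: str = "power"
    # stats
    alpha: float = 0.05
    reporting_cut: float = 0.005
    # bookkeeping
    out_dir: str = "corespec_out"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is not None:
            self.design = self.design.replace(master_seed=int(self.seed))
        if self.roi_reduction not in ("power", "mean"):
            raise ConfigurationError(
                f"roi_reduction must be 'power' or 'mean', got "
                f"{self.roi_reduction!r}"
            )

    def replace(self, **changes) -> "PipelineConfig":
        return replace(self, **changes)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        data = asdict(self)
        design = data["design"]
        design["band_scheme"] = [
            {"name": b.name, "f_lo": b.f_lo, "f_hi": b.f_hi}
            for b in self.design.band_scheme
        ]
        design["effects"] = {
            group: {f"{roi}|{band}": mult for (roi, band), mult in cells.items()}
            for group, cells in self.design.effects.items()
        }
        return data

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        design_data = dict(data.pop("design", {}))
        if "band_scheme" in design_data:
            design_data["band_scheme"] = BandScheme(
                [Band(**b) for b in design_data["band_scheme"]]
            )
        if "effects" in design_data:
            effects: EffectMap = {}
            for group, cells in design_data["effects"].items():
                if group not in GROUPS:
                    raise ConfigurationError(f"unknown group {group!r} in config")
                effects[group] = {
                    tuple(key.split("|", 1)): float(mult)
                    for key, mult in cells.items()
                }
            design_data["effects"] = effects
        design = CohortDesign(**design_data) if design_data else CohortDesign()
        return cls(design=design, **data)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(data or {})

    def hash(self) -> str:
        """Content hash recorded in output provenance."""
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]
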