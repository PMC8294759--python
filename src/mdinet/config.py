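"""Pipeline configuration: every threshold in one auditable place.

Defaults are the study's printed operating points: S/N >= 4, minimum
intensity 1.5e6 counts, 1-ppm alignment window, 3-ppm isotopologue spacing
tolerance with r >= 0.9, 10% presence, 0.1-ppm network edge error, 0.2-ppm
annotation tolerance, 10 allowed assignment failures, sevenfold CV, and the
"reference class count > 40" rule for tissue-style ORA.  Configs round-trip
losslessly through YAML and can be layered (defaults < file < overrides).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    # peak filtering
    snr: float = 4.0
    min_intensity: float = 1.5e6
    # mass-defect feasibility filter
    mass_defect_filter: bool = True
    mass_defect_ppm: float = 1.0
    acquisition_min_mz: float = 147.4
    acquisition_max_mz: float = 1000.0
    # calibration
    calibration_match_ppm: float = 2.0
    calibration_min_matches: int = 5
    # alignment & matrix cleaning
    align_ppm: float = 1.0
    isotopologue_removal: bool = True
    isotope_ppm: float = 3.0
    isotope_r: float = 0.9
    presence_fraction: float = 0.10
    # network & annotation
    edge_ppm: float = 0.1
    annotation_ppm: float = 0.2
    max_failures: int = 10
    n_auto_seeds: int = 5
    # multivariate
    folds: int = 7
    keep_fraction: float = 0.5
    max_iter: int = 20
    component_grid: tuple[int, ...] = (1, 2, 3, 4, 5)
    scaling: str = "uv"  # "uv" (unit variance) or "center"
    risk_label: str = "risk"
    # enrichment
    min_class_size: int | None = 40  # tissue-style ORA only; None disables
    ora_tail: str = "upper"
    mdea_min_edges: int = 5
    add_qvalues: bool = False
    # replication selection
    replication_p: float = 0.1
    # global seed
    seed: int = 0
    # file paths (all optional; synthetic runs fill them in)
    paths: dict = field(default_factory=dict)
    # synthetic-data generation parameters
    simulate: dict = field(default_factory=dict)

    @property
    def scale(self) -> bool:
        return self.scaling == "uv"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["component_grid"] = list(self.component_grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        d = dict(d)
        if "component_grid" in d:
            d["component_grid"] = tuple(d["component_grid"])
        return cls(**d)

    def updated(self, **overrides) -> "PipelineConfig":
        d = self.to_dict()
        d.update(overrides)
        return self.from_dict(d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def load_config(path=None, **overrides) -> PipelineConfig:
    """Layered config: package defaults < YAML file < keyword overrides."""
    cfg = PipelineConfig.from_yaml(path) if path else PipelineConfig()
    return cfg.updated(**overrides) if overrides else cfg
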