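"""Run configuration: every analysis constant in one serializable record.

Defaults equal the study's printed values (10 discarded volumes, 4 mm
FWHM smoothing, 0.01–0.08 Hz band, 2.0 mm / 2.0 degree exclusion
thresholds, first-level FDR q = 0.01 with 20-voxel extent, cluster-forming
Z = 2.3 with cluster alpha 0.05, 40% gray-matter threshold, 5 mm spheres).
Unknown keys in a config file are errors, protecting against silent typos
in threshold names.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    # preprocessing
    n_discard: int = 10
    fwhm_mm: float = 4.0
    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    fd_radius_mm: float = 50.0
    translation_limit_mm: float = 2.0
    rotation_limit_deg: float = 2.0
    # statistics
    first_level_q: float = 0.01
    first_level_extent: int = 20
    cluster_forming_z: float = 2.3
    cluster_alpha: float = 0.05
    gm_threshold: float = 0.40
    sphere_radius_mm: float = 5.0
    posthoc_alpha: float = 0.05
    # oracle / reproducibility
    n_perm: int = 0  # 0 disables the permutation oracle during a run
    seed: int = 0
    schema_version: int = SCHEMA_VERSION

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if cfg.schema_version != SCHEMA_VERSION:
            raise ValueError(
                f"config schema version {cfg.schema_version} != {SCHEMA_VERSION}"
            )
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
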