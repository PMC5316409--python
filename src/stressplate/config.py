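"""Run configuration: one validated object drives the whole pipeline.

A :class:`RunConfig` collects every stage's tunables, the root seed and the
output directory, and round-trips through YAML so a run can be reproduced
from its manifest.  All parameters are validated up front, before any
stage executes.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cluster import LINKAGES, METRICS
from .synthetic import CLASS_NAMES


class ConfigError(ValueError):
    """Raised when a run configuration fails validation."""


@dataclass
class TreatmentConfig:
    """Dynamics class planted for one treatment."""

    class_name: str = "null"
    onset_h: float = 2.0
    peak_h: float = 8.0
    decay_h: float = 15.0
    amplitude: float = 1.0
    noise_cv: float = 0.2


@dataclass
class PlateConfig:
    """One simulated plate: batch effect and imaging duration."""

    plate_id: str = "P1"
    intensity_scale: float = 1.0
    intensity_shift: float = 0.0
    total_duration_h: float = 24.0


@dataclass
class SimulateConfig:
    mode: str = "curves"  # curves | images
    plates: list[PlateConfig] = field(
        default_factory=lambda: [
            PlateConfig("P1", 1.0, 0.0, 24.0),
            PlateConfig("P2", 1.6, 0.1, 22.0),
        ]
    )
    reporters: list[str] = field(default_factory=lambda: ["Nrf2", "Srxn1", "p21"])
    treatments: dict[str, TreatmentConfig] = field(
        default_factory=lambda: {
            "CDDO": TreatmentConfig("transient_nuclear", 2.0, 8.0, 15.0, 4.0, 0.2),
            "DEM": TreatmentConfig("sustained_cytosolic", 3.0, 12.0, 24.0, 3.0, 0.2),
            "ETOP": TreatmentConfig("sustained_cytosolic", 4.0, 14.0, 24.0, 2.5, 0.2),
        }
    )
    n_replicates: int = 3
    concentration: float = 10.0
    death_fraction: float = 0.0
    n_cells: int = 25


@dataclass
class NormalizeConfig:
    df: int = 6
    n_out: int = 24
    scaling: str = "minmax"  # minmax | none
    quantile: bool = True


@dataclass
class StatsConfig:
    variant: str = "pooled"  # pooled | welch
    meandiff_on: str = "x_diff"  # x_diff | raw


@dataclass
class ClusterConfig:
    metric: str = "euclidean"
    linkage: str = "complete"
    compare_axis: str = "treatment"
    n_clusters: int = 3


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "stressplate_run"
    stages: list[str] = field(
        default_factory=lambda: ["simulate", "normalize", "stats", "cluster"]
    )
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    normalize: NormalizeConfig = field(default_factory=NormalizeConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)

    def validate(self) -> "RunConfig":
        known = {"simulate", "quantify", "normalize", "stats", "cluster"}
        bad = [s for s in self.stages if s not in known]
        if bad:
            raise ConfigError(f"unknown stages {bad}; choose from {sorted(known)}")
        if self.simulate.mode not in ("curves", "images"):
            raise ConfigError("simulate.mode must be 'curves' or 'images'")
        for name, tc in self.simulate.treatments.items():
            if tc.class_name not in CLASS_NAMES:
                raise ConfigError(
                    f"treatment {name!r}: unknown class {tc.class_name!r}"
                )
        if self.normalize.df < 1 or self.normalize.n_out < 2:
            raise ConfigError("normalize.df must be >=1 and n_out >=2")
        if self.normalize.scaling not in ("minmax", "none"):
            raise ConfigError("normalize.scaling must be 'minmax' or 'none'")
        if self.stats.variant not in ("pooled", "welch"):
            raise ConfigError("stats.variant must be 'pooled' or 'welch'")
        if self.cluster.metric not in METRICS:
            raise ConfigError(f"cluster.metric must be one of {METRICS}")
        if self.cluster.linkage not in LINKAGES:
            raise ConfigError(f"cluster.linkage must be one of {LINKAGES}")
        if self.cluster.compare_axis not in ("treatment", "reporter"):
            raise ConfigError("cluster.compare_axis must be 'treatment' or 'reporter'")
        ids = [p.plate_id for p in self.simulate.plates]
        if len(set(ids)) != len(ids):
            raise ConfigError(f"duplicate plate ids in simulate.plates: {ids}")
        return self

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        sim = dict(data.get("simulate", {}))
        if "plates" in sim:
            sim["plates"] = [PlateConfig(**p) for p in sim["plates"]]
        if "treatments" in sim:
            sim["treatments"] = {
                k: TreatmentConfig(**v) for k, v in sim["treatments"].items()
            }
        cfg = cls(
            seed=int(data.get("seed", 0)),
            outdir=str(data.get("outdir", "stressplate_run")),
            stages=list(data.get("stages", ["simulate", "normalize", "stats", "cluster"])),
            simulate=SimulateConfig(**sim),
            normalize=NormalizeConfig(**data.get("normalize", {})),
            stats=StatsConfig(**data.get("stats", {})),
            cluster=ClusterConfig(**data.get("cluster", {})),
        )
        return cfg.validate()

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def content_hash(self) -> str:
        """Stable hash of the canonical YAML dump, recorded in manifests."""
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(canon).hexdigest()[:16]
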