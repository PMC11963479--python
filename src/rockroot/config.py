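"""Run configuration for the simulation and reproduction commands."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml

from .errors import ConfigError

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class RunConfig:
    """Declarative configuration of one simulation experiment.

    Defaults reproduce the packaged single-root microdomain: a 9 mm2
    square with a centered 1 mm root, 40% rock, 100 um cells, drying
    from saturation to a -1.5 MPa root boundary.
    """

    schema_version: int = SCHEMA_VERSION
    rock: str = "breccia"  # breccia | dolostone
    contact: bool = True
    root_material: str = "root_stressed"  # root_ww | root_stressed
    area_mm2: float = 9.0
    root_diameter_mm: float = 1.0
    rock_fraction: float = 0.4
    cell_um: float = 100.0
    n_rock_blocks: int = 2
    psi_init: float = 0.0
    psi_root: float = -1.5
    t_end_s: float = 3600.0
    dt_init_s: float = 1e-2
    dt_max_s: float = 10.0
    dt_min_s: float = 1e-3
    picard_tol: float = 1e-6
    snapshot_every_s: float = 0.0  # 0 disables field snapshots
    wilting_fraction: float = 0.99  # psi_max threshold as fraction of psi_root
    seed: int = 0

    def __post_init__(self) -> None:
        if self.schema_version != SCHEMA_VERSION:
            raise ConfigError(
                f"unsupported schema_version {self.schema_version} "
                f"(expected {SCHEMA_VERSION})"
            )
        if self.rock not in ("breccia", "dolostone"):
            raise ConfigError(f"unknown rock {self.rock!r}")
        if self.root_material not in ("root_ww", "root_stressed"):
            raise ConfigError(f"unknown root_material {self.root_material!r}")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        """Short stable digest of the full configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
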