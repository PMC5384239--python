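"""Run configuration: a fully serializable description of a protocol run.

One YAML document drives the whole pipeline (fixture generation aside):
input structures, anchor mapping, native-distance table, region lengths,
integrator settings, phosphorylation flag, seed.  Every output file
header records the config digest so runs are traceable.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import yaml

from .errors import ConfigError

__all__ = ["RunConfig", "load_config", "dump_config", "config_digest"]

SCHEMA_ID = "flycast/run-config/1"


@dataclass
class RunConfig:
    # inputs: paths to PDB files (chain ids taken from the files)
    structure_a: str = ""
    structure_b: str = ""
    # Region I anchor mapping: [[ [chain, res], [chain, [res, ...]] ], ...]
    anchors: list = field(default_factory=list)
    wall_d0: float = 5.0
    wall_k: float = 10.0
    # Region III table: pairs [[chain, res], [chain, res]] + distances (Å)
    native_pairs: list = field(default_factory=list)
    native_distances: list = field(default_factory=list)
    native_k: float = 10.0
    # Gō-style inter-chain attraction defining the bound state:
    # [[chain, res], [chain, res], rest distance Å] per contact
    interface_contacts: list = field(default_factory=list)
    interface_eps: float = 2.0  # k_BT per interface contact
    region_steps: list = field(default_factory=lambda: [10000, 90000, 10000])
    separation: float = 60.0
    contact_cutoff: float = 8.0
    potential: dict = field(default_factory=dict)
    dynamics: dict = field(default_factory=dict)
    phospho: dict = field(default_factory=dict)
    seed: int = 0
    output_dir: str = "."
    schema: str = SCHEMA_ID

    def __post_init__(self):
        if self.schema != SCHEMA_ID:
            raise ConfigError(
                f"unsupported config schema {self.schema!r}")
        if len(self.region_steps) != 3 or min(self.region_steps) <= 0:
            raise ConfigError("region_steps must be three positive ints")
        if self.native_pairs and len(self.native_pairs) != len(
                self.native_distances):
            raise ConfigError("native_pairs and native_distances must pair up")
        self.anchors = [
            ((a[0], int(a[1])), (g[0], [int(r) for r in g[1]]))
            for a, g in self.anchors
        ]
        self.native_pairs = [
            ((p[0], int(p[1])), (q[0], int(q[1])))
            for p, q in self.native_pairs
        ]
        self.interface_contacts = [
            ((p[0], int(p[1])), (q[0], int(q[1])), float(r0))
            for p, q, r0 in self.interface_contacts
        ]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["anchors"] = [
            [[a[0], a[1]], [g[0], list(g[1])]] for a, g in self.anchors]
        d["native_pairs"] = [
            [[p[0], p[1]], [q[0], q[1]]] for p, q in self.native_pairs]
        d["interface_contacts"] = [
            [[p[0], p[1]], [q[0], q[1]], r0]
            for p, q, r0 in self.interface_contacts]
        return d


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    try:
        return RunConfig(**data)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def dump_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def config_digest(cfg: RunConfig) -> str:
    canonical = yaml.safe_dump(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
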