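"""Run configuration: one YAML file per pipeline stage, CLI flags override.

A config may contain (all blocks optional):

    seed: 7
    outdir: results/
    datasets:
      - {path: saxs.dat, contrast: xray}
    fixed: {h_belt: 24.0, sigma_r: 2.0}
    free:
      eps: {init: 1.2, lo: 1.0, hi: 1.8}
    composition: {belt: dh5, n_tag: 0}
    observables: [saxs_obs.tsv, noe_obs.tsv]
    theta: 10.0
    weights: weights.tsv
    ensemble: ensemble.pdb
    selection: {atom_name: BB}
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .composition import MolecularComposition, BELT_DH5, BELT_DH4H5
from .fitting import FreeParam
from .geometry import NanodiscParams


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    data: dict = field(default_factory=dict)
    path: str | None = None

    def get(self, key, default=None):
        return self.data.get(key, default)

    @property
    def seed(self) -> int:
        return int(self.data.get("seed", 0))

    @property
    def outdir(self) -> Path:
        return Path(self.data.get("outdir", "."))

    def free_params(self) -> list[FreeParam]:
        out = []
        for name, spec in (self.data.get("free") or {}).items():
            try:
                out.append(FreeParam(name, float(spec["init"]),
                                     float(spec["lo"]), float(spec["hi"])))
            except (KeyError, TypeError) as exc:
                raise ConfigError(f"free parameter {name}: needs init/lo/hi") from exc
        return out

    def fixed_params(self) -> NanodiscParams:
        return NanodiscParams(**(self.data.get("fixed") or {}))

    def composition(self) -> MolecularComposition:
        block = self.data.get("composition") or {}
        belt = {"dh5": BELT_DH5, "dh4h5": BELT_DH4H5}[block.get("belt", "dh5")]
        return MolecularComposition(belt=belt, n_tag=int(block.get("n_tag", 0)))

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.data, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    cfg = RunConfig(data=data, path=str(path))
    cfg.free_params()  # validates bounds early
    return cfg
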