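"""Configuration files: model specifications and run configurations.

A model specification is a small YAML/JSON mapping:

    functions: [ADD, ADD, ADD, ADD, ADD, ADD]
    prevalence: 0.10
    loci:                      # optional per-locus probability overrides
      TF1: {0: 0.25, 1: 0.5, 2: 0.25}
      environment: {-2: 0.2, -1: 0.2, 0: 0.2, 1: 0.2, 2: 0.2}

Function names are accepted case-insensitively and as operator symbols.
Round-trips are lossless. A run is reproducible from (config, seed) alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .distributions import DiscreteDistribution
from .model import HierarchyModel, LOCUS_NAMES, Locus, default_loci

__all__ = ["ModelSpec", "RunConfig", "load_model", "save_model", "config_hash"]


@dataclass
class ModelSpec:
    """Serializable model description: six function names, optional locus
    probability overrides, and the target disease prevalence."""

    functions: list[str]
    prevalence: float = 0.10
    loci: dict[str, dict[int, float]] = field(default_factory=dict)

    def to_model(self) -> HierarchyModel:
        loci = default_loci()
        for name, probs in self.loci.items():
            if name not in LOCUS_NAMES:
                raise ValueError(f"unknown locus {name!r} in model spec")
            loci[name] = Locus(name, DiscreteDistribution({int(k): v for k, v in probs.items()}))
        return HierarchyModel(functions=tuple(self.functions), loci=loci)

    @classmethod
    def from_model(cls, model: HierarchyModel, prevalence: float = 0.10) -> "ModelSpec":
        loci = {
            name: {int(v): float(p) for v, p in locus.dist.items()}
            for name, locus in model.loci.items()
        }
        return cls(functions=list(model.functions), prevalence=prevalence, loci=loci)

    def to_dict(self) -> dict:
        return {
            "functions": list(self.functions),
            "prevalence": self.prevalence,
            "loci": {n: dict(p) for n, p in self.loci.items()},
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ModelSpec":
        if not 0.0 < float(data.get("prevalence", 0.10)) < 1.0:
            raise ValueError(f"prevalence: must be in (0, 1), got {data.get('prevalence')}")
        return cls(
            functions=[str(f) for f in data["functions"]],
            prevalence=float(data.get("prevalence", 0.10)),
            loci={
                str(n): {int(k): float(v) for k, v in probs.items()}
                for n, probs in (data.get("loci") or {}).items()
            },
        )


def load_model(path) -> ModelSpec:
    with Path(path).open() as fh:
        return ModelSpec.from_dict(yaml.safe_load(fh))


def save_model(spec: ModelSpec, path) -> None:
    with Path(path).open("w") as fh:
        yaml.safe_dump(spec.to_dict(), fh, sort_keys=True)


@dataclass
class RunConfig:
    """Full simulation run: model, sampling parameters, evaluation
    parameters and the master seed."""

    model: ModelSpec
    pop_size: int = 100_000
    n_cases: int = 1000
    n_controls: int = 1000
    noise_snps: int = 0
    maf_range: tuple[float, float] = (0.05, 0.5)
    replicates: int = 1
    loci: tuple[str, str, str] = ("TF1", "TF2", "enhancer")
    n_perm: int = 1000
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["model"] = self.model.to_dict()
        d["maf_range"] = list(self.maf_range)
        d["loci"] = list(self.loci)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        kwargs = dict(data)
        kwargs["model"] = ModelSpec.from_dict(data["model"])
        if "maf_range" in kwargs:
            kwargs["maf_range"] = tuple(kwargs["maf_range"])
        if "loci" in kwargs:
            kwargs["loci"] = tuple(kwargs["loci"])
        return cls(**kwargs)


def config_hash(config_dict: dict) -> str:
    """Stable short hash of a configuration for run logging."""
    payload = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
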