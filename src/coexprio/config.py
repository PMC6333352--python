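"""Run configuration: YAML loading and fail-fast validation."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Invalid run configuration; the message names the offending field."""


@dataclass
class DatasetConfig:
    name: str
    expression: str
    metadata: str
    # optional probe-level inputs; when set, the presence filter + median
    # summarization run before everything else
    probes: str | None = None
    probe_map: str | None = None
    detection: str | None = None


@dataclass
class RunConfig:
    rng_seed: int
    out_dir: str
    datasets: list[DatasetConfig]
    ppi: str
    seeds: str
    references: str
    wgcna: dict = field(default_factory=dict)
    neri: dict = field(default_factory=dict)
    mset: dict = field(default_factory=dict)
    robustness: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            datasets = [DatasetConfig(**d) for d in raw.pop("datasets")]
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"datasets: {exc}") from exc
        try:
            cfg = cls(datasets=datasets, **raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc
        cfg.fill_defaults()
        return cfg

    def fill_defaults(self) -> None:
        w = {
            "beta_candidates": list(range(1, 21)),
            "r2_min": 0.8,
            "min_module_size": 50,
            "merge_cut_height": 0.25,
            "deepsplit": 2,
            "n_permutations": 100,
            "exclude_samples": [],
        }
        w.update(self.wgcna or {})
        self.wgcna = w
        n = {"fraction": 0.10, "score": "delta_prime", "path_cap": 10000}
        n.update(self.neri or {})
        self.neri = n
        m = {"n_permutations": 10000}
        m.update(self.mset or {})
        self.mset = m
        r = {
            "enabled": False,
            "fractions": [0.1, 0.2, 0.3, 0.4],
            "n_sets": 50,
            "tops": [50, 100, 150, 200],
        }
        r.update(self.robustness or {})
        self.robustness = r

    def validate(self) -> None:
        for ds in self.datasets:
            for fieldname in ("expression", "metadata"):
                path = getattr(ds, fieldname)
                if not Path(path).is_file():
                    raise ConfigError(f"datasets[{ds.name}].{fieldname}: file not found: {path}")
        for fieldname in ("ppi", "seeds", "references"):
            path = getattr(self, fieldname)
            if not Path(path).is_file():
                raise ConfigError(f"{fieldname}: file not found: {path}")
        for key in ("min_module_size", "n_permutations"):
            if self.wgcna[key] <= 0:
                raise ConfigError(f"wgcna.{key}: must be positive")
        if not (0 < self.neri["fraction"] <= 1):
            raise ConfigError("neri.fraction: must be in (0, 1]")
        if self.mset["n_permutations"] <= 0:
            raise ConfigError("mset.n_permutations: must be positive")
        if self.robustness["n_sets"] <= 0:
            raise ConfigError("robustness.n_sets: must be positive")
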