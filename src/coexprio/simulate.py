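"""Synthetic two-condition expression cohorts, PPI scaffolds, seeds and reference sets.

The expression model is a one-factor Gaussian block model: every gene of a
planted module m loads with weight lambda on a per-sample standard-normal
latent factor f_m, plus independent Gaussian noise.  Under this model the
expected within-module Pearson correlation is lambda^2 / (lambda^2 +
noise_sd^2), which gives a closed form to test against.  One designated
module has its loading multiplied by (1 - delta) in the disease group only,
planting a "least preserved" disease module; background genes are pure
noise.

The PPI scaffold is a Barabasi-Albert preferential-attachment graph (so the
degree sequence is scale-free, like curated interactomes) with extra random
edges wired inside each planted module so that module genes are also
topologically close, plus a seed set drawn partly from the perturbed module
(emulating GWAS hits inside the disease module).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CohortDesign",
    "PpiDesign",
    "ReferenceDesign",
    "PlantedTruth",
    "generate_expression",
    "generate_ppi",
    "generate_reference_sets",
    "generate_metadata",
    "generate_probe_level",
    "default_cohort_design",
    "default_ppi_design",
    "default_reference_design",
    "write_synthetic_study",
]


class InvalidDesignError(ValueError):
    """Raised when a generator design violates its own invariants."""


# --------------------------------------------------------------------------
# designs


@dataclass(frozen=True)
class CohortDesign:
    """Two-group one-factor cohort: control vs disease with one perturbed module."""

    n_genes: int = 300
    n_samples_per_group: int = 33
    module_sizes: tuple[int, ...] = (60, 60, 60)
    factor_loading: float = 0.9
    loading_spread: float = 0.25
    perturbed_module: int = 0
    perturbation_strength: float = 0.9
    noise_sd: float = math.sqrt(1.0 - 0.81)
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_genes <= 0 or self.n_samples_per_group <= 0:
            raise InvalidDesignError("n_genes and n_samples_per_group must be positive")
        if sum(self.module_sizes) > self.n_genes:
            raise InvalidDesignError("module_sizes exceed n_genes")
        if any(m < 2 for m in self.module_sizes):
            raise InvalidDesignError("every module needs >= 2 genes")
        if not (0 < self.factor_loading <= 1):
            raise InvalidDesignError("factor_loading must be in (0, 1]")
        if not (0 <= self.loading_spread < self.factor_loading):
            raise InvalidDesignError("loading_spread must be in [0, factor_loading)")
        if not (0 <= self.perturbation_strength <= 1):
            raise InvalidDesignError("perturbation_strength must be in [0, 1]")
        if not (0 <= self.perturbed_module < len(self.module_sizes)):
            raise InvalidDesignError("perturbed_module index out of range")
        if self.noise_sd <= 0:
            raise InvalidDesignError("noise_sd must be positive")


@dataclass(frozen=True)
class PpiDesign:
    """Scale-free PPI scaffold covering (at least) the cohort's gene universe."""

    n_nodes: int = 450
    attachment: int = 2
    intra_module_extra_edges: int = 60
    n_seeds: int = 30
    seed_in_perturbed_fraction: float = 0.5
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_nodes <= 0 or self.attachment <= 0 or self.n_seeds <= 0:
            raise InvalidDesignError("n_nodes, attachment and n_seeds must be positive")
        if self.intra_module_extra_edges < 0:
            raise InvalidDesignError("intra_module_extra_edges must be >= 0")
        if not (0 <= self.seed_in_perturbed_fraction <= 1):
            raise InvalidDesignError("seed_in_perturbed_fraction must be in [0, 1]")


@dataclass(frozen=True)
class ReferenceDesign:
    """Named reference gene sets with a guaranteed fraction from the perturbed module."""

    set_names: tuple[str, ...] = ("CNV", "DEG", "DMG", "EXOM", "GWAS")
    set_sizes: tuple[int, ...] = (4, 60, 10, 30, 24)
    overlap_with_perturbed: tuple[float, ...] = (0.0, 0.5, 0.0, 0.0, 0.0)
    rng_seed: int = 0

    def __post_init__(self):
        if not (len(self.set_names) == len(self.set_sizes) == len(self.overlap_with_perturbed)):
            raise InvalidDesignError("set_names, set_sizes and overlap_with_perturbed must align")
        if any(s <= 0 for s in self.set_sizes):
            raise InvalidDesignError("set sizes must be positive")
        if any(not (0 <= f <= 1) for f in self.overlap_with_perturbed):
            raise InvalidDesignError("overlap fractions must be in [0, 1]")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of a generated cohort: module membership and perturbation."""

    module_of: dict  # gene -> module index, or None for background
    modules: tuple[tuple[str, ...], ...]
    background: tuple[str, ...]
    perturbed_module: int
    perturbation_strength: float

    @property
    def perturbed_genes(self) -> tuple[str, ...]:
        return self.modules[self.perturbed_module]

    def labels(self) -> pd.Series:
        """Module labels as strings ('M0', 'M1', ..., 'grey' for background)."""
        return pd.Series(
            {g: ("grey" if m is None else f"M{m}") for g, m in self.module_of.items()}
        ).sort_index()

    def to_dict(self) -> dict:
        return {
            "module_of": {g: (m if m is not None else None) for g, m in self.module_of.items()},
            "perturbed_module": self.perturbed_module,
            "perturbation_strength": self.perturbation_strength,
        }


# --------------------------------------------------------------------------
# helpers


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def _module_assignment(design: CohortDesign) -> tuple[tuple[tuple[str, ...], ...], tuple[str, ...]]:
    """Deterministic membership: sorted gene ids filled module by module."""
    genes = _gene_names(design.n_genes)
    modules, start = [], 0
    for size in design.module_sizes:
        modules.append(tuple(genes[start : start + size]))
        start += size
    return tuple(modules), tuple(genes[start:])


def planted_truth(design: CohortDesign) -> PlantedTruth:
    modules, background = _module_assignment(design)
    module_of: dict[str, int | None] = {g: None for g in background}
    for idx, mod in enumerate(modules):
        for g in mod:
            module_of[g] = idx
    return PlantedTruth(
        module_of=module_of,
        modules=modules,
        background=background,
        perturbed_module=design.perturbed_module,
        perturbation_strength=design.perturbation_strength,
    )


# --------------------------------------------------------------------------
# generators


def generate_expression(design: CohortDesign) -> tuple[pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Draw (control, disease) genes x samples matrices plus the planted truth.

    Gene g of module m in sample s:  x = lambda_g * f_m(s) + eps.  Within a
    module the loadings are evenly spaced over [factor_loading -
    loading_spread, factor_loading] in sorted gene order, planting the hub
    gradient real modules show (set loading_spread=0 for the exchangeable
    one-factor model with its closed-form within-module correlation
    lambda^2 / (lambda^2 + noise_sd^2)).  The perturbed module's loadings
    are scaled by (1 - delta) in the disease group only; background genes
    are pure noise.
    """
    truth = planted_truth(design)
    rng = np.random.default_rng(design.rng_seed)
    n = design.n_samples_per_group

    base_loading: dict[str, float] = {}
    for mod in truth.modules:
        lams = np.linspace(
            design.factor_loading - design.loading_spread, design.factor_loading, len(mod)
        )
        for g, lam in zip(mod, lams):
            base_loading[g] = float(lam)

    frames = []
    for group, delta in (("CTL", 0.0), ("SCZ", design.perturbation_strength)):
        factors = rng.standard_normal((len(design.module_sizes), n))
        genes = _gene_names(design.n_genes)
        loadings = np.zeros(design.n_genes)
        factor_idx = np.zeros(design.n_genes, dtype=int)
        for i, g in enumerate(genes):
            m = truth.module_of[g]
            if m is None:
                loadings[i] = 0.0
            else:
                lam = base_loading[g]
                if m == design.perturbed_module:
                    lam *= 1.0 - delta
                loadings[i] = lam
                factor_idx[i] = m
        values = loadings[:, None] * factors[factor_idx, :] + rng.normal(
            0.0, design.noise_sd, size=(design.n_genes, n)
        )
        cols = [f"{group}{i:03d}" for i in range(n)]
        frames.append(pd.DataFrame(values, index=genes, columns=cols))
    return frames[0], frames[1], truth


def generate_ppi(design: PpiDesign, cohort: CohortDesign) -> tuple[nx.Graph, list[str]]:
    """Barabasi-Albert scaffold + intra-module wiring, and a seed gene list.

    Returns the relabelled graph (cohort genes plus extra protein nodes) and
    seeds sampled so that round(n_seeds * seed_in_perturbed_fraction) lie in
    the perturbed module.
    """
    if design.n_nodes < cohort.n_genes:
        raise InvalidDesignError("PPI must cover the cohort gene universe")
    if design.n_seeds > design.n_nodes:
        raise InvalidDesignError("cannot request more seeds than PPI nodes")
    rng = np.random.default_rng(design.rng_seed)
    backbone = nx.barabasi_albert_graph(
        design.n_nodes, design.attachment, seed=int(rng.integers(2**31))
    )
    names = _gene_names(cohort.n_genes) + [
        f"P{i:05d}" for i in range(design.n_nodes - cohort.n_genes)
    ]
    order = rng.permutation(design.n_nodes)
    mapping = {node: names[order[node]] for node in backbone.nodes}
    graph = nx.relabel_nodes(backbone, mapping)
    nx.set_edge_attributes(graph, {e: {"sources": ["scaffold"]} for e in graph.edges})

    modules, _ = _module_assignment(cohort)
    for mod in modules:
        mod = sorted(mod)
        non_edges = [
            (a, b)
            for i, a in enumerate(mod)
            for b in mod[i + 1 :]
            if not graph.has_edge(a, b)
        ]
        k = min(design.intra_module_extra_edges, len(non_edges))
        if k:
            picks = rng.choice(len(non_edges), size=k, replace=False)
            for idx in sorted(picks):
                a, b = non_edges[idx]
                graph.add_edge(a, b, sources=["module_wiring"])

    truth = planted_truth(cohort)
    perturbed = sorted(truth.perturbed_genes)
    others = sorted(set(graph.nodes) - set(perturbed))
    k_pert = round(design.n_seeds * design.seed_in_perturbed_fraction)
    k_pert = min(k_pert, len(perturbed))
    seeds = list(rng.choice(perturbed, size=k_pert, replace=False))
    seeds += list(rng.choice(others, size=design.n_seeds - k_pert, replace=False))
    return graph, sorted(seeds)


def generate_reference_sets(design: ReferenceDesign, truth: PlantedTruth) -> dict[str, list[str]]:
    """Named gene sets: a guaranteed perturbed-module core plus uniform filler.

    round(size * overlap) genes come from the perturbed module; the remainder
    is drawn uniformly from the rest of the universe (which still includes
    the unchosen perturbed genes, so overlap=0 reduces to a uniform draw).
    """
    rng = np.random.default_rng(design.rng_seed)
    universe = sorted(truth.module_of)
    perturbed = sorted(truth.perturbed_genes)
    sets: dict[str, list[str]] = {}
    for name, size, frac in zip(design.set_names, design.set_sizes, design.overlap_with_perturbed):
        if size > len(universe):
            raise InvalidDesignError(f"set {name!r} larger than gene universe")
        k = round(size * frac)
        if k > len(perturbed):
            raise InvalidDesignError(f"set {name!r} demands more perturbed genes than exist")
        chosen = list(rng.choice(perturbed, size=k, replace=False))
        rest = sorted(set(universe) - set(chosen))
        chosen += list(rng.choice(rest, size=size - k, replace=False))
        sets[name] = sorted(chosen)
    return sets


def generate_metadata(design: CohortDesign, rng_seed: int | None = None) -> pd.DataFrame:
    """Per-sample clinical covariates mirroring a post-mortem brain cohort.

    Ages ~44 +/- 8 y, PMI ~30 +/- 14 h, brain pH slightly lower in cases,
    suicide and anti-psychotic exposure confined to the disease group — the
    kind of demographic table the demographic screen is meant to consume.
    """
    rng = np.random.default_rng(design.rng_seed + 1 if rng_seed is None else rng_seed)
    rows = []
    n = design.n_samples_per_group
    for group in ("CTL", "SCZ"):
        scz = group == "SCZ"
        for i in range(n):
            rows.append(
                {
                    "sample_id": f"{group}{i:03d}",
                    "condition": group,
                    "age": float(np.round(rng.normal(43.5, 8.0), 1)),
                    "sex": "M" if rng.random() < 0.73 else "F",
                    "pmi": float(np.round(max(rng.normal(30.0, 14.0), 4.0), 1)),
                    "ph": float(np.round(rng.normal(6.47 if scz else 6.60, 0.25), 2)),
                    "suicide": "Y" if (scz and rng.random() < 0.2) else "N",
                    "antipsychotics": "Y" if scz else "N",
                    "smoking": rng.choice(
                        ["Y", "N", "Unknown"], p=[0.63, 0.11, 0.26] if scz else [0.26, 0.26, 0.48]
                    ),
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


def generate_probe_level(
    expr: pd.DataFrame,
    rng_seed: int = 0,
    max_probes: int = 3,
    probe_noise_sd: float = 0.1,
    detection_rate: float = 0.9,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Expand a gene-level matrix into 1..max_probes noisy probes per gene.

    Returns (probe values, probe->gene map, Bernoulli detection flags);
    exercises the presence filter and the median probe summarization.
    """
    rng = np.random.default_rng(rng_seed)
    values, mapping = [], {}
    for gene in expr.index:
        for j in range(int(rng.integers(1, max_probes + 1))):
            pid = f"{gene}_p{j}"
            mapping[pid] = gene
            values.append(
                pd.Series(
                    expr.loc[gene].to_numpy() + rng.normal(0, probe_noise_sd, expr.shape[1]),
                    index=expr.columns,
                    name=pid,
                )
            )
    probe_values = pd.DataFrame(values)
    detected = pd.DataFrame(
        rng.random(probe_values.shape) < detection_rate,
        index=probe_values.index,
        columns=probe_values.columns,
    )
    return probe_values, pd.Series(mapping, name="gene"), detected


# --------------------------------------------------------------------------
# study-level defaults and writers


def default_cohort_design(rng_seed: int = 0, **overrides) -> CohortDesign:
    return CohortDesign(rng_seed=rng_seed, **overrides)


def default_ppi_design(rng_seed: int = 0, **overrides) -> PpiDesign:
    return PpiDesign(rng_seed=rng_seed, **overrides)


def default_reference_design(rng_seed: int = 0, **overrides) -> ReferenceDesign:
    return ReferenceDesign(rng_seed=rng_seed, **overrides)


def write_synthetic_study(out_dir, rng_seed: int = 0, robustness: bool = False) -> dict:
    """Write a complete two-cohort study (shared PPI/seeds/references) + config.

    The two cohorts share the planted structure but use independent draws,
    emulating two expression experiments on the same tissue.  Returns the
    path map; a ready-to-run YAML config is included.
    """
    from pathlib import Path

    import yaml

    from . import io as cio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict = {"datasets": []}

    cohort0 = default_cohort_design(rng_seed)
    ppi_design = default_ppi_design(rng_seed + 1)
    ref_design = default_reference_design(rng_seed + 2)
    graph, seeds = generate_ppi(ppi_design, cohort0)
    truth0 = planted_truth(cohort0)
    refs = generate_reference_sets(ref_design, truth0)

    cio.write_graph(graph, out / "ppi.tsv")
    cio.write_seeds(seeds, out / "seeds.txt")
    cio.write_gmt(refs, out / "references.gmt")
    paths.update(ppi=str(out / "ppi.tsv"), seeds=str(out / "seeds.txt"), references=str(out / "references.gmt"))

    for tag, offset in (("d1", 0), ("d2", 100003)):
        design = default_cohort_design(rng_seed + offset)
        ctl, scz, truth = generate_expression(design)
        expr = pd.concat([ctl, scz], axis=1)
        meta = generate_metadata(design)
        cio.write_expression(expr, out / f"{tag}_expression.tsv")
        cio.write_metadata(meta, out / f"{tag}_metadata.tsv")
        cio.write_json(truth.to_dict(), out / f"{tag}_truth.json")
        paths["datasets"].append(
            {
                "name": tag,
                "expression": str(out / f"{tag}_expression.tsv"),
                "metadata": str(out / f"{tag}_metadata.tsv"),
            }
        )

    config = {
        "rng_seed": int(rng_seed),
        "out_dir": str(out / "results"),
        "datasets": paths["datasets"],
        "ppi": paths["ppi"],
        "seeds": paths["seeds"],
        "references": paths["references"],
        "wgcna": {
            "beta_candidates": list(range(1, 13)),
            "r2_min": 0.8,
            "min_module_size": 50,
            "merge_cut_height": 0.25,
            "deepsplit": 2,
            "n_permutations": 100,
            "exclude_samples": [],
        },
        "neri": {"fraction": 0.10, "score": "delta_prime", "path_cap": 10000},
        "mset": {"n_permutations": 10000},
        "robustness": {
            "enabled": bool(robustness),
            "fractions": [0.1, 0.2, 0.3, 0.4],
            "n_sets": 10,
            "tops": [25, 50, 75, 100],
        },
    }
    cfg_path = out / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    paths["config"] = str(cfg_path)
    return paths
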