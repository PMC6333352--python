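"""Seed-based PPI gene prioritization from concordance-scored best shortest paths.

Starting from a merged protein-protein interaction graph and a list of
disease seed genes, one condition-specific "cutting" is built per group:
for every seed pair (and every seed/seed-neighbor pair) all equal-length
shortest paths are enumerated and the path whose member genes show the
highest expression concordance — Kendall's coefficient of concordance W
over the sample rankings, with the standard tie correction — is selected.
Per condition, each gene accumulates a relative importance from the W of
the selected paths it sits on, damped by its distance to the nearest seed.
Genes are finally ranked by the sum (sigma') or difference (delta') of
their per-condition fractional importance ranks; the top fraction of the
cutting is the prioritized list.
"""

from __future__ import annotations

import math
import warnings
from collections import deque
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "SeedSet",
    "Cutting",
    "merge_ppi",
    "map_seeds",
    "path_concordance",
    "build_cutting",
    "build_cuttings",
    "relative_importance",
    "rank_genes",
    "run_neri",
    "seed_robustness",
]


# --------------------------------------------------------------------------
# graph assembly


def merge_ppi(edge_tables: list[pd.DataFrame]) -> nx.Graph:
    """Union of interaction tables into one simple graph with source tags.

    Symbols are uppercased, self-loops dropped and duplicate edges collapsed
    while retaining every source tag on the merged edge.
    """
    graph = nx.Graph()
    for table in edge_tables:
        cols = list(table.columns)
        a_col, b_col = cols[0], cols[1]
        src_col = "source" if "source" in table.columns else None
        for row in table.itertuples(index=False):
            a = str(getattr(row, a_col)).upper()
            b = str(getattr(row, b_col)).upper()
            src = str(getattr(row, src_col)) if src_col else "unknown"
            if a == b:
                continue
            if graph.has_edge(a, b):
                graph.edges[a, b]["sources"].update(src.split(";"))
            else:
                graph.add_edge(a, b, sources=set(src.split(";")))
    if graph.number_of_edges() == 0:
        raise ValueError("empty PPI union")
    for _, _, data in graph.edges(data=True):
        data["sources"] = set(data["sources"])
    return graph


@dataclass(frozen=True)
class SeedSet:
    """Requested seed symbols partitioned into mapped / unmapped on the graph."""

    requested: tuple[str, ...]
    mapped: tuple[str, ...]
    unmapped: tuple[str, ...]


def map_seeds(graph: nx.Graph, seeds) -> SeedSet:
    """Uppercase and partition the seed list by presence in the PPI node set."""
    requested = tuple(str(s).upper() for s in seeds)
    if not requested:
        raise ValueError("empty seed list")
    nodes = set(graph.nodes)
    mapped = tuple(sorted({s for s in requested if s in nodes}))
    unmapped = tuple(sorted(set(requested) - set(mapped)))
    if not mapped:
        raise ValueError("no seed mapped to the PPI network")
    if len(mapped) < 2:
        warnings.warn("fewer than 2 mapped seeds: no seed pairs to connect")
    return SeedSet(requested=requested, mapped=mapped, unmapped=unmapped)


# --------------------------------------------------------------------------
# concordance


def path_concordance(path_genes, expr: pd.DataFrame) -> float:
    """Kendall's W of the sample rankings produced by the path's genes.

    Each measured gene acts as a judge ranking the n samples by expression;
    W = 12 S / (m^2 (n^3 - n) - m * sum_i T_i) with S the sum of squared
    deviations of the sample rank sums and T_i the tie correction of judge
    i.  Genes absent from the expression matrix are skipped (reducing m);
    fewer than 2 remaining judges scores 0 with a warning.
    """
    genes = [g for g in path_genes if g in expr.index]
    m = len(genes)
    if m < 2:
        warnings.warn("path has fewer than 2 measured genes; concordance undefined, scored 0")
        return 0.0
    x = expr.loc[genes].to_numpy(dtype=float)
    n = x.shape[1]
    if n < 2:
        raise ValueError("need at least 2 samples")
    ranks = np.apply_along_axis(rankdata, 1, x)
    rank_sums = ranks.sum(axis=0)
    s = float(np.sum((rank_sums - m * (n + 1) / 2.0) ** 2))
    tie_term = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts**3 - counts))
    denom = m**2 * (n**3 - n) - m * tie_term
    if denom <= 0:
        return 0.0
    return float(np.clip(12.0 * s / denom, 0.0, 1.0))


# --------------------------------------------------------------------------
# cuttings


@dataclass
class Cutting:
    """Condition-specific subnetwork of selected best shortest paths."""

    condition: str
    selected_paths: list[tuple[str, ...]]
    path_scores: list[float]
    subnetwork: nx.Graph
    skipped_pairs: list[tuple[str, str]] = field(default_factory=list)


def _bfs_tree(graph: nx.Graph, source: str) -> tuple[dict, dict]:
    """Distances and shortest-path predecessor lists from ``source``."""
    dist = {source: 0}
    preds: dict[str, list[str]] = {source: []}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in graph.neighbors(u):
            if v not in dist:
                dist[v] = dist[u] + 1
                preds[v] = [u]
                queue.append(v)
            elif dist[v] == dist[u] + 1:
                preds[v].append(u)
    return dist, preds


def _enumerate_paths(preds: dict, source: str, target: str, cap: int) -> tuple[list, bool]:
    """All shortest paths source->target from a predecessor DAG, capped."""
    paths: list[tuple[str, ...]] = []
    stack = [(target, (target,))]
    truncated = False
    while stack:
        node, suffix = stack.pop()
        if node == source:
            paths.append(suffix)
            if len(paths) >= cap:
                truncated = bool(stack)
                break
            continue
        for p in sorted(preds[node], reverse=True):
            stack.append((p, (p,) + suffix))
    return paths, truncated


def _qualifying_pairs(graph: nx.Graph, seed_set: SeedSet) -> list[tuple[str, str]]:
    """Unordered seed-seed pairs plus seed-(own neighbor) pairs."""
    seeds = list(seed_set.mapped)
    pairs = {tuple(sorted((a, b))) for i, a in enumerate(seeds) for b in seeds[i + 1 :]}
    seed_lookup = set(seeds)
    for s in seeds:
        for v in graph.neighbors(s):
            if v not in seed_lookup:
                pairs.add(tuple(sorted((s, v))))
    return sorted(pairs)


def _candidate_paths(
    graph: nx.Graph, seed_set: SeedSet, path_cap: int = 10000
) -> tuple[dict, list]:
    """Per qualifying pair, the list of equal-length shortest paths."""
    pairs = _qualifying_pairs(graph, seed_set)
    sources = sorted({p[0] for p in pairs})
    trees = {s: _bfs_tree(graph, s) for s in sources}
    candidates: dict[tuple[str, str], list[tuple[str, ...]]] = {}
    skipped = []
    for a, b in pairs:
        dist, preds = trees[a]
        if b not in dist:
            skipped.append((a, b))
            continue
        paths, truncated = _enumerate_paths(preds, a, b, path_cap)
        if truncated:
            warnings.warn(f"path enumeration for pair {a}-{b} capped at {path_cap}")
        candidates[(a, b)] = paths
    return candidates, skipped


def _select_paths(candidates: dict, expr: pd.DataFrame) -> tuple[list, list]:
    """Best-W path per pair; ties broken by lexicographically smallest sequence."""
    selected, scores = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # unmeasured-gene warnings are per-path noise here
        for pair in sorted(candidates):
            best_path, best_w = None, -1.0
            for path in candidates[pair]:
                w = path_concordance(path, expr)
                if w > best_w or (w == best_w and (best_path is None or path < best_path)):
                    best_path, best_w = path, w
            if best_path is not None:
                selected.append(best_path)
                scores.append(best_w)
    return selected, scores


def _cutting_from_paths(condition, paths, scores, skipped) -> Cutting:
    sub = nx.Graph()
    for path in paths:
        nx.add_path(sub, path)
    return Cutting(
        condition=condition,
        selected_paths=paths,
        path_scores=scores,
        subnetwork=sub,
        skipped_pairs=skipped,
    )


def build_cutting(
    graph: nx.Graph, seed_set: SeedSet, expr: pd.DataFrame, condition: str = "", path_cap: int = 10000
) -> Cutting:
    """Condition-specific cutting: union of the best-concordance shortest paths.

    With a single mapped seed only the seed-neighbor pairs remain (the
    degenerate star case); zero mapped seeds is rejected upstream.
    """
    candidates, skipped = _candidate_paths(graph, seed_set, path_cap)
    paths, scores = _select_paths(candidates, expr)
    return _cutting_from_paths(condition, paths, scores, skipped)


def build_cuttings(
    graph: nx.Graph,
    seed_set: SeedSet,
    expr_control: pd.DataFrame,
    expr_case: pd.DataFrame,
    path_cap: int = 10000,
) -> tuple[Cutting, Cutting]:
    """Both condition cuttings, sharing one shortest-path enumeration."""
    candidates, skipped = _candidate_paths(graph, seed_set, path_cap)
    out = []
    for condition, expr in (("control", expr_control), ("case", expr_case)):
        paths, scores = _select_paths(candidates, expr)
        out.append(_cutting_from_paths(condition, paths, scores, skipped))
    return out[0], out[1]


# --------------------------------------------------------------------------
# importance and ranking


def _proximity(cutting: Cutting, seeds: tuple[str, ...]) -> dict[str, float]:
    """1 / (1 + distance to the nearest seed) within the cutting subnetwork."""
    sub = cutting.subnetwork
    sources = [s for s in seeds if s in sub]
    if not sources:
        return {g: 0.0 for g in sub.nodes}
    dist = nx.multi_source_dijkstra_path_length(sub, sources)
    return {g: 1.0 / (1.0 + dist.get(g, math.inf)) for g in sub.nodes}


def relative_importance(
    cut_control: Cutting, cut_case: Cutting, seed_set: SeedSet
) -> pd.DataFrame:
    """Per-gene relative importance per condition with sigma/delta rankings.

    importance_c(g) = prox_c(g) * sum of W over selected paths containing g,
    max-normalized within condition.  sigma = case + control and delta =
    case - control; sigma'/delta' are the same combinations on fractional
    within-condition ranks (1 = most important), computed over the union of
    both cuttings' genes.
    """
    genes = sorted(set(cut_control.subnetwork.nodes) | set(cut_case.subnetwork.nodes))
    if not genes:
        raise ValueError("both cuttings are empty")
    table = pd.DataFrame(index=pd.Index(genes, name="gene"))
    for tag, cutting in (("control", cut_control), ("case", cut_case)):
        prox = _proximity(cutting, seed_set.mapped)
        raw = dict.fromkeys(genes, 0.0)
        counts = dict.fromkeys(genes, 0)
        for path, w in zip(cutting.selected_paths, cutting.path_scores):
            for g in path:
                raw[g] += w
                counts[g] += 1
        imp = np.array([raw[g] * prox.get(g, 0.0) for g in genes])
        if imp.max() > 0:
            imp = imp / imp.max()
        table[f"importance_{tag}"] = imp
        table[f"path_count_{tag}"] = [counts[g] for g in genes]
        # fractional rank in (0, 1]; 1 = top importance; ties share the mean rank
        table[f"rank_{tag}"] = rankdata(imp, method="average") / len(genes)
    table["sigma"] = table["importance_case"] + table["importance_control"]
    table["delta"] = table["importance_case"] - table["importance_control"]
    table["sigma_prime"] = table["rank_case"] + table["rank_control"]
    table["delta_prime"] = table["rank_case"] - table["rank_control"]
    return table


def rank_genes(
    table: pd.DataFrame,
    score: str = "delta_prime",
    fraction: float = 0.10,
    signed: bool = False,
) -> pd.DataFrame:
    """Top fraction of the cutting genes by the chosen score.

    delta' measures differential importance between conditions, so by
    default its ranking uses the magnitude |delta'| (a gene whose importance
    collapses in disease is as interesting as one that surges); pass
    ``signed=True`` for a plain descending sort on the signed value.
    sigma' always sorts on its (non-negative) value.  Ties break by sigma,
    then by symbol; the list length is ceil(fraction * n_genes).
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if score not in ("delta_prime", "sigma_prime"):
        raise ValueError("score must be 'delta_prime' or 'sigma_prime'")
    if table.empty:
        warnings.warn("empty importance table")
        return table.copy()
    key = table[score].abs() if (score == "delta_prime" and not signed) else table[score]
    # deterministic ordering: score desc, sigma desc, symbol asc
    sigma = table["sigma"]
    tie_sorted = sorted(table.index, key=lambda g: (-key.at[g], -sigma.at[g], g))
    n_top = math.ceil(fraction * len(table))
    top = table.loc[tie_sorted[:n_top]].copy()
    top["rank"] = np.arange(1, len(top) + 1)
    top["score_used"] = score
    return top


def run_neri(
    graph: nx.Graph,
    seeds,
    expr_control: pd.DataFrame,
    expr_case: pd.DataFrame,
    score: str = "delta_prime",
    fraction: float = 0.10,
    path_cap: int = 10000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full prioritization: (importance table, top-fraction ranked list)."""
    seed_set = map_seeds(graph, seeds)
    cut_ctrl, cut_case = build_cuttings(graph, seed_set, expr_control, expr_case, path_cap)
    table = relative_importance(cut_ctrl, cut_case, seed_set)
    top = rank_genes(table, score=score, fraction=fraction)
    return table, top


# --------------------------------------------------------------------------
# seed robustness


def seed_robustness(
    graph: nx.Graph,
    seeds,
    expr_control: pd.DataFrame,
    expr_case: pd.DataFrame,
    fractions=(0.1, 0.2, 0.3, 0.4),
    n_sets: int = 50,
    tops=(50, 100, 150, 200),
    rng_seed: int = 0,
    score: str = "delta_prime",
    path_cap: int = 10000,
) -> pd.DataFrame:
    """Leave-seeds-out cross-validation of the ranking.

    The full-seed ranking is the reference; for each removal fraction,
    ``n_sets`` random seed subsets rerun the whole method and the overlap
    percentage of each top-k list with the reference top-k is recorded
    (long format: fraction, replicate, top_k, overlap_pct).
    """
    seeds = [str(s).upper() for s in seeds]
    max_remove = max(int(round(f * len(seeds))) for f in fractions)
    if len(seeds) < max_remove + 2:
        raise ValueError("seed list too small for the requested removal fractions")
    table, _ = run_neri(graph, seeds, expr_control, expr_case, score=score, path_cap=path_cap)
    reference = _full_ranking(table, score)
    rng = np.random.default_rng(rng_seed)
    rows = []
    for frac in fractions:
        n_remove = int(round(frac * len(seeds)))
        for rep in range(n_sets):
            removed = set(rng.choice(seeds, size=n_remove, replace=False))
            kept = [s for s in seeds if s not in removed]
            if len(kept) < 2:
                warnings.warn("removal left fewer than 2 seeds; replicate skipped")
                continue
            sub_table, _ = run_neri(
                graph, kept, expr_control, expr_case, score=score, path_cap=path_cap
            )
            ranking = _full_ranking(sub_table, score)
            for k in tops:
                k_eff = min(k, len(reference), len(ranking))
                ref_top = set(reference[:k_eff])
                new_top = set(ranking[:k_eff])
                rows.append(
                    {
                        "fraction": float(frac),
                        "replicate": rep,
                        "top_k": int(k),
                        "overlap_pct": 100.0 * len(ref_top & new_top) / k_eff,
                    }
                )
    return pd.DataFrame(rows)


def _full_ranking(table: pd.DataFrame, score: str) -> list[str]:
    return list(rank_genes(table, score=score, fraction=1.0).index)
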