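"""Method combination, replication overlap, MSET permutation tests, hub genes.

The combined list merges the least-preserved co-expression module with the
prioritizer's top list, with per-gene provenance.  MSET is an empirical
gene-set overlap test: the observed overlap of a query list with a reference
set is compared against the overlaps of random query-sized draws from a
stated background, p = (#{null >= observed} + 1) / (N + 1).  Hub rules
follow the two conventions used for the two methods: module membership
strength (kME >= 0.90) plus an intramodular-connectivity percentile window,
and a full-interactome degree percentile window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MsetResult",
    "HubReport",
    "combine",
    "replication_overlap",
    "mset",
    "hubs_wgcna",
    "hubs_neri",
]


def combine(wgcna_genes, neri_genes) -> pd.DataFrame:
    """Union of both method lists with provenance flags.

    Rows are sorted with 'both' genes first, then by the prioritizer rank
    (order of ``neri_genes``), then by symbol.
    """
    wgcna = list(dict.fromkeys(wgcna_genes))
    neri = list(dict.fromkeys(neri_genes))
    if not wgcna or not neri:
        raise ValueError("both input lists must be non-empty")
    neri_rank = {g: i + 1 for i, g in enumerate(neri)}
    rows = []
    for g in sorted(set(wgcna) | set(neri)):
        in_w, in_n = g in set(wgcna), g in neri_rank
        rows.append(
            {
                "gene": g,
                "provenance": "both" if (in_w and in_n) else ("wgcna_only" if in_w else "neri_only"),
                "source_rank": neri_rank.get(g, np.nan),
            }
        )
    df = pd.DataFrame(rows)
    df["_both"] = (df["provenance"] != "both").astype(int)
    df = df.sort_values(["_both", "source_rank", "gene"], na_position="last").drop(columns="_both")
    return df.reset_index(drop=True)


def replication_overlap(list_1, list_2, background) -> tuple[set, float]:
    """Intersection of two lists plus its upper-tail hypergeometric p-value.

    Genes outside the background are dropped with a warning.  The p-value is
    P(overlap >= observed) when |list_1| genes are drawn at random from the
    background and compared with list_2.
    """
    bg = set(background)
    l1, l2 = set(list_1), set(list_2)
    outside = (l1 | l2) - bg
    if outside:
        warnings.warn(f"{len(outside)} list genes outside the background were dropped")
        l1 &= bg
        l2 &= bg
    overlap = l1 & l2
    p = float(stats.hypergeom.sf(len(overlap) - 1, len(bg), len(l2), len(l1)))
    return overlap, min(p, 1.0)


@dataclass(frozen=True)
class MsetResult:
    """Permutation overlap test summary."""

    query_size: int
    background_size: int
    reference_size: int  # within background
    observed: int
    n_permutations: int
    null_mean: float
    null_sd: float
    p_value: float


def mset(
    query,
    background,
    reference,
    n_permutations: int = 10_000,
    rng_seed: int = 0,
    chunk: int = 2_000,
) -> MsetResult:
    """Empirical overlap enrichment of ``query`` in ``reference`` vs ``background``.

    N permutations draw |query| genes uniformly without replacement from the
    background; p = (#{null >= observed} + 1) / (N + 1), never exactly 0.
    Query genes outside the background are dropped with a warning; the
    reference is intersected with the background.
    """
    bg = sorted(set(background))
    q = set(query)
    outside = q - set(bg)
    if outside:
        warnings.warn(f"{len(outside)} query genes outside the background were dropped")
        q &= set(bg)
    ref = set(reference) & set(bg)
    observed = len(q & ref)
    if not ref:
        warnings.warn("reference does not intersect the background; p = 1")
        return MsetResult(len(q), len(bg), 0, 0, n_permutations, 0.0, 0.0, 1.0)
    rng = np.random.default_rng(rng_seed)
    ref_mask = np.fromiter((g in ref for g in bg), dtype=bool, count=len(bg))
    n_bg, n_q = len(bg), len(q)
    null_counts = np.empty(n_permutations, dtype=np.int64)
    done = 0
    while done < n_permutations:
        size = min(chunk, n_permutations - done)
        # row-wise draw without replacement: argpartition of uniform keys
        keys = rng.random((size, n_bg))
        idx = np.argpartition(keys, n_q - 1, axis=1)[:, :n_q]
        null_counts[done : done + size] = ref_mask[idx].sum(axis=1)
        done += size
    p = (np.count_nonzero(null_counts >= observed) + 1) / (n_permutations + 1)
    return MsetResult(
        query_size=n_q,
        background_size=n_bg,
        reference_size=len(ref),
        observed=observed,
        n_permutations=n_permutations,
        null_mean=float(null_counts.mean()),
        null_sd=float(null_counts.std(ddof=1)),
        p_value=float(p),
    )


@dataclass(frozen=True)
class HubReport:
    """Hub genes under a method-specific rule."""

    method: str
    kme_hubs: tuple[str, ...]
    window_hubs: tuple[str, ...]
    thresholds: dict

    @property
    def hubs(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.kme_hubs) | set(self.window_hubs)))


def hubs_wgcna(
    module_set,
    module_label: str,
    kme_min: float = 0.90,
    window: tuple[float, float] = (90.0, 99.0),
) -> HubReport:
    """Module hubs: kME >= 0.90, plus a ktotal percentile window [90th, 99th].

    Percentiles use linear interpolation between order statistics and the
    window is closed on both ends; modules under 10 genes degenerate and
    report an empty window with a warning.
    """
    genes = module_set.genes_of(module_label)
    if not genes:
        raise ValueError(f"module {module_label!r} not found or empty")
    kme = module_set.kme.loc[genes, module_label]
    kme_hubs = tuple(sorted(kme.index[kme >= kme_min]))
    ktotal = module_set.ktotal.loc[genes]
    if len(genes) < 10 or ktotal.isna().any():
        warnings.warn("module too small (or ktotal unavailable) for a percentile window")
        window_hubs: tuple[str, ...] = ()
        lo = hi = float("nan")
    else:
        lo, hi = np.percentile(ktotal.to_numpy(), window)
        mask = (ktotal >= lo) & (ktotal <= hi)
        window_hubs = tuple(sorted(ktotal.index[mask]))
    return HubReport(
        method="wgcna",
        kme_hubs=kme_hubs,
        window_hubs=window_hubs,
        thresholds={"kme_min": kme_min, "window": window, "ktotal_lo": float(lo), "ktotal_hi": float(hi)},
    )


def hubs_neri(
    ranked_genes,
    graph: nx.Graph,
    window: tuple[float, float] = (90.0, 99.0),
) -> HubReport:
    """Prioritized genes whose full-interactome degree falls in [90th, 99th] pct."""
    degrees = dict(graph.degree())
    all_deg = np.fromiter(degrees.values(), dtype=float, count=len(degrees))
    lo, hi = np.percentile(all_deg, window)
    hubs = tuple(
        sorted(g for g in ranked_genes if g in degrees and lo <= degrees[g] <= hi)
    )
    return HubReport(
        method="neri",
        kme_hubs=(),
        window_hubs=hubs,
        thresholds={"window": window, "degree_lo": float(lo), "degree_hi": float(hi)},
    )
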