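"""Weighted co-expression networks: soft threshold, TOM, modules, preservation.

The network is unsigned: adjacency a_ij = |cor(x_i, x_j)|^beta with beta
chosen as the smallest candidate whose connectivity distribution fits a
power law with R^2 above a threshold (scale-free topology criterion).
Genes are clustered by average linkage on the topological-overlap
dissimilarity 1 - TOM, with

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij).

Module preservation between a reference and a test condition is a
permutation Z-score framework: module density (mean adjacency) and
connectivity-pattern agreement (correlation of intramodular connectivity
and of adjacency entries between the two networks) are compared against
random same-size gene sets; Zsummary averages the density and connectivity
components, and medianRank orders modules by their observed statistics
(rank 1 = most preserved, so the highest medianRank marks the least
preserved — the disease-module candidate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "SoftThresholdScan",
    "ModuleSet",
    "scale_free_fit",
    "adjacency_matrix",
    "select_soft_threshold",
    "compute_tom",
    "detect_modules",
    "eigengene_kme",
    "module_preservation",
    "trait_association",
    "MODULE_COLORS",
]

# classical module palette, assigned by decreasing module size
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
]

GREY = "grey"

_DEEPSPLIT_CUT = {0: 0.997, 1: 0.995, 2: 0.99, 3: 0.98, 4: 0.97}


# --------------------------------------------------------------------------
# scale-free fit and soft threshold


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the log-log regression of binned connectivity frequencies.

    Connectivities are histogrammed into equal-width bins; log10 frequency is
    regressed on log10 mean bin connectivity.  Degenerate inputs (all equal,
    or fewer than two occupied bins) return 0 by convention.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[np.isfinite(k) & (k > 0)]
    if k.size == 0 or np.allclose(k, k[0]):
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    log_freq, log_k = [], []
    for b in range(n_bins):
        members = k[which == b]
        if members.size == 0:
            continue
        log_freq.append(np.log10(members.size / k.size))
        log_k.append(np.log10(members.mean()))
    if len(log_k) < 2 or np.allclose(log_k, log_k[0]) or np.allclose(log_freq, log_freq[0]):
        return 0.0
    res = stats.linregress(log_k, log_freq)
    return float(res.rvalue**2)


def adjacency_matrix(expr: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Unsigned adjacency |Pearson cor|^beta over genes (rows of expr)."""
    cor = np.corrcoef(expr.to_numpy(dtype=float))
    cor = np.nan_to_num(cor, nan=0.0)
    adj = np.abs(cor) ** beta
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=expr.index, columns=expr.index)


@dataclass
class SoftThresholdScan:
    """Per-beta scale-free fit and mean connectivity, plus the chosen beta."""

    scan: pd.DataFrame  # columns: beta, r_squared, mean_connectivity
    chosen_beta: int | None


def select_soft_threshold(
    expr: pd.DataFrame,
    beta_candidates=range(1, 21),
    r2_min: float = 0.8,
    n_bins: int = 10,
) -> SoftThresholdScan:
    """Pick the smallest beta whose scale-free fit R^2 exceeds ``r2_min``.

    Connectivity of gene i is the row sum of adjacency excluding the
    diagonal.  When no candidate reaches the threshold ``chosen_beta`` is
    None (a reported condition, not an error).
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    cor = np.corrcoef(expr.to_numpy(dtype=float))
    cor = np.abs(np.nan_to_num(cor, nan=0.0))
    np.fill_diagonal(cor, 0.0)
    rows = []
    chosen = None
    for beta in beta_candidates:
        adj = cor**beta
        k = adj.sum(axis=1)
        r2 = scale_free_fit(k, n_bins=n_bins)
        rows.append({"beta": int(beta), "r_squared": r2, "mean_connectivity": float(k.mean())})
        if chosen is None and r2 > r2_min:
            chosen = int(beta)
    return SoftThresholdScan(scan=pd.DataFrame(rows), chosen_beta=chosen)


# --------------------------------------------------------------------------
# TOM


def compute_tom(adjacency: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Unsigned topological overlap of an adjacency matrix (diagonal -> 1)."""
    is_frame = isinstance(adjacency, pd.DataFrame)
    a = adjacency.to_numpy(dtype=float) if is_frame else np.asarray(adjacency, dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    shared = a @ a
    k = a.sum(axis=1)
    min_k = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (shared + a) / (min_k + 1.0 - a)
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    if is_frame:
        return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)
    return tom


# --------------------------------------------------------------------------
# module detection


@dataclass
class ModuleSet:
    """Gene->module partition with eigengenes, kME and intramodular connectivity."""

    labels: pd.Series  # gene -> module name; GREY = unassigned
    me: pd.DataFrame  # module x sample eigengene scores (unit variance)
    kme: pd.DataFrame  # gene x module correlations
    ktotal: pd.Series  # per-gene intramodular connectivity
    params: dict = field(default_factory=dict)

    @property
    def module_names(self) -> list[str]:
        return [m for m in self.me.index]

    def genes_of(self, module: str) -> list[str]:
        return sorted(self.labels.index[self.labels == module])


def _module_eigengene(x: np.ndarray) -> np.ndarray:
    """First principal component score of a standardized genes x samples block."""
    z = _standardize_rows(x)
    # SVD of the gene x sample block: right singular vector = sample scores
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    me = vt[0]
    sd = me.std()
    if sd > 0:
        me = me / sd
    # sign-align to positive mean correlation with the member genes
    cors = _row_cor_with(z, me)
    if np.nanmean(cors) < 0:
        me = -me
    return me


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def _row_cor_with(z: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Pearson correlation of every (standardized) row of z with vector v."""
    vz = (v - v.mean()) / (v.std() or 1.0)
    zz = _standardize_rows(z)
    return zz @ vz / len(v)


def eigengene_kme(
    expr: pd.DataFrame,
    labels: pd.Series,
    adjacency: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series | None]:
    """Module eigengenes, gene x module kME, and intramodular connectivity.

    The eigengene is the first principal component of the module's
    standardized expression, sign-aligned so its mean correlation with the
    module's genes is positive and scaled to unit variance.  ktotal needs
    the adjacency matrix and is None when it is not supplied.
    """
    labels = labels.loc[expr.index]
    modules = sorted(m for m in labels.unique() if m != GREY)
    me_rows = {}
    for m in modules:
        block = expr.loc[labels == m].to_numpy(dtype=float)
        me_rows[m] = _module_eigengene(block)
    me = pd.DataFrame(me_rows, index=expr.columns).T
    z = _standardize_rows(expr.to_numpy(dtype=float))
    kme = pd.DataFrame(
        {m: _row_cor_with(z, me.loc[m].to_numpy()) for m in modules}, index=expr.index
    )
    ktotal = None
    if adjacency is not None:
        ktotal = pd.Series(0.0, index=expr.index)
        adj = adjacency.loc[expr.index, expr.index].to_numpy(dtype=float).copy()
        np.fill_diagonal(adj, 0.0)
        for m in modules:
            idx = np.flatnonzero((labels == m).to_numpy())
            sub = adj[np.ix_(idx, idx)]
            ktotal.iloc[idx] = sub.sum(axis=1)
        ktotal.name = "ktotal"
    return me, kme, ktotal


def detect_modules(
    expr: pd.DataFrame,
    tom: pd.DataFrame,
    min_module_size: int = 50,
    merge_cut_height: float = 0.25,
    deepsplit: int = 2,
    cut_height_fraction: float | None = None,
    adjacency: pd.DataFrame | None = None,
) -> ModuleSet:
    """Average-linkage clustering of 1 - TOM with a static cut and ME merging.

    The tree is cut at ``cut_height_fraction * max merge height`` (the
    deepsplit preset sets the fraction; 2 -> 0.99); clusters smaller than
    ``min_module_size`` become grey; modules whose eigengenes correlate above
    1 - merge_cut_height are merged iteratively until stable.  Modules are
    named by size rank using the classical color palette.
    """
    genes = list(expr.index)
    if not tom.index.equals(expr.index):
        tom = tom.loc[genes, genes]
    if len(genes) < min_module_size:
        warnings.warn("fewer genes than the minimum module size: everything is grey")
        labels = pd.Series(GREY, index=expr.index)
        me = pd.DataFrame(columns=expr.columns)
        kme = pd.DataFrame(index=expr.index)
        return ModuleSet(labels, me, kme, pd.Series(0.0, index=expr.index), {})

    dist = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    z = linkage(squareform(dist, checks=False), method="average")
    if cut_height_fraction is None:
        cut_height_fraction = _DEEPSPLIT_CUT.get(int(deepsplit), 0.99)
    cut = cut_height_fraction * z[:, 2].max()
    assignments = fcluster(z, t=cut, criterion="distance")

    labels = pd.Series(assignments, index=expr.index).astype(object)
    sizes = labels.value_counts()
    small = sizes.index[sizes < min_module_size]
    labels[labels.isin(small)] = GREY

    labels = _merge_by_eigengene(expr, labels, merge_cut_height, min_module_size)

    # name modules by decreasing size
    sizes = labels[labels != GREY].value_counts()
    renames = {}
    for rank, mod in enumerate(sizes.index):
        renames[mod] = MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module_{rank + 1}"
    labels = labels.map(lambda m: renames.get(m, GREY))

    me, kme, ktotal = eigengene_kme(expr, labels, adjacency=adjacency)
    if ktotal is None:
        ktotal = pd.Series(np.nan, index=expr.index, name="ktotal")
    params = {
        "min_module_size": min_module_size,
        "merge_cut_height": merge_cut_height,
        "deepsplit": deepsplit,
        "cut_height_fraction": cut_height_fraction,
    }
    return ModuleSet(labels=labels, me=me, kme=kme, ktotal=ktotal, params=params)


def _merge_by_eigengene(
    expr: pd.DataFrame, labels: pd.Series, merge_cut_height: float, min_module_size: int
) -> pd.Series:
    """Iteratively merge module pairs whose eigengenes correlate > 1 - cut."""
    threshold = 1.0 - merge_cut_height
    labels = labels.copy()
    while True:
        modules = sorted(m for m in labels.unique() if m != GREY)
        if len(modules) < 2:
            return labels
        me = {
            m: _module_eigengene(expr.loc[labels == m].to_numpy(dtype=float)) for m in modules
        }
        best, best_cor = None, threshold
        for i, a in enumerate(modules):
            for b in modules[i + 1 :]:
                c = float(np.corrcoef(me[a], me[b])[0, 1])
                if c > best_cor:
                    best, best_cor = (a, b), c
        if best is None:
            return labels
        a, b = best
        labels[labels == b] = a


# --------------------------------------------------------------------------
# module preservation


def _preservation_stats(
    adj_ref: np.ndarray, adj_test: np.ndarray, idx: np.ndarray
) -> tuple[float, float, float]:
    """(mean test adjacency, cor of intramodular k, cor of adjacency entries)."""
    sub_ref = adj_ref[np.ix_(idx, idx)]
    sub_test = adj_test[np.ix_(idx, idx)]
    n = len(idx)
    off = ~np.eye(n, dtype=bool)
    mean_adj = float(sub_test[off].mean())
    k_ref = sub_ref[off].reshape(n, n - 1).sum(axis=1)
    k_test = sub_test[off].reshape(n, n - 1).sum(axis=1)
    cor_kim = _safe_cor(k_ref, k_test)
    iu = np.triu_indices(n, k=1)
    cor_adj = _safe_cor(sub_ref[iu], sub_test[iu])
    return mean_adj, cor_kim, cor_adj


def _safe_cor(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman agreement; rank-based because the beta power makes adjacency
    heavy-tailed and Pearson on it is dominated by a few large entries."""
    if a.std() == 0 or b.std() == 0:
        return 0.0
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    return float(np.corrcoef(ra, rb)[0, 1])


def module_preservation(
    ref_expr: pd.DataFrame,
    test_expr: pd.DataFrame,
    ref_labels: pd.Series,
    beta: int,
    n_permutations: int = 100,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Permutation Zsummary / medianRank preservation of reference modules.

    For each non-grey module, the observed density (mean test adjacency) and
    connectivity agreement (correlation of intramodular connectivities and
    of adjacency entries between reference and test) are standardized
    against ``n_permutations`` random same-size gene sets:
    Z = (obs - mean_null) / sd_null, z_connectivity = median of the two
    connectivity Zs, z_summary = (z_density + z_connectivity) / 2.
    medianRank is the per-module median of the modules' ranks under each
    observed statistic (rank 1 = most preserved; ties get the mean rank).
    """
    if not ref_expr.index.equals(test_expr.index):
        common = ref_expr.index.intersection(test_expr.index)
        if len(common) == 0:
            raise ValueError("reference and test share no genes")
        ref_expr, test_expr = ref_expr.loc[common], test_expr.loc[common]
    # canonical gene order so the permutation null does not depend on row order
    order = ref_expr.index.sort_values()
    ref_expr, test_expr = ref_expr.loc[order], test_expr.loc[order]
    genes = ref_expr.index
    labels = ref_labels.loc[genes]
    adj_ref = adjacency_matrix(ref_expr, beta).to_numpy()
    adj_test = adjacency_matrix(test_expr, beta).to_numpy()
    rng = np.random.default_rng(rng_seed)
    modules = sorted(m for m in labels.unique() if m != GREY)
    if not modules:
        raise ValueError("no non-grey modules to assess")

    observed = {}
    zscores = {}
    n_genes = len(genes)
    for m in modules:
        idx = np.flatnonzero((labels == m).to_numpy())
        obs = _preservation_stats(adj_ref, adj_test, idx)
        null = np.array(
            [
                _preservation_stats(
                    adj_ref, adj_test, rng.choice(n_genes, size=len(idx), replace=False)
                )
                for _ in range(n_permutations)
            ]
        )
        mu, sd = null.mean(axis=0), null.std(axis=0, ddof=1)
        zs = np.empty(3)
        for j in range(3):
            if sd[j] == 0:
                warnings.warn(f"degenerate permutation null for module {m}")
                zs[j] = np.inf if obs[j] > mu[j] else (-np.inf if obs[j] < mu[j] else 0.0)
            else:
                zs[j] = (obs[j] - mu[j]) / sd[j]
        observed[m] = obs
        zscores[m] = zs

    report = pd.DataFrame(index=pd.Index(modules, name="module"))
    report["module_size"] = [int((labels == m).sum()) for m in modules]
    report["z_density"] = [zscores[m][0] for m in modules]
    report["z_connectivity"] = [float(np.median(zscores[m][1:])) for m in modules]
    report["z_summary"] = (report["z_density"] + report["z_connectivity"]) / 2.0

    obs_table = pd.DataFrame(
        {m: observed[m] for m in modules}, index=["mean_adj", "cor_kim", "cor_adj"]
    ).T
    # rank 1 = most preserved (largest observed statistic); ties -> mean rank
    ranks = obs_table.rank(ascending=False, method="average")
    report["median_rank"] = ranks.median(axis=1)
    return report


# --------------------------------------------------------------------------
# trait association


def trait_association(
    me: pd.DataFrame,
    traits: pd.DataFrame,
    categorical: tuple[str, ...] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Module eigengene vs trait: F-test of the linear model against the null.

    One fixed-effects linear model per (module, trait); the p-value compares
    the full model with the intercept-only null (equivalent to the ANOVA /
    likelihood-ratio comparison for nested Gaussian models).  Constant
    traits are reported as undefined, not raised.
    """
    import statsmodels.api as sm

    samples = me.columns.intersection(traits.index)
    if len(samples) < 3:
        raise ValueError("module eigengenes and traits share too few samples")
    if categorical is None:
        categorical = tuple(
            c for c in traits.columns if not pd.api.types.is_numeric_dtype(traits[c])
        )
    rows = []
    for module in me.index:
        y = me.loc[module, samples].to_numpy(dtype=float)
        for col in traits.columns:
            t = traits.loc[samples, col]
            mask = t.notna().to_numpy()
            if t[mask].nunique() < 2:
                rows.append(
                    {
                        "module": module,
                        "trait": col,
                        "estimate": float("nan"),
                        "p_value": float("nan"),
                        "significant": False,
                        "note": "constant trait",
                    }
                )
                continue
            if col in categorical:
                x = pd.get_dummies(t[mask], drop_first=True).to_numpy(dtype=float)
            else:
                x = t[mask].to_numpy(dtype=float).reshape(-1, 1)
            model = sm.OLS(y[mask], sm.add_constant(x)).fit()
            estimate = float(model.params[1]) if x.shape[1] == 1 else float(model.rsquared)
            p = float(model.f_pvalue) if np.isfinite(model.f_pvalue) else float("nan")
            rows.append(
                {
                    "module": module,
                    "trait": col,
                    "estimate": estimate,
                    "p_value": p,
                    "significant": bool(p <= alpha) if np.isfinite(p) else False,
                    "note": "",
                }
            )
    return pd.DataFrame(rows)
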