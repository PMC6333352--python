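"""Probe filtering, gene summarization, SVD trait screening and demographic tests.

Probe-level microarray matrices come with per-probe detection calls; a probe
is kept only when it is detected in at least half of the samples of *each*
group, and a gene's expression is the median over its retained probes.  The
SVD screen associates principal components of the row-centred matrix with
sample covariates to flag global confounders.  The demographic report mirrors
a clinical "Table 1": chi-square with Yates continuity correction for 2x2
contingency tables, plain Pearson chi-square for larger ones, and Welch's t
or Mann-Whitney for continuous traits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ProbeMatrix",
    "filter_and_summarize",
    "svd_screen",
    "demographic_tests",
    "yates_chi2",
]


@dataclass
class ProbeMatrix:
    """Probe-level values with detection calls and a probe->gene map."""

    values: pd.DataFrame  # probes x samples
    probe_to_gene: pd.Series  # probe -> gene symbol
    detected: pd.DataFrame  # probes x samples booleans

    def __post_init__(self):
        if self.values.shape != self.detected.shape:
            raise ValueError("values and detected must share shape")
        if not self.values.index.equals(self.detected.index) or not self.values.columns.equals(
            self.detected.columns
        ):
            raise ValueError("values and detected must share index/columns")
        missing = self.values.index.difference(self.probe_to_gene.index)
        if len(missing):
            raise ValueError(f"{len(missing)} probes lack a gene mapping")


def filter_and_summarize(probes: ProbeMatrix, groups: pd.Series) -> pd.DataFrame:
    """Presence-filter probes per group and summarize genes by the probe median.

    A probe survives iff detected in >= 50% of the samples of each group; a
    gene is emitted iff at least one of its probes survives; its per-sample
    value is the median across surviving probes.  Gene rows come out sorted.
    """
    groups = pd.Series(groups)
    samples = probes.values.columns.intersection(groups.index)
    if len(samples) == 0:
        raise ValueError("no overlap between probe samples and group labels")
    groups = groups.loc[samples]
    keep = pd.Series(True, index=probes.values.index)
    for _, members in groups.groupby(groups).groups.items():
        frac = probes.detected.loc[:, members].mean(axis=1)
        keep &= frac >= 0.5
    retained = probes.values.loc[keep, samples]
    if retained.empty:
        return pd.DataFrame(columns=samples)
    gene_of = probes.probe_to_gene.loc[retained.index]
    summarized = retained.groupby(gene_of).median()
    summarized.index.name = None
    return summarized.sort_index()


def svd_screen(
    expr: pd.DataFrame,
    traits: pd.DataFrame,
    n_components: int = 5,
    categorical: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Associate principal components of the row-centred matrix with traits.

    Continuous traits are tested with a univariate linear model of the PC
    scores on the trait, categorical ones with a one-way ANOVA; both report
    the variance explained (R^2) and the p-value.  Constant traits yield NaN
    rather than an exception.
    """
    n_components = int(n_components)
    if n_components > min(expr.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    samples = expr.columns.intersection(traits.index)
    x = expr.loc[:, samples].to_numpy(dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    var_explained = s**2 / np.sum(s**2)
    if categorical is None:
        categorical = tuple(
            c for c in traits.columns if not pd.api.types.is_numeric_dtype(traits[c])
        )
    rows = []
    for pc in range(n_components):
        scores = vt[pc]
        for col in traits.columns:
            tvals = traits.loc[samples, col]
            kind = "categorical" if col in categorical else "continuous"
            r2, p = _associate(scores, tvals, kind)
            rows.append(
                {
                    "component": pc + 1,
                    "variance_explained": float(var_explained[pc]),
                    "trait": col,
                    "kind": kind,
                    "r_squared": r2,
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)


def _associate(scores: np.ndarray, trait: pd.Series, kind: str) -> tuple[float, float]:
    mask = trait.notna().to_numpy()
    y, t = scores[mask], trait[mask]
    if len(y) < 3 or t.nunique() < 2:
        return float("nan"), float("nan")
    if kind == "continuous":
        res = stats.linregress(t.to_numpy(dtype=float), y)
        return float(res.rvalue**2), float(res.pvalue)
    levels = [y[(t == lv).to_numpy()] for lv in t.unique()]
    if any(len(g) == 0 for g in levels):
        levels = [g for g in levels if len(g)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*levels)
    grand = y.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in levels)
    ss_total = float(np.sum((y - grand) ** 2))
    r2 = ss_between / ss_total if ss_total > 0 else float("nan")
    return float(r2), float(p)


def yates_chi2(table: np.ndarray) -> tuple[float, float]:
    """Chi-square on a contingency table; continuity-corrected when 2x2.

    The 2x2 correction uses the floored form max(0, |O-E| - 0.5) per cell, so
    tables whose observed counts all sit within half a count of expectation
    score exactly 0 (p = 1).  Larger tables use the plain Pearson statistic.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.size == 0:
        raise ValueError("table must be a 2-D contingency table")
    # drop all-zero rows/columns before testing
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return float("nan"), float("nan")
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    dof = (table.shape[0] - 1) * (table.shape[1] - 1)
    if table.shape == (2, 2):
        dev = np.maximum(np.abs(table - expected) - 0.5, 0.0)
    else:
        dev = np.abs(table - expected)
    stat = float(np.sum(dev**2 / expected))
    return stat, float(stats.chi2.sf(stat, dof))


def demographic_tests(
    traits: pd.DataFrame,
    condition: str = "condition",
    continuous: tuple[str, ...] | None = None,
    continuous_test: str = "welch",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Clinical-table group comparison: one test per trait, chosen by type.

    Categorical traits get a chi-square on the condition x level table (Yates
    continuity correction when 2x2); continuous traits get Welch's t by
    default or Mann-Whitney (``continuous_test='mannwhitney'``).
    """
    if condition not in traits.columns:
        raise ValueError(f"missing condition column {condition!r}")
    cond = traits[condition]
    groups = cond.unique()
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    if continuous is None:
        continuous = tuple(
            c for c in traits.columns if c != condition and pd.api.types.is_numeric_dtype(traits[c])
        )
    rows = []
    for col in traits.columns:
        if col == condition:
            continue
        a = traits.loc[cond == groups[0], col]
        b = traits.loc[cond == groups[1], col]
        if col in continuous:
            if continuous_test == "mannwhitney":
                stat, p = stats.mannwhitneyu(a.dropna(), b.dropna(), alternative="two-sided")
                test = "mann-whitney"
            else:
                stat, p = stats.ttest_ind(a.dropna(), b.dropna(), equal_var=False)
                test = "welch-t"
            summary = " vs ".join(
                f"mean:{g.mean():.2f} sd:{g.std():.2f}" for g in (a, b)
            )
        else:
            table = pd.crosstab(cond, traits[col])
            stat, p = yates_chi2(table.to_numpy())
            test = "chi-square-yates" if table.shape == (2, 2) else "chi-square"
            summary = " vs ".join(
                "/".join(f"{k}:{v}" for k, v in table.loc[g].items()) for g in table.index
            )
        rows.append(
            {
                "trait": col,
                "test": test,
                "statistic": float(stat),
                "p_value": float(p),
                "significant": bool(p <= alpha),
                "groups": summary,
            }
        )
    return pd.DataFrame(rows)
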