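"""Cohort-level statistics: differential editing, expression–editing
correlation, and hierarchical clustering of tissue editing profiles.

Differential editing compares per-sample editing indices between two
cohorts site by site with a two-sided Welch t-test (default) or
Mann–Whitney U. The fold-change flag is evaluated on the |log2 fold
change| scale with a default cutoff of 0.9 (log2 1.9 ≈ 0.926, i.e. a
“>1.9-fold” change). Raw p-values are reported; an optional
Benjamini–Hochberg column is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .containers import EditingMatrix

__all__ = [
    "differential_editing",
    "correlate_expression_editing",
    "cluster_tissues",
    "CorrelationResult",
]


def _two_group_test(x: np.ndarray, y: np.ndarray, test: str) -> tuple[float, float]:
    """Two-sided test; degenerate equal-constant groups report p = 1."""
    if np.ptp(x) == 0 and np.ptp(y) == 0 and len(x) and len(y):
        if x[0] == y[0]:
            return 0.0, 1.0
        # zero variance in both groups but distinct values: certain shift
        return (np.inf if x[0] > y[0] else -np.inf), 0.0
    if test == "welch":
        res = stats.ttest_ind(x, y, equal_var=False)
    elif test == "student":
        res = stats.ttest_ind(x, y, equal_var=True)
    elif test == "mannwhitney":
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    stat, p = float(res.statistic), float(res.pvalue)
    if np.isnan(p):  # zero variance in both groups but unequal means
        p = 0.0 if np.mean(x) != np.mean(y) else 1.0
        stat = np.inf if np.mean(x) > np.mean(y) else -np.inf
    return stat, p


def differential_editing(
    em: EditingMatrix,
    groups: tuple[str, str] = ("healthy", "diseased"),
    alpha: float = 0.05,
    fc_cutoff: float = 0.9,
    test: str = "welch",
    min_valid: int = 2,
    bh: bool = False,
) -> pd.DataFrame:
    """Per-site differential editing between two cohorts.

    Group means use valid cells only; ``log2_fc`` is
    log2(mean_first/mean_second) and left missing when either mean is
    zero (the p-value is still computed). Sites with fewer than
    ``min_valid`` valid samples in either group are skipped (column
    ``skipped`` on the returned frame's attrs lists them). Output is
    sorted by p-value.
    """
    if "group" not in em.samples.columns:
        raise ValueError("sample metadata lacks a 'group' column")
    ga, gb = groups
    cols_a = np.flatnonzero((em.samples["group"] == ga).to_numpy())
    cols_b = np.flatnonzero((em.samples["group"] == gb).to_numpy())
    if len(cols_a) == 0 or len(cols_b) == 0:
        raise ValueError(f"both groups must be non-empty; got {len(cols_a)} {ga!r} and {len(cols_b)} {gb!r}")
    rows, skipped = [], []
    for i in range(em.n_sites):
        xa = em.values[i, cols_a]
        xb = em.values[i, cols_b]
        xa = xa[np.isfinite(xa)]
        xb = xb[np.isfinite(xb)]
        if len(xa) < min_valid or len(xb) < min_valid:
            skipped.append(i)
            continue
        ma, mb = float(np.mean(xa)), float(np.mean(xb))
        if ma > 0 and mb > 0:
            log2_fc = float(np.log2(ma / mb))
            fold = ma / mb
        else:
            log2_fc, fold = np.nan, np.nan
        stat, p = _two_group_test(xa, xb, test)
        rows.append(
            (
                em.sites.loc[i, "contig"],
                em.sites.loc[i, "pos"],
                ma,
                mb,
                len(xa),
                len(xb),
                fold,
                log2_fc,
                stat,
                p,
                bool(np.isfinite(log2_fc) and abs(log2_fc) >= fc_cutoff),
                bool(p < alpha),
            )
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "contig", "pos", f"mean_{ga}", f"mean_{gb}", f"n_{ga}", f"n_{gb}",
            "fold_change", "log2_fc", "stat", "p", "passes_fc_cutoff", "passes_significance",
        ],
    )
    if bh and len(out):
        order = np.argsort(out["p"].to_numpy())
        n = len(out)
        adj = np.empty(n)
        ranked = out["p"].to_numpy()[order] * n / (np.arange(n) + 1)
        adj[order] = np.minimum.accumulate(ranked[::-1])[::-1]
        out["p_bh"] = np.minimum(adj, 1.0)
    out = out.sort_values("p", kind="mergesort").reset_index(drop=True)
    out.attrs["skipped_sites"] = skipped
    return out


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    slope: float
    intercept: float
    p: float
    n: int


def correlate_expression_editing(expression, editing) -> CorrelationResult:
    """Pearson correlation and least-squares line between paired vectors.

    Used for enzyme-expression vs editing-level comparisons; pairs with
    a missing value in either vector are dropped. Requires ≥3 complete
    pairs and non-constant vectors.
    """
    x = np.asarray(expression, dtype=float)
    y = np.asarray(editing, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = stats.linregress(x, y)
    return CorrelationResult(
        r=float(res.rvalue), slope=float(res.slope),
        intercept=float(res.intercept), p=float(res.pvalue), n=len(x),
    )


def _tree_to_newick(node, labels, parent_height: float) -> str:
    length = max(parent_height - node.dist, 0.0) / 2.0
    if node.is_leaf():
        return f"{labels[node.id]}:{length:.6g}"
    left = _tree_to_newick(node.left, labels, node.dist)
    right = _tree_to_newick(node.right, labels, node.dist)
    return f"({left},{right}):{length:.6g}"


def cluster_tissues(
    em: EditingMatrix,
    method: str = "average",
    metric: str = "euclidean",
):
    """Hierarchical clustering of per-tissue mean editing profiles.

    Tissues are ordered alphabetically before linkage so ties break
    deterministically; sites with a missing mean in any tissue are
    dropped to keep a shared site set. Returns ``(linkage, labels,
    newick)``; branch lengths are ultrametric (half the merge-height
    difference).
    """
    if "tissue" not in em.samples.columns:
        raise ValueError("sample metadata lacks a 'tissue' column")
    labels = sorted(em.samples["tissue"].unique())
    if len(labels) < 3:
        raise ValueError(f"need at least 3 tissues, got {len(labels)}")
    profiles = []
    for tissue in labels:
        cols = np.flatnonzero((em.samples["tissue"] == tissue).to_numpy())
        with np.errstate(invalid="ignore"):
            profiles.append(np.nanmean(em.values[:, cols], axis=1))
    P = np.vstack(profiles)
    shared = np.isfinite(P).all(axis=0)
    if shared.sum() < 1:
        raise ValueError("no site has a valid mean in every tissue")
    Z = hierarchy.linkage(P[:, shared], method=method, metric=metric)
    root = hierarchy.to_tree(Z)
    newick = _tree_to_newick(root, labels, root.dist) + ";"
    return Z, labels, newick
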