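"""Editing-index computation and editing-matrix assembly.

The editing index of a site in one sample is g/(a+g) on the transcribed
strand: C/T reads at an A→G site are treated as sequencing noise rather
than unedited transcripts. ``denominator="coverage"`` switches to the
total-coverage convention. Internally everything is a fraction;
percentages appear only in exported summaries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import BaseCountMatrix, EditingMatrix

__all__ = ["editing_index", "build_editing_matrix", "summarize_by_tissue"]


def editing_index(a_count, g_count):
    """g/(a+g), NaN when a+g = 0. Accepts scalars or arrays."""
    a = np.asarray(a_count)
    g = np.asarray(g_count)
    if (a < 0).any() or (g < 0).any():
        raise ValueError("counts must be non-negative")
    denom = a + g
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, g / np.maximum(denom, 1), np.nan)
    if np.isscalar(a_count) and np.isscalar(g_count):
        return float(out)
    return out


def build_editing_matrix(
    matrix: BaseCountMatrix,
    site_index=None,
    exclusions: np.ndarray | None = None,
    sample_meta: pd.DataFrame | None = None,
    denominator: str = "ag",
) -> EditingMatrix:
    """Assemble a sites × samples editing matrix.

    Parameters
    ----------
    site_index:
        row indices into ``matrix.sites`` to keep (default: all).
    exclusions:
        optional boolean (n_selected_sites, n_samples) mask of cells to
        invalidate (e.g. the multi-editing filter's per-sample
        exclusions); masked cells become NaN.
    sample_meta:
        sample sheet with at least a ``sample`` column; must cover every
        matrix sample (unknown ids raise). Default: bare sample ids.
    """
    if site_index is None:
        site_index = np.arange(matrix.n_sites)
    site_index = np.asarray(site_index)
    sub = matrix.subset_sites(site_index)
    a = sub.base("A").astype(float)
    g = sub.base("G").astype(float)
    if denominator == "ag":
        denom = a + g
        num = g
    elif denominator == "coverage":
        denom = sub.coverage.astype(float)
        num = g
    else:
        raise ValueError("denominator must be 'ag' or 'coverage'")
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(denom > 0, num / np.maximum(denom, 1), np.nan)
    if exclusions is not None:
        exclusions = np.asarray(exclusions, dtype=bool)
        if exclusions.shape != values.shape:
            raise ValueError("exclusions mask shape does not match selected sites × samples")
        values = np.where(exclusions, np.nan, values)
    if sample_meta is None:
        sample_meta = pd.DataFrame({"sample": matrix.samples})
    else:
        lookup = sample_meta.set_index("sample")
        unknown = [s for s in matrix.samples if s not in lookup.index]
        if unknown:
            raise KeyError(f"sample ids missing from sample sheet: {unknown}")
        sample_meta = lookup.loc[matrix.samples].reset_index()
    return EditingMatrix(values=values, sites=sub.sites, samples=sample_meta)


def summarize_by_tissue(em: EditingMatrix) -> pd.DataFrame:
    """Per-tissue, per-site summary: mean, SD, n over valid cells.

    SD is the sample SD (ddof=1), missing for single-sample tissues.
    ``mean_pct``/``sd_pct`` report percentages to one decimal, the
    convention of exported tables.
    """
    if "tissue" not in em.samples.columns:
        raise ValueError("sample metadata lacks a 'tissue' column")
    rows = []
    tissues = sorted(em.samples["tissue"].unique())
    for tissue in tissues:
        cols = np.flatnonzero((em.samples["tissue"] == tissue).to_numpy())
        vals = em.values[:, cols]
        valid = np.isfinite(vals)
        n = valid.sum(axis=1)
        with np.errstate(invalid="ignore"):
            mean = np.where(n > 0, np.nanmean(np.where(valid, vals, np.nan), axis=1), np.nan)
        sd = np.full(len(mean), np.nan)
        for i in np.flatnonzero(n >= 2):
            sd[i] = np.nanstd(vals[i, valid[i]], ddof=1)
        for i in range(em.n_sites):
            rows.append(
                (
                    em.sites.loc[i, "contig"],
                    em.sites.loc[i, "pos"],
                    tissue,
                    mean[i],
                    sd[i],
                    int(n[i]),
                )
            )
    out = pd.DataFrame(rows, columns=["contig", "pos", "tissue", "mean", "sd", "n"])
    out["mean_pct"] = (out["mean"] * 100).round(1)
    out["sd_pct"] = (out["sd"] * 100).round(1)
    return out
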