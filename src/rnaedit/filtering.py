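"""Staged filter cascade for editing-site discovery.

Stages run in a fixed order, each only removing sites (or, for the
multi-editing stage, excluding individual samples at a site):

1. nomination — transcribed-strand A with ≥1 G read anywhere;
2. multi-editing — samples whose alternative reads are dominated by a
   base other than the target are excluded at that site;
3. consistency — a site is kept only when the target base dominates the
   alternative reads in a large enough fraction of informative samples;
4. profile cutoffs — a sample *supports* a site when it meets the
   per-tissue coverage / consensus-read / minimum-editing cutoffs, and
   the site must collect enough supporting samples;
5. blacklist — sites inside hypervariable intervals (HLA, ribosomal
   genes and the like) are removed.

All scalar cutoff comparisons are inclusive (≥). The per-tissue cutoff
profiles bundled in :func:`builtin_profiles` are the published
per-tissue settings; the two auxiliary thresholds (other-alt fraction,
dominant-sample fraction) are package defaults, configurable on the
profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .containers import BASE_INDEX, BaseCountMatrix
from .discovery import nominate_candidates

__all__ = [
    "FilterProfile",
    "FilterReport",
    "builtin_profiles",
    "get_profile",
    "sample_supports",
    "multi_editing_filter",
    "consistency_filter",
    "profile_cutoff_filter",
    "blacklist_filter",
    "ag_enrichment",
    "run_cascade",
]


@dataclass(frozen=True)
class FilterProfile:
    """One tissue's cutoff set.

    ``min_editing`` (per-sample editing index), ``consensus_reads``
    (minimum G-carrying reads for a sample to count the site as edited),
    ``min_coverage`` and ``min_supporting_samples`` are the published
    per-tissue cutoffs. ``max_other_alt_fraction`` and
    ``min_dominant_sample_fraction`` quantify the multi-editing and
    consistency stages (defaults 0.2 and 0.8).
    """

    tissue_label: str
    min_editing: float
    consensus_reads: int
    min_coverage: int
    min_supporting_samples: int
    max_other_alt_fraction: float = 0.2
    min_dominant_sample_fraction: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 < self.min_editing < 1.0:
            raise ValueError("min_editing must lie in (0, 1)")
        for name in ("consensus_reads", "min_coverage", "min_supporting_samples"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("max_other_alt_fraction", "min_dominant_sample_fraction"):
            if not 0.0 < getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")

    def replace(self, **kwargs) -> "FilterProfile":
        return replace(self, **kwargs)


_BUILTIN = [
    ("aorta", 0.05, 2, 15, 70),
    ("ventricular appendage", 0.05, 2, 5, 70),
    ("coronaries", 0.03, 2, 15, 70),
    ("tibial artery", 0.05, 2, 5, 70),
    ("left ventricle", 0.03, 2, 5, 100),
]


def builtin_profiles() -> dict[str, FilterProfile]:
    """The five published per-tissue cutoff profiles, keyed by tissue."""
    return {
        t: FilterProfile(t, min_editing=e, consensus_reads=c, min_coverage=cov,
                         min_supporting_samples=s)
        for t, e, c, cov, s in _BUILTIN
    }


def get_profile(name: str) -> FilterProfile:
    profiles = builtin_profiles()
    if name not in profiles:
        raise KeyError(f"unknown tissue profile {name!r}; options: {sorted(profiles)}")
    return profiles[name]


def sample_supports(profile: FilterProfile, a: int, c: int, g: int, t: int) -> bool:
    """Does one sample's count vector support an A→G site?

    True iff coverage ≥ min_coverage, G ≥ consensus_reads and the
    editing index g/(a+g) ≥ min_editing (all inclusive).
    """
    cov = a + c + g + t
    if cov < profile.min_coverage or g < profile.consensus_reads:
        return False
    if a + g == 0:
        return False
    return g / (a + g) >= profile.min_editing


def _counts_views(counts: np.ndarray, ref_idx: np.ndarray, alt_idx: np.ndarray):
    """Per-candidate ref/target/other-alt count arrays, (n_cand, n_samples)."""
    n = np.arange(counts.shape[0])
    total = counts.sum(axis=2)
    ref = counts[n[:, None], np.arange(counts.shape[1])[None, :], ref_idx[:, None]]
    tgt = counts[n[:, None], np.arange(counts.shape[1])[None, :], alt_idx[:, None]]
    total_alt = total - ref
    other = total_alt - tgt
    return ref, tgt, total_alt, other


def multi_editing_filter(
    profile: FilterProfile,
    counts: np.ndarray,
    ref_idx: np.ndarray,
    alt_idx: np.ndarray,
) -> np.ndarray:
    """Per-sample exclusion flags for multi-edited samples.

    A sample is excluded at a candidate when it has at least
    ``consensus_reads`` alternative (non-reference) reads and more than
    ``max_other_alt_fraction`` of them are not the target base. Samples
    with too few alternative reads are left alone (vacuously kept).
    Returns a boolean (n_candidates, n_samples) array, True = excluded.
    """
    _, tgt, total_alt, other = _counts_views(counts, ref_idx, alt_idx)
    judgeable = total_alt >= profile.consensus_reads
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total_alt > 0, other / np.maximum(total_alt, 1), 0.0)
    return judgeable & (frac > profile.max_other_alt_fraction)


def consistency_filter(
    profile: FilterProfile,
    counts: np.ndarray,
    ref_idx: np.ndarray,
    alt_idx: np.ndarray,
) -> np.ndarray:
    """Keep flags for the cross-sample consistency stage.

    Among samples with ≥ consensus_reads alternative reads, the target
    base must be the dominant alternative (ties count for the target)
    in at least ``min_dominant_sample_fraction`` of them; sites with no
    such informative sample are dropped.
    """
    n_cand, n_samples, _ = counts.shape
    _, tgt, total_alt, _ = _counts_views(counts, ref_idx, alt_idx)
    qualifying = total_alt >= profile.consensus_reads
    # dominant: target >= every other alternative base count
    other_max = np.zeros((n_cand, n_samples), dtype=counts.dtype)
    for b in range(4):
        is_other = (ref_idx != b) & (alt_idx != b)
        if is_other.any():
            other_max[is_other] = np.maximum(other_max[is_other], counts[is_other, :, b])
    dominant = tgt >= other_max
    n_qual = qualifying.sum(axis=1)
    n_dom = (qualifying & dominant).sum(axis=1)
    keep = np.zeros(n_cand, dtype=bool)
    informative = n_qual > 0
    keep[informative] = (
        n_dom[informative] >= profile.min_dominant_sample_fraction * n_qual[informative] - 1e-12
    )
    return keep


def support_matrix(
    profile: FilterProfile,
    counts: np.ndarray,
    ref_idx: np.ndarray,
    alt_idx: np.ndarray,
    excluded: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean (n_candidates, n_samples) support flags under a profile."""
    ref, tgt, _, _ = _counts_views(counts, ref_idx, alt_idx)
    cov = counts.sum(axis=2)
    denom = ref + tgt
    with np.errstate(invalid="ignore", divide="ignore"):
        index = np.where(denom > 0, tgt / np.maximum(denom, 1), 0.0)
    ok = (
        (cov >= profile.min_coverage)
        & (tgt >= profile.consensus_reads)
        & (denom > 0)
        & (index >= profile.min_editing)
    )
    if excluded is not None:
        ok &= ~excluded
    return ok


def profile_cutoff_filter(profile: FilterProfile, n_supporting: np.ndarray) -> np.ndarray:
    """Keep candidates with at least min_supporting_samples supporters."""
    return np.asarray(n_supporting) >= profile.min_supporting_samples


def blacklist_filter(sites: pd.DataFrame, blacklist: pd.DataFrame | None) -> np.ndarray:
    """Keep flags for sites outside every blacklist interval.

    Intervals are 0-based half-open; a site at position p is removed
    when any interval [start, end) on its contig satisfies
    start ≤ p < end.
    """
    keep = np.ones(len(sites), dtype=bool)
    if blacklist is None or len(blacklist) == 0:
        return keep
    trees: dict[str, IntervalTree] = {}
    for _, r in blacklist.iterrows():
        if r["end"] <= r["start"]:
            continue
        trees.setdefault(r["contig"], IntervalTree()).addi(int(r["start"]), int(r["end"]))
    for i, (contig, pos) in enumerate(zip(sites["contig"], sites["pos"])):
        tree = trees.get(contig)
        if tree is not None and tree.overlaps_point(int(pos)):
            keep[i] = False
    return keep


def ag_enrichment(ref: np.ndarray, alt: np.ndarray) -> float | None:
    """Fraction of surviving candidates whose mismatch class is A→G.

    Returns None (reported as missing) when no candidate survives.
    """
    n = len(ref)
    if n == 0:
        return None
    return float(((np.asarray(ref) == "A") & (np.asarray(alt) == "G")).sum() / n)


@dataclass
class StageRecord:
    name: str
    sites_in: int
    sites_out: int
    detail: dict = field(default_factory=dict)


@dataclass
class FilterReport:
    """Per-stage bookkeeping of one cascade run."""

    stages: list[StageRecord]
    final: pd.DataFrame
    enrichment: dict[str, float | None]
    profile: FilterProfile
    support: np.ndarray | None = None
    excluded: np.ndarray | None = None

    @property
    def final_site_keys(self) -> set[tuple[str, int]]:
        return set(zip(self.final["contig"], self.final["pos"]))

    def stage_counts(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.name, s.sites_in, s.sites_out) for s in self.stages],
            columns=["stage", "sites_in", "sites_out"],
        )

    def to_dict(self) -> dict:
        return {
            "profile": vars(self.profile),
            "stages": [
                {"name": s.name, "sites_in": s.sites_in, "sites_out": s.sites_out, **s.detail}
                for s in self.stages
            ],
            "enrichment": self.enrichment,
            "n_final": len(self.final),
        }


def run_cascade(
    matrix: BaseCountMatrix,
    profile: FilterProfile,
    blacklist: pd.DataFrame | None = None,
    all_classes: bool = False,
) -> FilterReport:
    """Run the full staged cascade on a base-count matrix.

    With ``all_classes=True`` the cascade runs over candidates of all
    twelve mismatch classes and the report's enrichment trace gives the
    A→G fraction after each stage (the diagnostic used to tune per-
    tissue cutoffs); the final site table is still restricted to A→G.
    """
    cands = nominate_candidates(matrix, all_classes=all_classes)
    n0 = matrix.n_sites
    counts = matrix.counts[cands.site_index]
    ref_idx = np.array([BASE_INDEX[b] for b in cands.ref], dtype=int)
    alt_idx = np.array([BASE_INDEX[b] for b in cands.alt], dtype=int)

    stages: list[StageRecord] = []
    enrichment: dict[str, float | None] = {}
    alive = np.ones(len(cands), dtype=bool)

    def n_sites_alive() -> int:
        # a site may carry several candidate classes in diagnostic mode
        return int(len(np.unique(cands.site_index[alive])))

    def record(name: str, n_in: int, detail: dict | None = None) -> None:
        stages.append(StageRecord(name, n_in, n_sites_alive(), detail or {}))
        enrichment[name] = ag_enrichment(cands.ref[alive], cands.alt[alive])

    record("nomination", n0)

    excluded = multi_editing_filter(profile, counts, ref_idx, alt_idx)
    # the stage excludes samples, not sites; site count is unchanged
    record("multi_editing", n_sites_alive(),
           {"n_excluded_cells": int(excluded[alive].sum())})

    n_in = n_sites_alive()
    alive &= consistency_filter(profile, counts, ref_idx, alt_idx)
    record("consistency", n_in)

    support = support_matrix(profile, counts, ref_idx, alt_idx, excluded=excluded)
    n_supporting = support.sum(axis=1)
    n_in = n_sites_alive()
    alive &= profile_cutoff_filter(profile, n_supporting)
    record("profile_cutoffs", n_in)

    cand_sites = matrix.sites.iloc[cands.site_index].reset_index(drop=True)
    n_in = n_sites_alive()
    alive &= blacklist_filter(cand_sites, blacklist)
    record("blacklist", n_in)

    keep = alive & cands.is_ag
    ref_c, tgt, _, _ = _counts_views(counts, ref_idx, alt_idx)
    with np.errstate(invalid="ignore", divide="ignore"):
        index = np.where((ref_c + tgt) > 0, tgt / np.maximum(ref_c + tgt, 1), np.nan)
    mean_editing = np.array([
        float(np.mean(index[i, support[i]])) if support[i].any() else np.nan
        for i in np.flatnonzero(keep)
    ])
    final = cand_sites.loc[keep].reset_index(drop=True)
    final["mismatch"] = [f"{r}>{a}" for r, a in zip(cands.ref[keep], cands.alt[keep])]
    final["n_supporting"] = n_supporting[keep]
    final["mean_editing"] = mean_editing
    final = final.sort_values(["contig", "pos"]).reset_index(drop=True)
    return FilterReport(
        stages=stages,
        final=final,
        enrichment=enrichment,
        profile=profile,
        support=support,
        excluded=excluded,
    )
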