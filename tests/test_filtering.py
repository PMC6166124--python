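"""The staged filter cascade: published per-tissue cutoffs, the two
quantified auxiliary stages, blacklist arithmetic, and cascade-level
properties (monotonicity, idempotence, confounder behaviour)."""

import numpy as np
import pandas as pd
import pytest

import rnaedit as re_
from rnaedit.containers import BASE_INDEX
from rnaedit.filtering import (
    consistency_filter,
    multi_editing_filter,
    profile_cutoff_filter,
    sample_supports,
    support_matrix,
)

A, C, G, T = (BASE_INDEX[b] for b in "ACGT")


@pytest.mark.parametrize(
    "tissue,min_editing,consensus,min_cov,min_support",
    [
        ("aorta", 0.05, 2, 15, 70),
        ("ventricular appendage", 0.05, 2, 5, 70),
        ("coronaries", 0.03, 2, 15, 70),
        ("tibial artery", 0.05, 2, 5, 70),
        ("left ventricle", 0.03, 2, 5, 100),
    ],
)
def test_builtin_tissue_profiles(tissue, min_editing, consensus, min_cov, min_support):
    p = re_.get_profile(tissue)
    assert p.min_editing == min_editing
    assert p.consensus_reads == consensus
    assert p.min_coverage == min_cov
    assert p.min_supporting_samples == min_support


def test_unknown_profile_name_raises():
    with pytest.raises(KeyError, match="unknown tissue profile"):
        re_.get_profile("spleen")


@pytest.mark.parametrize(
    "counts,profile_kw,expected",
    [
        # coverage 14 under aorta's min_coverage 15
        ((7, 0, 7, 0), dict(min_editing=0.05, consensus_reads=2, min_coverage=15), False),
        # index 0.2, 2 consensus reads, coverage 10 ≥ 5
        ((8, 0, 2, 0), dict(min_editing=0.05, consensus_reads=2, min_coverage=5), True),
        # single G read never meets consensus_reads=2
        ((19, 0, 1, 0), dict(min_editing=0.01, consensus_reads=2, min_coverage=5), False),
        # boundary: index exactly at min_editing counts (inclusive)
        ((19, 0, 1, 0), dict(min_editing=0.05, consensus_reads=1, min_coverage=5), True),
    ],
)
def test_sample_support_predicate(counts, profile_kw, expected):
    p = re_.FilterProfile("t", min_supporting_samples=1, **profile_kw)
    a, c, g, t = counts
    assert sample_supports(p, a, c, g, t) is expected


def _one_site(counts_per_sample):
    arr = np.array([counts_per_sample])  # (1, n_samples, 4)
    ref = np.array([A])
    alt = np.array([G])
    return arr, ref, alt


@pytest.mark.parametrize(
    "sample_counts,excluded",
    [
        ([10, 5, 5, 0], True),    # other-alt fraction 5/10 = 0.5 > 0.2
        ([10, 0, 5, 0], False),   # fraction 0
        ([10, 1, 0, 0], False),   # only 1 alt read: too few to judge
        ([10, 1, 4, 0], False),   # fraction 1/5 = 0.2, not > 0.2
    ],
)
def test_multi_editing_exclusion(sample_counts, excluded):
    p = re_.get_profile("aorta")
    arr, ref, alt = _one_site([sample_counts])
    assert multi_editing_filter(p, arr, ref, alt)[0, 0] == excluded


def test_consistency_requires_dominant_g_in_enough_samples():
    p = re_.get_profile("aorta")  # min_dominant_sample_fraction 0.8
    g_dom = [5, 0, 5, 0]   # alt reads all G
    c_dom = [5, 5, 1, 0]   # alt reads mostly C
    arr, ref, alt = _one_site([g_dom] * 7 + [c_dom] * 3)
    assert not consistency_filter(p, arr, ref, alt)[0]  # 7/10 < 0.8
    arr, ref, alt = _one_site([g_dom] * 10)
    assert consistency_filter(p, arr, ref, alt)[0]
    arr, ref, alt = _one_site([g_dom] * 8 + [c_dom] * 2)
    assert consistency_filter(p, arr, ref, alt)[0]  # exactly 0.8, inclusive
    # no sample reaches consensus alt reads → not reliably edited
    arr, ref, alt = _one_site([[10, 0, 1, 0]] * 5)
    assert not consistency_filter(p, arr, ref, alt)[0]


def test_supporting_sample_cutoff_is_inclusive():
    p = re_.get_profile("aorta")  # min_supporting_samples 70
    assert not profile_cutoff_filter(p, np.array([69]))[0]
    assert profile_cutoff_filter(p, np.array([70]))[0]


def test_excluded_samples_cannot_support():
    p = re_.FilterProfile("t", 0.05, 2, 5, 1)
    arr, ref, alt = _one_site([[10, 5, 5, 0]])
    excl = multi_editing_filter(p, arr, ref, alt)
    assert excl[0, 0]
    assert not support_matrix(p, arr, ref, alt, excluded=excl)[0, 0]
    assert support_matrix(p, arr, ref, alt)[0, 0]


def test_blacklist_interval_arithmetic():
    sites = pd.DataFrame(
        {"contig": "c", "pos": [100, 100, 250], "strand": "+", "ref_base": "A"}
    )
    bl = pd.DataFrame({"contig": ["c", "c"], "start": [100, 300], "end": [101, 400]})
    keep = re_.blacklist_filter(sites.iloc[[0]], bl)
    assert not keep[0]  # position 100 ∈ [100, 101)
    bl2 = pd.DataFrame({"contig": ["c"], "start": [101], "end": [200]})
    assert re_.blacklist_filter(sites.iloc[[1]], bl2)[0]  # 100 ∉ [101, 200)
    assert re_.blacklist_filter(sites, None).all()


def test_blacklist_removes_planted_sites(small_cohort):
    _, matrix, truth, _ = small_cohort
    covered = truth.sites.iloc[:2]
    bl = pd.DataFrame(
        {"contig": covered["contig"], "start": covered["pos"], "end": covered["pos"] + 1}
    )
    profile = re_.FilterProfile("t", 0.05, 2, 5, 5)
    report = re_.run_cascade(matrix, profile, blacklist=bl)
    assert len(report.final) == len(truth.sites) - 2
    keys = report.final_site_keys
    for _, s in covered.iterrows():
        assert (s["contig"], s["pos"]) not in keys


def test_ag_enrichment_arithmetic():
    ref = np.array(["A"] * 9 + ["A"], dtype=object)
    alt = np.array(["G"] * 9 + ["C"], dtype=object)
    assert re_.ag_enrichment(ref, alt) == pytest.approx(0.9)
    assert re_.ag_enrichment(np.array([], dtype=object), np.array([], dtype=object)) is None


def test_enrichment_trace_starts_near_one_twelfth_and_rises():
    # uniform errors spread candidates evenly over the 12 mismatch
    # classes; planted A→G sites dominate after the support stages
    cfg = re_.SimConfig(seed=41, n_edit_sites=20, error_rate=0.01,
                        reference_length=20_000, n_genes=10, mean_depth=50,
                        rate_range=(0.3, 0.6), n_samples=30)
    matrix, _, _ = re_.simulate_cohort(cfg, re_.make_design(30, 0))
    profile = re_.get_profile("aorta").replace(min_supporting_samples=20)
    report = re_.run_cascade(matrix, profile, all_classes=True)
    assert report.enrichment["nomination"] == pytest.approx(1 / 12, abs=0.03)
    assert report.enrichment["blacklist"] > report.enrichment["nomination"]
    assert report.enrichment["blacklist"] == pytest.approx(1.0, abs=0.05)


def test_error_free_all_ag_simulation_has_enrichment_one(small_cohort):
    _, matrix, _, _ = small_cohort
    profile = re_.FilterProfile("t", 0.05, 2, 5, 5)
    report = re_.run_cascade(matrix, profile, all_classes=True)
    assert report.enrichment["blacklist"] == 1.0


def test_zero_editing_cohort_yields_no_sites():
    cfg = re_.SimConfig(seed=43, n_edit_sites=0, error_rate=0.001,
                        reference_length=10_000, n_genes=5, mean_depth=50,
                        n_samples=20)
    matrix, _, _ = re_.simulate_cohort(cfg, re_.make_design(20, 0))
    profile = re_.get_profile("aorta").replace(min_supporting_samples=14)
    report = re_.run_cascade(matrix, profile)
    assert len(report.final) == 0


def test_stage_counts_are_non_increasing(recovery_fixture):
    *_, report = recovery_fixture
    counts = report.stage_counts()
    assert (counts["sites_out"] <= counts["sites_in"]).all()
    assert (counts["sites_in"].to_numpy()[1:] == counts["sites_out"].to_numpy()[:-1]).all()


def test_cascade_recovers_planted_sites(recovery_fixture):
    _, matrix, truth, profile, report = recovery_fixture
    want = set(zip(truth.sites["contig"], truth.sites["pos"]))
    got = report.final_site_keys
    assert len(got & want) >= 95
    # nothing outside the truth table survives in a low-error run
    assert len(got - want) == 0


def test_cascade_is_idempotent(recovery_fixture):
    _, matrix, truth, profile, report = recovery_fixture
    keys = report.final_site_keys
    idx = [
        i for i, (c, p) in enumerate(zip(matrix.sites["contig"], matrix.sites["pos"]))
        if (c, p) in keys
    ]
    rerun = re_.run_cascade(matrix.subset_sites(idx), profile)
    assert rerun.final_site_keys == keys


@pytest.mark.parametrize(
    "tighten",
    [
        dict(min_editing=0.2),
        dict(consensus_reads=5),
        dict(min_coverage=40),
        dict(min_supporting_samples=75),
    ],
)
def test_tightening_any_cutoff_shrinks_the_site_set(recovery_fixture, tighten):
    _, matrix, _, profile, report = recovery_fixture
    tight = profile.replace(**tighten)
    tight_report = re_.run_cascade(matrix, tight)
    assert tight_report.final_site_keys <= report.final_site_keys


def test_snp_like_confounders_survive_the_printed_filters():
    # documented specificity gap: a fixed G/G genotype in half the
    # samples looks like consistent, heavy editing and passes the
    # cascade; a blacklist (or genotype masking upstream) must catch it
    cfg = re_.SimConfig(seed=45, n_edit_sites=5, n_snp_like=3, error_rate=0.0,
                        reference_length=10_000, n_genes=5, mean_depth=50,
                        rate_range=(0.3, 0.6), n_samples=40)
    matrix, truth, _ = re_.simulate_cohort(cfg, re_.make_design(40, 0))
    profile = re_.FilterProfile("t", 0.05, 2, 5, 10)
    report = re_.run_cascade(matrix, profile)
    snp_keys = {
        (r["contig"], r["start"]) for _, r in truth.confounders.iterrows()
        if r["kind"] == "snp_like"
    }
    assert snp_keys <= report.final_site_keys


def test_multi_mismatch_confounders_are_rejected():
    cfg = re_.SimConfig(seed=47, n_edit_sites=5, n_multi_mismatch=3, error_rate=0.0,
                        reference_length=10_000, n_genes=5, mean_depth=50,
                        rate_range=(0.3, 0.6), n_samples=40)
    matrix, truth, _ = re_.simulate_cohort(cfg, re_.make_design(40, 0))
    profile = re_.FilterProfile("t", 0.05, 2, 5, 10)
    report = re_.run_cascade(matrix, profile)
    mm_keys = {
        (r["contig"], r["start"]) for _, r in truth.confounders.iterrows()
        if r["kind"] == "multi_mismatch"
    }
    assert not (mm_keys & report.final_site_keys)
    want = set(zip(truth.sites["contig"], truth.sites["pos"]))
    assert want <= report.final_site_keys


def test_detection_probability_monotone_in_rate_and_depth():
    # small grid, many replicates: detection of a planted site should
    # not decrease with true rate or depth
    rates = [0.04, 0.12, 0.4]
    depths = [8, 25, 60]
    reps = 50
    det = np.zeros((3, 3))
    for i, mu in enumerate(rates):
        for j, depth in enumerate(depths):
            hits = 0
            for r in range(reps):
                cfg = re_.SimConfig(seed=10_000 + 100 * i + 10 * j + r,
                                    n_edit_sites=1, error_rate=0.001,
                                    reference_length=1200, n_genes=2,
                                    mean_depth=depth, rate_range=(mu, mu),
                                    n_samples=12)
                matrix, truth, _ = re_.simulate_cohort(cfg, re_.make_design(12, 0))
                profile = re_.FilterProfile("t", 0.05, 2, 5, 8)
                report = re_.run_cascade(matrix, profile)
                key = (truth.sites.loc[0, "contig"], truth.sites.loc[0, "pos"])
                hits += key in report.final_site_keys
            det[i, j] = hits / reps
    slack = 0.08  # binomial noise at 50 replicates
    assert (np.diff(det, axis=0) >= -slack).all(), det
    assert (np.diff(det, axis=1) >= -slack).all(), det


def test_profile_validation_rejects_bad_values():
    with pytest.raises(ValueError):
        re_.FilterProfile("t", min_editing=0.0, consensus_reads=2,
                          min_coverage=5, min_supporting_samples=1)
    with pytest.raises(ValueError):
        re_.FilterProfile("t", min_editing=0.05, consensus_reads=0,
                          min_coverage=5, min_supporting_samples=1)
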