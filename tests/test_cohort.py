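"""Differential editing, expression–editing correlation, and tissue
clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

import rnaedit as re_


def _em_from_values(vals_a, vals_b, groups=("healthy", "diseased")):
    vals_a, vals_b = np.atleast_2d(vals_a), np.atleast_2d(vals_b)
    values = np.concatenate([vals_a, vals_b], axis=1)
    n_sites = values.shape[0]
    sites = pd.DataFrame(
        {"contig": "c", "pos": np.arange(n_sites), "strand": "+", "ref_base": "A"}
    )
    meta = [(f"a{i}", "t", groups[0]) for i in range(vals_a.shape[1])]
    meta += [(f"b{i}", "t", groups[1]) for i in range(vals_b.shape[1])]
    samples = pd.DataFrame(meta, columns=["sample", "tissue", "group"])
    return re_.EditingMatrix(values=values, sites=sites, samples=samples)


def test_printed_cohort_means_exceed_the_fold_cutoff():
    # constant groups at the printed 23% / 12% means: log2 FC ≈ 0.9386
    # and linear fold 1.92, clearing the 0.9 / 1.9-fold thresholds
    em = _em_from_values(np.full(5, 0.23), np.full(5, 0.12))
    out = re_.differential_editing(em)
    rec = out.iloc[0]
    assert rec["log2_fc"] == pytest.approx(np.log2(23 / 12), abs=1e-12)
    assert rec["log2_fc"] == pytest.approx(0.9386, abs=5e-4)
    assert rec["fold_change"] > 1.9
    assert rec["passes_fc_cutoff"]
    # constant but different groups: degenerate variance → p = 0
    assert rec["p"] == 0.0 and rec["passes_significance"]


def test_identical_constant_groups_report_p_one_and_no_fc():
    em = _em_from_values(np.full(4, 0.3), np.full(6, 0.3))
    rec = re_.differential_editing(em).iloc[0]
    assert rec["p"] == 1.0
    assert not rec["passes_fc_cutoff"]
    assert rec["log2_fc"] == pytest.approx(0.0)


def test_zero_mean_group_leaves_fold_change_missing():
    em = _em_from_values(np.array([0.3, 0.4, 0.2]), np.zeros(4))
    rec = re_.differential_editing(em).iloc[0]
    assert np.isnan(rec["log2_fc"]) and np.isnan(rec["fold_change"])
    assert np.isfinite(rec["p"])
    assert not rec["passes_fc_cutoff"]


def test_sites_with_too_few_valid_samples_are_skipped():
    vals_a = np.array([[0.2, np.nan, np.nan], [0.2, 0.3, 0.25]])
    vals_b = np.array([[0.1, 0.15, 0.12], [0.1, 0.15, 0.12]])
    em = _em_from_values(vals_a, vals_b)
    out = re_.differential_editing(em)
    assert len(out) == 1
    assert out.attrs["skipped_sites"] == [0]


def test_empty_group_raises():
    em = _em_from_values(np.full(4, 0.3), np.full(4, 0.2), groups=("healthy", "healthy"))
    with pytest.raises(ValueError, match="non-empty"):
        re_.differential_editing(em)


def test_null_false_positive_rate_is_calibrated():
    # 1,000 null sites, both cohorts at the same mean: rejections at
    # α = 0.05 should land near 5%
    rng = np.random.default_rng(61)
    rates = np.full(1000, 0.2)
    em = re_.simulate_editing_matrix(
        {"healthy": (rates, 30), "diseased": (rates, 30)}, depth=50, rng=rng
    )
    out = re_.differential_editing(em)
    fpr = out["passes_significance"].mean()
    assert 0.03 <= fpr <= 0.07
    assert np.abs(out["log2_fc"]).median() < 0.15


def test_records_invariant_to_label_permutation_within_groups():
    rng = np.random.default_rng(63)
    em = re_.simulate_editing_matrix(
        {"healthy": (rng.uniform(0.2, 0.6, 20), 15),
         "diseased": (rng.uniform(0.2, 0.6, 20), 15)},
        depth=50, rng=rng,
    )
    out1 = re_.differential_editing(em)
    # shuffle sample columns within each group
    order = np.arange(len(em.samples))
    h = np.flatnonzero((em.samples["group"] == "healthy").to_numpy())
    d = np.flatnonzero((em.samples["group"] == "diseased").to_numpy())
    order[h] = rng.permutation(h)
    order[d] = rng.permutation(d)
    em2 = re_.EditingMatrix(
        values=em.values[:, order], sites=em.sites,
        samples=em.samples.iloc[order].reset_index(drop=True),
    )
    out2 = re_.differential_editing(em2)
    pd.testing.assert_frame_equal(out1, out2)


def test_mannwhitney_agrees_in_direction_with_welch():
    rng = np.random.default_rng(65)
    em = re_.simulate_editing_matrix(
        {"healthy": (np.full(10, 0.6), 25), "diseased": (np.full(10, 0.25), 25)},
        depth=60, rng=rng,
    )
    welch = re_.differential_editing(em, test="welch").set_index("pos")
    mw = re_.differential_editing(em, test="mannwhitney").set_index("pos")
    for pos in welch.index:
        assert welch.loc[pos, "mean_healthy"] > welch.loc[pos, "mean_diseased"]
        assert mw.loc[pos, "p"] < 0.05 and welch.loc[pos, "p"] < 0.05


def test_benjamini_hochberg_column_is_monotone_and_bounded():
    rng = np.random.default_rng(67)
    em = re_.simulate_editing_matrix(
        {"healthy": (rng.uniform(0.1, 0.8, 50), 10),
         "diseased": (rng.uniform(0.1, 0.8, 50), 10)},
        depth=40, rng=rng,
    )
    out = re_.differential_editing(em, bh=True)
    assert (out["p_bh"] <= 1).all() and (out["p_bh"] >= out["p"] - 1e-12).all()
    assert out["p_bh"].is_monotonic_increasing  # sorted by raw p


def test_perfect_linear_relation_has_r_one():
    x = np.arange(10, dtype=float)
    res = re_.correlate_expression_editing(x, 2 * x)
    assert res.r == pytest.approx(1.0)
    assert res.slope == pytest.approx(2.0)
    assert res.intercept == pytest.approx(0.0, abs=1e-12)


def test_correlation_is_symmetric_in_its_arguments():
    rng = np.random.default_rng(69)
    x, y = rng.normal(size=50), rng.normal(size=50)
    assert re_.correlate_expression_editing(x, y).r == pytest.approx(
        re_.correlate_expression_editing(y, x).r
    )


def test_constant_vector_correlation_is_an_error():
    with pytest.raises(ValueError, match="constant"):
        re_.correlate_expression_editing(np.ones(10), np.arange(10.0))
    with pytest.raises(ValueError, match="at least 3"):
        re_.correlate_expression_editing([1.0, 2.0], [1.0, 2.0])


def test_independent_vectors_rarely_show_large_r():
    rng = np.random.default_rng(71)
    small = sum(
        abs(re_.correlate_expression_editing(rng.normal(size=100), rng.normal(size=100)).r) < 0.3
        for _ in range(200)
    )
    assert small >= 190  # ≥95% of replicates


def _three_tissue_em(rng, delta=0.25):
    base = rng.uniform(0.3, 0.7, 20)
    distinct = np.clip(base - delta, 0.02, 0.98)
    return re_.simulate_editing_matrix(
        {"appendage": (base, 6), "ventricle": (base, 6), "artery": (distinct, 6)},
        depth=80, rng=rng, kappa=200.0,
    )


def test_similar_tissues_merge_first():
    rng = np.random.default_rng(73)
    em = _three_tissue_em(rng)
    Z, labels, _ = re_.cluster_tissues(em)
    first = {labels[int(Z[0, 0])], labels[int(Z[0, 1])]}
    assert first == {"appendage", "ventricle"}


def test_clustering_is_deterministic():
    rng1, rng2 = np.random.default_rng(75), np.random.default_rng(75)
    _, _, nwk1 = re_.cluster_tissues(_three_tissue_em(rng1))
    _, _, nwk2 = re_.cluster_tissues(_three_tissue_em(rng2))
    assert nwk1 == nwk2
    assert nwk1.endswith(";") and "appendage" in nwk1


def test_heart_and_artery_profiles_split_into_two_clades():
    rng = np.random.default_rng(77)
    heart = rng.uniform(0.15, 0.35, 25)
    artery = rng.uniform(0.6, 0.9, 25)
    em = re_.simulate_editing_matrix(
        {
            "ventricle": (heart, 5), "appendage": (heart, 5),
            "aorta": (artery, 5), "tibial": (artery, 5), "coronary": (artery, 5),
        },
        depth=80, rng=rng, kappa=200.0,
    )
    Z, labels, _ = re_.cluster_tissues(em)
    two = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    clades = {}
    for label, cl in zip(labels, two):
        clades.setdefault(cl, set()).add(label)
    assert {"ventricle", "appendage"} in clades.values()
    assert {"aorta", "tibial", "coronary"} in clades.values()


def test_fewer_than_three_tissues_is_an_error():
    rng = np.random.default_rng(79)
    em = re_.simulate_editing_matrix(
        {"t1": (np.full(5, 0.5), 4), "t2": (np.full(5, 0.4), 4)}, depth=40, rng=rng
    )
    with pytest.raises(ValueError, match="at least 3 tissues"):
        re_.cluster_tissues(em)
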