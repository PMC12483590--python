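"""Preprocessing chain, differential expression and marker scoring."""

import numpy as np
import pandas as pd
import pytest

from proteoscope.matrices import ConfigError, ScaleError
from proteoscope.prep import (
    collapse_replicates,
    compute_cv,
    cosine_marker_score,
    filter_low_detection,
    group_fold_change,
    impute_global_min,
    log2p1_median_normalize,
    lognormalize,
    wilcoxon_de,
)

from conftest import build_matrix


# ---------------------------------------------------------------------------
# Detection filter / imputation
# ---------------------------------------------------------------------------

def test_detection_filter_boundary(rng):
    # 54 samples; 2/54 = 3.7% dropped, 3/54 = 5.6% kept at the 5% rule
    lines = [f"L{i:02d}" for i in range(27)]
    vals = np.full((2, 54), np.nan)
    vals[0, :2] = 5.0
    vals[1, :3] = 5.0
    m = build_matrix(vals, lines, n_reps=2)
    filtered, dropped = filter_low_detection(m, 0.05)
    assert dropped == ["F000"]
    assert list(filtered.features) == ["F001"]


def test_detection_filter_zero_counts_as_undetected():
    vals = [[0.0, 0.0, 0.0, 7.0], [1.0, 1.0, 1.0, 1.0]]
    m = build_matrix(vals, ["A", "B"], n_reps=2)
    filtered, _ = filter_low_detection(m, min_frac=0.5)
    assert list(filtered.features) == ["F001"]


def test_detection_filter_min_frac_one_keeps_fully_observed():
    vals = np.array([[1.0, 2.0, 3.0, 4.0], [1.0, np.nan, 3.0, 4.0]])
    m = build_matrix(vals, ["A", "B"], n_reps=2)
    filtered, _ = filter_low_detection(m, min_frac=1.0)
    assert list(filtered.features) == ["F000"]


def test_detection_filter_rejects_bad_frac():
    m = build_matrix([[1.0, 2.0]], ["A"], n_reps=2)
    with pytest.raises(ConfigError):
        filter_low_detection(m, 0.0)


def test_impute_global_min():
    vals = np.array([[7.0, np.nan], [9.0, 12.0]])
    m = build_matrix(vals, ["A"], n_reps=2)
    out = impute_global_min(m)
    assert out.values.iloc[0, 1] == 7.0
    assert float(out.values.min().min()) == 7.0  # matrix minimum unchanged
    # no missing -> identity
    out2 = impute_global_min(out)
    pd.testing.assert_frame_equal(out.values, out2.values)


def test_impute_all_missing_errors():
    m = build_matrix(np.full((2, 2), np.nan), ["A"], n_reps=2)
    with pytest.raises(ValueError):
        impute_global_min(m)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def test_log2p1_values_and_median_postcondition(rng):
    vals = rng.lognormal(10, 2, size=(50, 6))
    vals[0, 0], vals[1, 1] = 0.0, 7.0
    m = build_matrix(vals, ["A", "B", "C"], n_reps=2)
    out = log2p1_median_normalize(m)
    assert out.scale == "log2p1"
    # log2(0+1)=0 and log2(7+1)=3 before the per-sample shift
    shift0 = (np.log2(vals[:, 0] + 1) - out.values.iloc[:, 0]).to_numpy()
    assert np.allclose(shift0, shift0[0])
    shift1 = (np.log2(vals[:, 1] + 1) - out.values.iloc[:, 1]).to_numpy()
    assert abs((np.log2(8) - out.values.iloc[1, 1]) - shift1[1]) < 1e-12
    medians = out.values.median(axis=0)
    assert np.allclose(medians, medians.iloc[0], atol=1e-9)


def test_lognormalize_closed_form_and_scale_invariance(rng):
    # single-feature column: ln(1 + sf)
    m = build_matrix([[5.0, 8.0]], ["A"], n_reps=2)
    out = lognormalize(m, scale_factor=100.0)
    assert np.allclose(out.values.to_numpy(), np.log(101.0))
    # doubling a column leaves its output unchanged
    vals = rng.lognormal(8, 1, size=(20, 4))
    m1 = build_matrix(vals, ["A", "B"], n_reps=2)
    m2 = build_matrix(vals * np.array([2.0, 1, 1, 1]), ["A", "B"], n_reps=2)
    pd.testing.assert_series_equal(
        lognormalize(m1).values.iloc[:, 0], lognormalize(m2).values.iloc[:, 0]
    )
    # independent reimplementation of the formula
    expected = np.log1p(10_000 * vals / vals.sum(axis=0, keepdims=True))
    assert np.allclose(lognormalize(m1).values.to_numpy(), expected)


def test_scale_tags_enforce_pipeline_order(rng):
    m = build_matrix(rng.lognormal(8, 1, size=(10, 4)), ["A", "B"], n_reps=2)
    norm = log2p1_median_normalize(m)
    with pytest.raises(ScaleError):
        log2p1_median_normalize(norm)  # double transform
    with pytest.raises(ScaleError):
        collapse_replicates(m)  # collapse before transform
    collapsed = collapse_replicates(norm)
    with pytest.raises(ScaleError):
        impute_global_min(collapsed)


# ---------------------------------------------------------------------------
# Collapse / CV / fold change
# ---------------------------------------------------------------------------

def test_collapse_replicates_mean_and_shape():
    # uneven replicate structure: A has 2 reps, B has 1
    vals = [[2.0, 4.0, 10.0], [1.0, 3.0, 5.0]]
    import pandas as pd
    from proteoscope.matrices import AbundanceMatrix

    meta = pd.DataFrame(
        {
            "cell_line": ["A", "A", "B"],
            "replicate": [1, 2, 1],
            "lineage": ["x", "x", "y"],
        },
        index=pd.Index(["A_R1", "A_R2", "B_R1"], name="sample"),
    )
    df = pd.DataFrame(vals, index=["F0", "F1"], columns=meta.index)
    m = AbundanceMatrix(df, meta, scale="log2p1")
    out = collapse_replicates(m)
    assert out.scale == "collapsed"
    assert list(out.samples) == ["A", "B"]
    assert out.values.loc["F0", "A"] == 3.0  # (2+4)/2
    assert out.values.loc["F0", "B"] == 10.0  # single replicate passthrough


def test_compute_cv_hand_example():
    vals = [[10.0, 10.0, 10.0, 1.0], [8.0, 12.0, 7.0, 2.0]]
    m = build_matrix(vals, ["A", "B"], n_reps=2)
    # line A = first two columns
    cv, frac = compute_cv(m, "A", threshold=0.2)
    assert cv["F000"] == 0.0
    assert np.isclose(cv["F001"], np.std([8, 12], ddof=1) / 10.0)
    assert frac == 0.5
    with pytest.raises(KeyError):
        compute_cv(m, "Z")


def test_group_fold_change_antisymmetry_and_shift(rng):
    vals = rng.normal(10, 2, size=(30, 6))
    m = build_matrix(vals, [f"L{i}" for i in range(6)], n_reps=1, scale="log2p1")
    collapsed = collapse_replicates(m)
    fc = group_fold_change(collapsed, ["L0", "L1"])
    fc_swap = group_fold_change(collapsed, ["L2", "L3", "L4", "L5"])
    assert np.allclose(fc, -fc_swap)
    shifted = collapsed.with_values(
        collapsed.values + np.array([3.0, 3.0, 0, 0, 0, 0])
    )
    assert np.allclose(group_fold_change(shifted, ["L0", "L1"]), fc + 3.0)
    with pytest.raises(ValueError):
        group_fold_change(collapsed, list(collapsed.samples))  # empty complement


# ---------------------------------------------------------------------------
# Wilcoxon DE
# ---------------------------------------------------------------------------

def test_wilcoxon_exact_small_sample():
    """Complete separation at n=3 vs 3: two-sided exact p = 2/C(6,3) = 0.1."""
    vals = np.array([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]])
    m = build_matrix(vals, [f"L{i}" for i in range(3)], n_reps=2, scale="log2p1")
    groups = {s: ("a" if i < 3 else "b") for i, s in enumerate(m.samples)}
    res = wilcoxon_de(m, groups).table
    p = res.loc[(res["group"] == "a"), "p"].iloc[0]
    assert np.isclose(p, 0.1)


def test_wilcoxon_constant_feature_p_one():
    vals = np.array([[5.0] * 6, [1, 2, 3, 7, 8, 9]])
    m = build_matrix(vals, [f"L{i}" for i in range(3)], n_reps=2, scale="log2p1")
    groups = {s: ("a" if i < 3 else "b") for i, s in enumerate(m.samples)}
    res = wilcoxon_de(m, groups).table
    assert (res.loc[res["feature"] == "F000", "p"] == 1.0).all()


def test_wilcoxon_bonferroni_and_joint_rule(rng):
    n_feat = 1000
    vals = rng.normal(10, 1, size=(n_feat, 8))
    vals[0, :4] += 5.0  # large planted effect
    m = build_matrix(vals, [f"L{i}" for i in range(4)], n_reps=2, scale="log2p1")
    groups = {s: ("a" if i < 4 else "b") for i, s in enumerate(m.samples)}
    res = wilcoxon_de(m, groups, fc_threshold=2.0).table
    row = res[(res["feature"] == "F000") & (res["group"] == "a")].iloc[0]
    assert np.isclose(row["p_adj"], min(1.0, row["p"] * n_feat))
    # significant requires BOTH conditions
    sig = res[res["significant"]]
    assert (sig["p_adj"] < 0.05).all() and (sig["log2_fc"].abs() > 2).all()


def test_wilcoxon_type_one_raw_rate(rng):
    """Under a global null, ~5% of raw p-values fall below 0.05."""
    vals = rng.normal(0, 1, size=(2000, 20))
    m = build_matrix(vals, [f"L{i:02d}" for i in range(10)], n_reps=2, scale="log2p1")
    groups = {s: ("a" if i < 10 else "b") for i, s in enumerate(m.samples)}
    res = wilcoxon_de(m, groups).table
    rate = (res.loc[res["group"] == "a", "p"] < 0.05).mean()
    assert 0.03 < rate < 0.07


# ---------------------------------------------------------------------------
# COSG marker scores
# ---------------------------------------------------------------------------

def _marker_matrix():
    # 6 lines in 2 groups; F0 expressed only and evenly in group a
    vals = np.array(
        [
            [5.0, 5.0, 5.0, 0.0, 0.0, 0.0],
            [2.0, 2.0, 2.0, 2.0, 2.0, 2.0],  # uniform
            [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],  # zero-norm
        ]
    )
    m = build_matrix(vals, [f"L{i}" for i in range(6)], n_reps=1)
    groups = {s: ("a" if i < 3 else "b") for i, s in enumerate(m.samples)}
    return m, groups


@pytest.mark.parametrize("mu", [0.5, 1.0, 2.0])
def test_perfect_indicator_scores_one_for_any_mu(mu):
    m, groups = _marker_matrix()
    scores = cosine_marker_score(m, groups, mu=mu)
    s = scores.set_index(["feature", "group"])["score"]
    assert np.isclose(s.loc[("F000", "a")], 1.0)


def test_uniform_feature_closed_form():
    """For a uniform feature, cos_k = sqrt(|g_k|/n) and sum_k cos^2 = 1, so
    the mu=1 score is (|g_k|/n)^(3/2)."""
    m, groups = _marker_matrix()
    s = cosine_marker_score(m, groups, mu=1.0).set_index(["feature", "group"])["score"]
    assert np.isclose(s.loc[("F001", "a")], (3 / 6) ** 1.5)
    assert np.isclose(s.loc[("F001", "b")], (3 / 6) ** 1.5)


def test_zero_variance_feature_scores_zero():
    m, groups = _marker_matrix()
    s = cosine_marker_score(m, groups).set_index(["feature", "group"])["score"]
    assert s.loc[("F002", "a")] == 0.0


def test_planted_markers_recovered_at_zero_noise(noise_free_config):
    from proteoscope.prep import collapse_replicates, log2p1_median_normalize
    from proteoscope.synthetic import simulate_proteome

    matrix, truth = simulate_proteome(noise_free_config)
    collapsed = collapse_replicates(log2p1_median_normalize(matrix))
    linear = collapsed.with_values(2.0 ** collapsed.values)
    scores = cosine_marker_score(linear, collapsed.meta["lineage"])
    s = scores.set_index(["feature", "group"])["score"]
    for protein, lineage in truth.marker_assignments.items():
        assert s.loc[(protein, lineage)] > 0.5, protein
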