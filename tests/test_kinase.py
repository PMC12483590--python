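"""Localization filtering, KSEA, the driver screen and phospho-protein
correlation."""

import numpy as np
import pandas as pd
import pytest

from proteoscope.kinase import (
    KinaseSubstrateMap,
    adjust_phospho_by_protein,
    filter_localization,
    ksea,
    ksea_all_lines,
    per_line_fold_changes,
    phospho_protein_correlation,
    screen_driver_kinases,
    sum_phospho_by_protein,
)
from proteoscope.matrices import AbundanceMatrix

from conftest import build_matrix


# ---------------------------------------------------------------------------
# Localization
# ---------------------------------------------------------------------------

def _sites(probs):
    return pd.DataFrame(
        {
            "protein": [f"P{i}" for i in range(len(probs))],
            "residue": "S",
            "position": range(1, len(probs) + 1),
            "localization_prob": probs,
        }
    )


def test_localization_strictly_greater():
    out = filter_localization(_sites([0.76, 0.75, 1.0, 0.74]))
    assert list(out["localization_prob"]) == [0.76, 1.0]


def test_localization_idempotent_and_identity():
    sites = _sites([1.0, 0.9, 0.8])
    once = filter_localization(sites)
    pd.testing.assert_frame_equal(once, filter_localization(once))
    pd.testing.assert_frame_equal(once, sites)


def test_localization_missing_prob_drop_vs_keep():
    sites = _sites([0.9, np.nan])
    assert len(filter_localization(sites)) == 1
    assert len(filter_localization(sites, keep_missing=True)) == 2


def test_localization_uniform_fraction(rng):
    sites = _sites(rng.uniform(0, 1, size=10_000))
    frac = len(filter_localization(sites)) / 10_000
    se = np.sqrt(0.25 * 0.75 / 10_000)
    assert abs(frac - 0.25) < 3 * se


# ---------------------------------------------------------------------------
# Kinase-substrate map
# ---------------------------------------------------------------------------

def test_ks_map_roundtrip_and_dedup():
    df = pd.DataFrame(
        {
            "kinase": ["K1", "K1", "K1", "K2"],
            "substrate": ["P1", "P1", "P2", "P1"],
            "site_label": ["S473", "S473", "T100", "Y10"],
        }
    )
    ks = KinaseSubstrateMap.from_frame(df)
    assert ks.substrates("K1") == frozenset({"P1:S473", "P2:T100"})
    back = KinaseSubstrateMap.from_frame(ks.to_frame())
    assert back.relations == ks.relations


# ---------------------------------------------------------------------------
# KSEA
# ---------------------------------------------------------------------------

def test_ksea_closed_form():
    """z = (mean_s - mean_p) * sqrt(m) / sd_p against a hand-evaluated case."""
    rng = np.random.default_rng(5)
    fc = pd.Series(rng.normal(0.2, 0.7, size=400),
                   index=[f"P{i:04d}:S{i}" for i in range(400)])
    subs = list(fc.index[:9])
    ks = KinaseSubstrateMap({"K": frozenset(subs)})
    res = ksea(fc, ks)
    expected = (fc[subs].mean() - fc.mean()) * 3.0 / fc.std(ddof=1)
    assert np.isclose(res.loc[0, "z"], expected)
    assert res.loc[0, "m"] == 9


def test_ksea_spec_example_z_three():
    """mean_s=1, mean_p=0, sd_p=1, m=9 gives z = 1 * sqrt(9) / 1 = 3."""
    # 9 substrates at 1; N others at -9/N +/- a with a chosen so that the
    # whole population has mean 0 and SD (ddof=1) exactly 1
    n, m = 401, 9
    N = n - m  # 392, even
    a = np.sqrt((n - 1 - m - m**2 / N) / N)
    others = -m / N + a * np.tile([1.0, -1.0], N // 2)
    x = np.concatenate([np.ones(m), others])
    s = pd.Series(x, index=[f"P{i}:S1" for i in range(n)])
    assert abs(s.mean()) < 1e-12 and abs(s.std(ddof=1) - 1.0) < 1e-12
    res = ksea(s, KinaseSubstrateMap({"K": frozenset(s.index[:m])}))
    assert np.isclose(res.loc[0, "z"], 3.0)


def test_ksea_monotone_in_substrate_shift():
    rng = np.random.default_rng(0)
    fc = pd.Series(rng.normal(0, 1, size=300),
                   index=[f"P{i}:S1" for i in range(300)])
    subs = frozenset(fc.index[:10])
    ks = KinaseSubstrateMap({"K": subs})
    z0 = ksea(fc, ks).loc[0, "z"]
    fc2 = fc.copy()
    fc2.loc[list(subs)] += 0.5
    z1 = ksea(fc2, ks).loc[0, "z"]
    assert z1 > z0


def test_ksea_sd_zero_errors_and_m_zero_omitted():
    fc = pd.Series([1.0, 1.0, 1.0], index=["A:S1", "B:S2", "C:S3"])
    ks = KinaseSubstrateMap({"K": frozenset(["A:S1"]), "K2": frozenset(["Z:S9"])})
    with pytest.raises(ValueError):
        ksea(fc, ks)
    fc = pd.Series([1.0, 2.0, 3.0], index=["A:S1", "B:S2", "C:S3"])
    res = ksea(fc, ks)
    assert list(res["kinase"]) == ["K"]  # K2 has no measured substrate


def test_ksea_active_requires_more_than_five_substrates():
    rng = np.random.default_rng(1)
    fc = pd.Series(rng.normal(0, 0.3, size=500),
                   index=[f"P{i}:S1" for i in range(500)])
    small = frozenset(fc.index[:5])
    big = frozenset(fc.index[5:15])
    fc.loc[list(small) + list(big)] += 3.0
    res = ksea(fc, KinaseSubstrateMap({"Ksmall": small, "Kbig": big})).set_index("kinase")
    assert not res.loc["Ksmall", "active"]  # m=5 is not "> five"
    assert res.loc["Kbig", "active"]


def test_per_line_fold_changes_one_vs_rest():
    m = build_matrix([[1.0, 2.0, 6.0]], [f"L{i}" for i in range(3)], n_reps=1,
                     scale="log2p1")
    fc = per_line_fold_changes(
        __import__("proteoscope.prep", fromlist=["collapse_replicates"]).collapse_replicates(m)
    )
    assert np.isclose(fc.loc["F000", "L2"], 6.0 - 1.5)
    assert np.isclose(fc.loc["F000", "L0"], 1.0 - 4.0)


# ---------------------------------------------------------------------------
# Driver screen
# ---------------------------------------------------------------------------

def _two_level(vals_p, vals_s, lines, n_reps):
    return (
        build_matrix(vals_p, lines, n_reps=n_reps),
        build_matrix(vals_s, lines, n_reps=n_reps),
    )


def test_driver_fold_pass_and_floor_fail():
    # F0: top line A mean 3.1 vs best other 2.0 -> 1.55-fold at both levels
    p = [[3.1, 3.1, 2.0, 2.0, 1.0, 1.0]]
    pm, sm = _two_level(p, p, ["A", "B", "C"], n_reps=2)
    hits = screen_driver_kinases(pm, sm)
    assert list(hits["feature"]) == ["F000"]
    assert np.isclose(hits.loc[0, "protein_fold"], 1.55)
    assert hits.loc[0, "cell_line"] == "A"
    # replicate floor: top reps (10, 4), other line's max replicate 9:
    # 4 > 0.5 * 9 = 4.5 is false -> no hit
    p2 = [[10.0, 4.0, 0.5, 0.5, 9.0, 0.5]]
    pm2, sm2 = _two_level(p2, p2, ["A", "B", "C"], n_reps=2)
    assert len(screen_driver_kinases(pm2, sm2)) == 0
    # same-line reading ignores the other line's spread: 4 > 0.5*10 false too
    assert len(screen_driver_kinases(pm2, sm2, floor_reference="same_line")) == 0
    # but with top reps (10, 6): other_lines fails? 6 > 4.5 ok; mean 8 vs 4.75
    p3 = [[10.0, 6.0, 0.5, 0.5, 9.0, 0.5]]
    pm3, sm3 = _two_level(p3, p3, ["A", "B", "C"], n_reps=2)
    assert len(screen_driver_kinases(pm3, sm3)) == 1


def test_driver_requires_both_levels():
    p = [[4.0, 4.0, 1.0, 1.0]]
    s = [[1.0, 1.0, 1.0, 1.0]]  # flat phosphorylation
    pm, sm = _two_level(p, s, ["A", "B"], n_reps=2)
    assert len(screen_driver_kinases(pm, sm)) == 0


def test_driver_skips_unshared_features():
    pm = build_matrix([[4.0, 4.0, 1.0, 1.0]], ["A", "B"], n_reps=2)
    sm = build_matrix([[4.0, 4.0, 1.0, 1.0]], ["A", "B"], n_reps=2,
                      features=["OTHER"])
    hits = screen_driver_kinases(pm, sm)
    assert len(hits) == 0 and set(hits.attrs["skipped"]) == {"F000", "OTHER"}


def test_sum_phospho_by_protein():
    m = build_matrix(
        [[1.0, 2.0], [3.0, 4.0], [10.0, 20.0]],
        ["A"], n_reps=2,
        features=["P1:S5", "P1:T9", "P2:Y3"],
    )
    out = sum_phospho_by_protein(m)
    assert out.values.loc["P1"].tolist() == [4.0, 6.0]
    assert out.values.loc["P2"].tolist() == [10.0, 20.0]


# ---------------------------------------------------------------------------
# Phospho-protein correlation / adjustment
# ---------------------------------------------------------------------------

def _collapsed(vals, features, lines):
    m = build_matrix(vals, lines, n_reps=1, scale="log2p1", features=features)
    from proteoscope.prep import collapse_replicates

    return collapse_replicates(m)


def test_phospho_protein_correlation_bins():
    lines = [f"L{i}" for i in range(6)]
    prot = _collapsed([[1, 2, 3, 4, 5, 6.0]], ["P1"], lines)
    phos = _collapsed(
        [[1, 2, 3, 4, 5, 6.0], [6, 5, 4, 3, 2, 1.0]],
        ["P1:S1", "P1:S2"], lines,
    )
    res = phospho_protein_correlation(phos, prot).set_index("site")
    assert res.loc["P1:S1", "r"] == 1.0 and res.loc["P1:S1", "bin"] == "strong"
    assert res.loc["P1:S2", "r"] == -1.0 and res.loc["P1:S2", "bin"] == "none"


def test_phospho_protein_correlation_excludes_orphans():
    lines = [f"L{i}" for i in range(6)]
    prot = _collapsed([[1, 2, 3, 4, 5, 6.0]], ["P1"], lines)
    phos = _collapsed([[1, 2, 3, 4, 5, 6.0]], ["P9:S1"], lines)
    res = phospho_protein_correlation(phos, prot)
    assert res.loc[0, "bin"] == "excluded" and np.isnan(res.loc[0, "r"])


def test_adjust_phospho_by_protein_elementwise(rng):
    lines = [f"L{i}" for i in range(5)]
    pv = rng.normal(10, 1, size=(2, 5))
    sv = rng.normal(12, 1, size=(3, 5))
    prot = _collapsed(pv, ["P1", "P2"], lines)
    phos = _collapsed(sv, ["P1:S1", "P2:S2", "P3:S3"], lines)
    adjusted, dropped = adjust_phospho_by_protein(phos, prot)
    assert dropped == ["P3:S3"]
    expected = sv[0] - pv[0]
    assert np.allclose(adjusted.values.loc["P1:S1"].to_numpy(), expected)
    # constant protein -> constant shift leaves ranks untouched
    prot2 = _collapsed([[7.0] * 5], ["P1"], lines)
    phos2 = _collapsed([sv[0]], ["P1:S1"], lines)
    adj2, _ = adjust_phospho_by_protein(phos2, prot2)
    assert (adj2.values.loc["P1:S1"].rank() == phos2.values.loc["P1:S1"].rank()).all()
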