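"""Self-validation benchmarks: recovery, calibration and oracle checks.

Each function plants known signal with the synthetic generators (or builds
an adversarial random input), runs the corresponding pipeline operation,
and returns the measured quantities as a plain dict. The acceptance script
and the acceptance test suite both call these, so the numbers they report
are always recomputed from scratch.

Problem sizes are desk-scale (hundreds of features, tens to a hundred
replicate runs); they are stated per function and chosen so the whole
battery runs in a few minutes on one core.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .cna import cna_feature_correlation, cis_trans_summary
from .glyco import (
    aggregate_site_glycans,
    class_fractions,
    consistency_filter,
    parse_glycan_composition,
)
from .kinase import KinaseSubstrateMap, ksea, screen_driver_kinases
from .matrices import AbundanceMatrix, make_meta
from .prep import (
    collapse_replicates,
    impute_global_min,
    log2p1_median_normalize,
    wilcoxon_de,
)
from .rppa import (
    foldchange_concordance,
    map_panel,
    per_protein_correlation,
    rppa_normalize,
)
from .synthetic import (
    SimConfig,
    TransHotspot,
    simulate_cna,
    simulate_glyco_psms,
    simulate_panel,
    simulate_proteome,
    simulate_rppa,
)


def _child_seed(seed: int, k: int) -> int:
    return (int(seed) * 1_000_003 + k) % (2**31 - 1)


# ---------------------------------------------------------------------------
# Glyco layer
# ---------------------------------------------------------------------------

_COMPOSITIONS = (
    "HexNAc(2)Hex(9)",
    "Hex(9)HexNAc(2)",  # alternative spelling of the same composition
    "HexNAc(4)Hex(5)NeuAc(2)",
    "HexNAc(4)Hex(5)Fuc(1)",
    "HexNAc(4)Hex(5)Fuc(1)NeuAc(1)",
    "HexNAc(2)Hex(3)",
)


def glyco_aggregation_oracle(seed: int, n_psms: int = 1000) -> dict:
    """Spectral-counting table vs an independent nested-loop tally.

    Returns the number of (key, sample) cells where the two disagree
    (0 = exact integer equality everywhere) on ``n_psms`` random PSMs.
    """
    rng = np.random.default_rng(_child_seed(seed, 1))
    psms = pd.DataFrame(
        {
            "protein": [f"P{rng.integers(1, 8)}" for _ in range(n_psms)],
            "site": rng.integers(1, 6, size=n_psms) * 10,
            "composition": rng.choice(_COMPOSITIONS, size=n_psms),
            "sample": [f"s{rng.integers(1, 7)}" for _ in range(n_psms)],
            "charge": rng.integers(2, 5, size=n_psms),
        }
    )
    table = aggregate_site_glycans(psms)

    tally: dict = {}
    for row in psms.itertuples(index=False):  # brute-force oracle
        key = (
            row.protein,
            row.site,
            parse_glycan_composition(row.composition).canonical(),
            row.sample,
        )
        tally[key] = tally.get(key, 0) + 1
    got = {
        (*key, sample): int(c)
        for key, r in table.counts.iterrows()
        for sample, c in r.items()
        if c > 0
    }
    mismatches = sum(1 for k in set(tally) | set(got) if tally.get(k) != got.get(k))
    mismatches += int(table.total_counts() != n_psms)
    return {"mismatches": mismatches, "n": n_psms}


def glyco_class_bookkeeping(seed: int, n_keys: int = 800) -> dict:
    """Class fractions vs the generator's drawn class tallies (exact)."""
    cfg = SimConfig(
        seed=_child_seed(seed, 2),
        n_lines=10, n_reps_per_line=3, n_lineages=2, lineage_sizes=(5, 5),
        n_proteins=200, n_phosphosites=50, n_markers_per_lineage=5,
        n_site_glycans=n_keys,
    )
    psms, truth = simulate_glyco_psms(cfg)
    frac = class_fractions(aggregate_site_glycans(psms))
    drawn = truth.glycan_classes.value_counts(normalize=True)
    max_err = max(
        abs(frac[c] - drawn.get(c, 0.0)) for c in frac.index
    )
    return {
        "max_fraction_error": float(max_err),
        "fraction_sum_dev": float(abs(frac.sum() - 1.0)),
        "n": n_keys,
    }


def consistency_filter_oracle(
    seed: int, n_rows: int = 500, n_lines: int = 5, n_reps: int = 3
) -> dict:
    """Kept-row set vs brute-force re-evaluation of the >half rule."""
    rng = np.random.default_rng(_child_seed(seed, 3))
    lines = [f"L{i}" for i in range(n_lines)]
    samples = [f"{l}_{r}" for l in lines for r in range(n_reps)]
    rep_map = {f"{l}_{r}": (l, r) for l in lines for r in range(n_reps)}
    counts = rng.integers(0, 3, size=(n_rows, len(samples)))
    counts[counts.sum(axis=1) == 0, 0] = 1  # every key needs >= 1 PSM

    rows = []
    for i in range(n_rows):
        for s, c in zip(samples, counts[i]):
            rows.extend([(f"P{i}", 10, "HexNAc(2)Hex(9)", s, 2)] * int(c))
    psms = pd.DataFrame(
        rows, columns=["protein", "site", "composition", "sample", "charge"]
    )
    table = aggregate_site_glycans(psms)
    kept, _ = consistency_filter(table, rep_map)
    kept_set = set(kept.counts.index)

    expected = set()
    for key, row in table.counts.iterrows():
        for l in lines:
            det = sum(row.get(f"{l}_{r}", 0) > 0 for r in range(n_reps))
            if det * 2 > n_reps:
                expected.add(key)
                break
    return {
        "mismatches": len(kept_set.symmetric_difference(expected)),
        "n": n_rows,
    }


# ---------------------------------------------------------------------------
# KSEA
# ---------------------------------------------------------------------------

def ksea_null_calibration(
    seed: int, n_kinases: int = 1000, n_sites: int = 10_000, m: int = 10
) -> dict:
    """z of kinases with background-drawn substrates should be ~N(0, 1)."""
    rng = np.random.default_rng(_child_seed(seed, 4))
    sites = [f"P{i:05d}:S{i % 999 + 1}" for i in range(n_sites)]
    fc = pd.Series(rng.normal(0.0, 0.5, size=n_sites), index=sites)
    rel = {
        f"K{k}": frozenset(rng.choice(sites, size=m, replace=False))
        for k in range(n_kinases)
    }
    res = ksea(fc, KinaseSubstrateMap(rel))
    return {
        "mean_z": float(res["z"].mean()),
        "sd_z": float(res["z"].std(ddof=1)),
        "n": n_kinases,
    }


def ksea_power(
    seed: int,
    n_runs: int = 100,
    n_sites: int = 1000,
    n_kinases: int = 20,
    m: int = 10,
    shift: float = 1.5,
    background_sd: float = 0.5,
) -> dict:
    """Planted-kinase detection rate and false-activation rate.

    One kinase's ``m`` substrates are shifted by ``shift`` log2 units on a
    background of SD ``background_sd``; activity = FDR < 0.05 and m > 5.
    """
    detected, false, n_null = 0, 0, 0
    for run in range(n_runs):
        rng = np.random.default_rng(_child_seed(seed, 5) + run)
        sites = [f"P{i:04d}:S1" for i in range(n_sites)]
        fc = pd.Series(rng.normal(0.0, background_sd, size=n_sites), index=sites)
        rel = {
            f"K{k}": frozenset(rng.choice(sites, size=m, replace=False))
            for k in range(n_kinases)
        }
        fc.loc[list(rel["K0"])] += shift
        res = ksea(fc, KinaseSubstrateMap(rel)).set_index("kinase")
        detected += int(res.loc["K0", "active"])
        others = res.drop("K0")
        false += int(others["active"].sum())
        n_null += len(others)
    return {
        "power": detected / n_runs,
        "false_rate": false / n_null,
        "n": n_runs,
    }


# ---------------------------------------------------------------------------
# Driver screen
# ---------------------------------------------------------------------------

def _exchangeable_pair(rng, n_feat, n_lines, n_reps, cv, planted_fold=None):
    """Two raw matrices (protein, phospho) with exchangeable lines; an
    optional driver planted in the first line at both levels."""
    lines = [f"L{i:02d}" for i in range(n_lines)]
    meta = make_meta(
        lines,
        {l: [f"{l}_R{r}" for r in range(n_reps)] for l in lines},
        {l: "x" for l in lines},
    )
    sd = cv / np.log(2)  # linear CV -> log2 replicate SD (small-cv approx)

    def level():
        base = rng.normal(20.0, 2.0, size=n_feat)
        vals = base[:, None] + rng.normal(0.0, sd, size=(n_feat, n_lines * n_reps))
        return vals

    p, s = level(), level()
    if planted_fold is not None:
        p[0, :n_reps] += np.log2(planted_fold)
        s[0, :n_reps] += np.log2(planted_fold)
    feats = [f"F{i}" for i in range(n_feat)]
    mk = lambda v: AbundanceMatrix(
        pd.DataFrame(2.0**v, index=feats, columns=meta.index), meta
    )
    return mk(p), mk(s)


def driver_screen_validation(
    seed: int,
    n_runs: int = 100,
    n_feat: int = 100,
    n_lines: int = 20,
    n_reps: int = 3,
    cv: float = 0.10,
    planted_fold: float = 2.0,
) -> dict:
    """Recovery of a planted dual-level 2-fold driver and the total hit
    count under exchangeable null lines."""
    recovered, null_hits = 0, 0
    for run in range(n_runs):
        rng = np.random.default_rng(_child_seed(seed, 6) + run)
        pm, sm = _exchangeable_pair(rng, n_feat, n_lines, n_reps, cv, planted_fold)
        hits = screen_driver_kinases(pm, sm)
        hit = hits.set_index("feature")
        recovered += int("F0" in hit.index and hit.loc["F0", "cell_line"] == "L00")
    for run in range(n_runs):
        rng = np.random.default_rng(_child_seed(seed, 7) + run)
        pm, sm = _exchangeable_pair(rng, n_feat, n_lines, n_reps, cv, None)
        null_hits += len(screen_driver_kinases(pm, sm))
    return {"recovery": recovered / n_runs, "null_hits": null_hits, "n": n_runs}


# ---------------------------------------------------------------------------
# Normalization post-conditions
# ---------------------------------------------------------------------------

def normalization_postconditions(seed: int) -> dict:
    """Median equality after log2(x+1) normalization; zero medians after
    RPPA two-pass centering (odd dimensions)."""
    rng = np.random.default_rng(_child_seed(seed, 8))
    lines = [f"L{i}" for i in range(9)]
    meta = make_meta(lines, {l: [f"{l}_R1"] for l in lines}, {l: "x" for l in lines})
    vals = rng.lognormal(12, 2, size=(201, 9))
    vals[rng.random(vals.shape) < 0.2] = np.nan
    m = AbundanceMatrix(pd.DataFrame(vals, index=[f"F{i}" for i in range(201)],
                                     columns=meta.index), meta)
    norm = log2p1_median_normalize(impute_global_min(m))
    medians = norm.values.median(axis=0)
    med_dev = float((medians - np.median(medians)).abs().max())

    rvals = rng.normal(8, 2, size=(7, 9))
    rm = AbundanceMatrix(
        pd.DataFrame(rvals, index=[f"AB{i}" for i in range(7)], columns=meta.index),
        meta, scale="log2",
    )
    centered = rppa_normalize(rm)
    # each pass zeroes its own margin: antibody medians right after the
    # first pass, sample medians after the second (both bit-exact: odd dims)
    pass1 = rm.values.sub(rm.values.median(axis=1), axis=0)
    row_dev = float(pass1.median(axis=1).abs().max())
    col_dev = float(centered.values.median(axis=0).abs().max())
    return {
        "median_norm_max_dev": med_dev,
        "rppa_col_median_dev": col_dev,
        "rppa_row_median_dev": row_dev,
        "n": vals.size,
    }


# ---------------------------------------------------------------------------
# Wilcoxon type-I control
# ---------------------------------------------------------------------------

def wilcoxon_type1(
    seed: int,
    n_runs: int = 100,
    n_features: int = 2000,
    n_lines: int = 27,
    n_reps: int = 2,
    n_groups: int = 7,
) -> dict:
    """Runs (of ``n_runs``) in which zero features pass the joint
    |log2FC| > 2 and Bonferroni < 0.05 rule under a global null
    (54 samples, one-vs-rest over 7 groups)."""
    lines = [f"L{i:02d}" for i in range(n_lines)]
    sizes = [n_lines // n_groups + (1 if i < n_lines % n_groups else 0)
             for i in range(n_groups)]
    lineage, idx = {}, 0
    for g, size in enumerate(sizes):
        for _ in range(size):
            lineage[lines[idx]] = f"G{g}"
            idx += 1
    meta = make_meta(
        lines,
        {l: [f"{l}_R{r}" for r in range(n_reps)] for l in lines},
        lineage,
    )
    clean = 0
    for run in range(n_runs):
        rng = np.random.default_rng(_child_seed(seed, 9) + run)
        vals = rng.normal(10.0, 1.0, size=(n_features, n_lines * n_reps))
        m = AbundanceMatrix(
            pd.DataFrame(vals, index=[f"F{i}" for i in range(n_features)],
                         columns=meta.index),
            meta, scale="log2p1",
        )
        res = wilcoxon_de(m, m.meta["lineage"])
        clean += int(res.table["significant"].sum() == 0)
    return {"runs_clean": clean, "n": n_runs}


# ---------------------------------------------------------------------------
# Cross-platform recovery
# ---------------------------------------------------------------------------

def crossplatform_recovery(seed: int, n_proteins: int = 250) -> dict:
    """Median per-protein MS-RPPA Spearman at the planted rho = 0.6 and
    fold-change concordance between two lineage groups."""
    cfg = SimConfig(seed=_child_seed(seed, 10), n_proteins=n_proteins,
                    n_phosphosites=50, n_site_glycans=10)
    ms, _ = simulate_proteome(cfg)
    panel = simulate_panel(ms, cfg, n_antibodies=200, n_phospho=5, n_absent=10)
    rp, _ = simulate_rppa(ms, panel, cfg)
    msn = collapse_replicates(log2p1_median_normalize(ms))
    rpn = collapse_replicates(rppa_normalize(rp))
    mapped = map_panel(panel, msn)
    mapped = mapped.loc[
        mapped["mapped"] & ~mapped["is_phospho"].astype(bool)
    ].drop_duplicates("ms_feature")
    rp_prot = rpn.with_values(
        rpn.values.loc[mapped["antibody"]].set_axis(mapped["ms_feature"].tolist())
    )
    values = per_protein_correlation(msn, rp_prot)
    groups = msn.meta.groupby("lineage").groups
    names = sorted(groups)
    fc = foldchange_concordance(
        msn, rp_prot, list(groups[names[0]]), list(groups[names[1]])
    )
    return {
        "median_r": values.summary["median_r"],
        "frac_positive": values.summary["frac_positive"],
        "fc_spearman": fc.summary["fc_spearman"],
        "n": values.summary["n_proteins"],
    }


# ---------------------------------------------------------------------------
# CNA recovery
# ---------------------------------------------------------------------------

def cna_recovery(
    seed: int, n_seeds: int = 100, n_hotspot_seeds: int = 5
) -> dict:
    """Mean recovered cis Spearman at planted rho = 0.6 (54 lines) and the
    fraction of passing trans associations on the planted hotspot arm."""
    cis_rs = []
    for run in range(n_seeds):
        cfg = SimConfig(seed=_child_seed(seed, 11) + run, n_proteins=150,
                        n_phosphosites=20, n_site_glycans=10, n_cis_genes=30,
                        n_markers_per_lineage=5)
        ms, _ = simulate_proteome(cfg)
        coll = collapse_replicates(log2p1_median_normalize(impute_global_min(ms)))
        cna, truth = simulate_cna(cfg, coll)
        corr = cna_feature_correlation(cna, coll)
        cis = corr[corr["cis"] & corr["gene"].isin(truth.cis_genes)]
        cis_rs.append(float(cis["r"].mean()))

    on_arm, passing = 0, 0
    for run in range(n_hotspot_seeds):
        cfg = SimConfig(seed=_child_seed(seed, 12) + run, n_proteins=150,
                        n_phosphosites=20, n_site_glycans=10, n_cis_genes=20,
                        n_markers_per_lineage=5)
        ms, _ = simulate_proteome(cfg)
        coll = collapse_replicates(log2p1_median_normalize(impute_global_min(ms)))
        cna, truth = simulate_cna(
            cfg, coll, trans_hotspot=TransHotspot(arm="5p", n_pairs=15, rho=0.9)
        )
        corr = cna_feature_correlation(
            cna, coll, trans_genes=list(cna.genes), trans_features=100
        )
        summ = cis_trans_summary(corr, threshold=0.6)
        trans = summ[~summ["cis"]]
        passing += int(trans["n_passing"].sum())
        on_arm += int(trans.loc[trans["arm"] == "5p", "n_passing"].sum())
    return {
        "mean_cis_r": float(np.mean(cis_rs)),
        "hotspot_fraction": (on_arm / passing) if passing else float("nan"),
        "trans_passing": passing,
        "n": n_seeds,
    }
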