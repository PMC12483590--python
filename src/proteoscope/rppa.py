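"""MS vs RPPA cross-platform comparison.

RPPA (reverse-phase protein array) quantifies a few hundred antibody
targets across all samples at once. Starting from SuperCurve log2 values,
normalization is two-pass median centering: each antibody's median is
subtracted, then each sample's median. The "linear" view used for some
downstream displays is the antilog 2^x of the centered values.

The comparison layer maps each antibody to one representative protein
accession, classifies targets by MS detection coverage (detected in more
than half of samples / in at most half / not at all), correlates the two
platforms per protein across cell lines, and checks fold-change
concordance between two groups of lines computed identically on both
platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrices import AbundanceMatrix

COVERAGE_CLASSES = ("ms_majority", "ms_minority", "ms_absent")

PANEL_COLUMNS = ("antibody", "targets", "representative", "is_phospho", "site_label")


def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Check panel invariants: unique antibody IDs, representative among targets."""
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise KeyError(f"panel is missing columns {missing}")
    if panel["antibody"].duplicated().any():
        dup = panel.loc[panel["antibody"].duplicated(), "antibody"].iloc[0]
        raise ValueError(f"duplicate antibody ID {dup!r}")
    for _, row in panel.iterrows():
        targets = str(row["targets"]).split(";")
        if str(row["representative"]) not in targets:
            raise ValueError(
                f"representative {row['representative']!r} of antibody "
                f"{row['antibody']!r} is not among its targets"
            )
    return panel


def rppa_normalize(
    raw_log2: AbundanceMatrix, linearize: bool = False
) -> AbundanceMatrix:
    """Median-center an antibody x sample log2 matrix.

    First each antibody (row) median is subtracted, then each sample
    (column) median. With ``linearize=True`` the centered values are
    antilogged (2^x) to a linear view; the scale tag then becomes ``raw``.
    """
    raw_log2.require_scale("log2")
    V = raw_log2.values
    if V.isna().all(axis=1).any() or V.isna().all(axis=0).any():
        raise ValueError("matrix has an all-missing antibody row or sample column")
    centered = V.sub(V.median(axis=1, skipna=True), axis=0)
    centered = centered.sub(centered.median(axis=0, skipna=True), axis=1)
    if linearize:
        return raw_log2.with_values(np.power(2.0, centered), scale="raw")
    return raw_log2.with_values(centered, scale="log2")


# ---------------------------------------------------------------------------
# Panel mapping and detection coverage
# ---------------------------------------------------------------------------

def map_panel(panel: pd.DataFrame, ms: AbundanceMatrix) -> pd.DataFrame:
    """Join each antibody to one MS feature via its representative accession.

    Returns one row per antibody with columns ``antibody``, ``representative``,
    ``is_phospho``, ``ms_feature`` (NaN when unmapped) and ``mapped``.
    """
    validate_panel(panel)
    if ms.features.duplicated().any():  # pragma: no cover - container forbids it
        raise ValueError("MS matrix has duplicate feature rows")
    in_ms = panel["representative"].isin(ms.features)
    out = panel[["antibody", "representative", "is_phospho"]].copy()
    out["ms_feature"] = panel["representative"].where(in_ms)
    out["mapped"] = in_ms.to_numpy()
    return out


@dataclass
class CoverageReport:
    """MS detection coverage of the (non-phospho) RPPA panel.

    ``per_antibody`` maps each antibody to its class; ``counts`` and
    ``fractions`` summarize the partition ms_majority / ms_minority /
    ms_absent.
    """

    per_antibody: pd.DataFrame
    counts: pd.Series
    fractions: pd.Series


def detection_coverage(panel: pd.DataFrame, ms: AbundanceMatrix) -> CoverageReport:
    """Classify each non-phospho antibody target by MS detection fraction.

    ms_majority: detected (non-missing, > 0) in strictly more than 50% of
    samples; ms_minority: detected in at least one but at most 50%;
    ms_absent: unmapped or never detected.
    """
    joined = map_panel(panel, ms)
    joined = joined.loc[~joined["is_phospho"].astype(bool)].copy()
    det = (ms.values.notna() & (ms.values > 0)).mean(axis=1)

    def classify(row) -> str:
        if not row["mapped"]:
            return "ms_absent"
        frac = det.loc[row["ms_feature"]]
        if frac > 0.5:
            return "ms_majority"
        if frac > 0:
            return "ms_minority"
        return "ms_absent"

    joined["detection_frac"] = [
        det.loc[f] if isinstance(f, str) else 0.0 for f in joined["ms_feature"]
    ]
    joined["coverage_class"] = joined.apply(classify, axis=1)
    counts = (
        joined["coverage_class"].value_counts().reindex(COVERAGE_CLASSES, fill_value=0)
    )
    return CoverageReport(
        per_antibody=joined,
        counts=counts,
        fractions=counts / counts.sum(),
    )


# ---------------------------------------------------------------------------
# Correlation and fold-change concordance
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceReport:
    """Cross-platform agreement summary.

    ``per_protein`` holds one Spearman r per shared protein (values part)
    or one (MS, RPPA) log2 FC pair per protein (fold-change part);
    ``summary`` carries the headline numbers (median r, fraction positive,
    FC Spearman, exclusion counts).
    """

    per_protein: pd.DataFrame
    summary: dict


def per_protein_correlation(
    ms_collapsed: AbundanceMatrix,
    rppa_collapsed: AbundanceMatrix,
    min_shared: int = 5,
) -> ConcordanceReport:
    """Spearman r between MS and RPPA values per protein across cell lines.

    Both matrices must be collapsed and indexed by protein accession
    (map the panel to representative accessions first).
    """
    ms_collapsed.require_scale("collapsed")
    rppa_collapsed.require_scale("collapsed")
    lines = [l for l in ms_collapsed.samples if l in set(rppa_collapsed.samples)]
    proteins = ms_collapsed.features.intersection(rppa_collapsed.features)
    M = ms_collapsed.values.loc[proteins, lines]
    R = rppa_collapsed.values.loc[proteins, lines]

    rows, n_excluded = [], 0
    for prot in proteins:
        x, y = M.loc[prot], R.loc[prot]
        ok = x.notna() & y.notna()
        if int(ok.sum()) < min_shared:
            n_excluded += 1
            continue
        r = stats.spearmanr(x[ok], y[ok]).statistic
        rows.append((prot, int(ok.sum()), float(r)))
    per = pd.DataFrame(rows, columns=["protein", "n", "r"])
    summary = {
        "n_proteins": len(per),
        "n_excluded": n_excluded,
        "median_r": float(per["r"].median()) if len(per) else float("nan"),
        "frac_positive": float((per["r"] > 0).mean()) if len(per) else float("nan"),
    }
    return ConcordanceReport(per_protein=per, summary=summary)


def foldchange_concordance(
    ms_collapsed: AbundanceMatrix,
    rppa_collapsed: AbundanceMatrix,
    group_a: list[str],
    group_b: list[str],
) -> ConcordanceReport:
    """Per-protein log2 FC (A vs B) on both platforms and their Spearman.

    FC is the difference of group means of the collapsed log-scale values,
    computed identically on both platforms. Proteins missing either group
    on either platform are excluded and counted.
    """
    ms_collapsed.require_scale("collapsed")
    rppa_collapsed.require_scale("collapsed")
    ga, gb = list(group_a), list(group_b)
    if not ga or not gb:
        raise ValueError("both groups must be non-empty")
    if set(ga) & set(gb):
        raise ValueError("groups must be disjoint")
    for m in (ms_collapsed, rppa_collapsed):
        missing = [l for l in ga + gb if l not in set(m.samples)]
        if missing:
            raise KeyError(f"cell lines absent from a platform matrix: {missing}")

    proteins = ms_collapsed.features.intersection(rppa_collapsed.features)
    rows, n_excluded = [], 0
    for prot in proteins:
        vals = []
        for m in (ms_collapsed, rppa_collapsed):
            a = m.values.loc[prot, ga].dropna()
            b = m.values.loc[prot, gb].dropna()
            if a.empty or b.empty:
                vals = None
                break
            vals.append(float(a.mean() - b.mean()))
        if vals is None:
            n_excluded += 1
            continue
        rows.append((prot, vals[0], vals[1]))
    per = pd.DataFrame(rows, columns=["protein", "fc_ms", "fc_rppa"])
    if len(per) >= 3:
        rho = float(stats.spearmanr(per["fc_ms"], per["fc_rppa"]).statistic)
    else:
        rho = float("nan")
    summary = {
        "n_proteins": len(per),
        "n_excluded": n_excluded,
        "fc_spearman": rho,
    }
    return ConcordanceReport(per_protein=per, summary=summary)


def intra_inter_correlation(
    m: AbundanceMatrix, groups: pd.Series | dict | None = None
) -> dict:
    """Mean pairwise sample Spearman within vs between groups.

    Groups default to cell lines (replicates within a line are the
    intra-group pairs). Singleton groups contribute no intra pairs.
    """
    if groups is None:
        groups = m.meta["cell_line"]
    labels = pd.Series(groups).reindex(m.samples)
    if labels.isna().any():
        raise KeyError("every sample needs a group label")
    if labels.nunique() < 2:
        raise ValueError("need at least 2 groups")

    V = m.values.dropna(how="any")
    corr, _ = stats.spearmanr(V.to_numpy())
    corr = np.atleast_2d(corr)
    samples = list(m.samples)
    intra, inter = [], []
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            r = corr[i, j]
            if labels.iloc[i] == labels.iloc[j]:
                intra.append(r)
            else:
                inter.append(r)
    return {
        "intra_mean": float(np.mean(intra)) if intra else float("nan"),
        "inter_mean": float(np.mean(inter)) if inter else float("nan"),
        "n_intra_pairs": len(intra),
        "n_inter_pairs": len(inter),
    }
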