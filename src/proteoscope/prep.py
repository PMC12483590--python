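"""Abundance-matrix preprocessing and differential analysis.

The label-free MS pipeline applied here: drop features detected in fewer
than 5% of samples, impute missing values with the global minimum observed
intensity (left-censoring assumption), log2(x+1)-transform with sample-wise
median adjustment, and average replicates to one column per cell line.
Downstream statistics: replicate CV, group fold change as a difference of
log2 means, one-vs-rest Wilcoxon rank-sum tests with Bonferroni correction
(significant = |log2FC| > 2 and adjusted p < 0.05), and COSG-style cosine
marker scores.

Scale tags on :class:`~proteoscope.matrices.AbundanceMatrix` enforce the
pipeline order; calling a step on the wrong scale raises ``ScaleError``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrices import AbundanceMatrix, ConfigError, collapsed_meta


def _detected(values: pd.DataFrame) -> pd.DataFrame:
    """Detection mask: non-missing AND strictly positive."""
    return values.notna() & (values > 0)


def filter_low_detection(
    m: AbundanceMatrix, min_frac: float = 0.05
) -> tuple[AbundanceMatrix, list[str]]:
    """Drop features detected in less than ``min_frac`` of samples.

    Returns the filtered matrix and the list of dropped feature IDs.
    """
    m.require_scale("raw")
    if not 0 < min_frac <= 1:
        raise ConfigError(f"min_frac must be in (0, 1], got {min_frac}")
    frac = _detected(m.values).mean(axis=1)
    keep = frac >= min_frac
    dropped = m.values.index[~keep].tolist()
    return m.with_values(m.values.loc[keep]), dropped


def impute_global_min(m: AbundanceMatrix) -> AbundanceMatrix:
    """Replace every missing cell with the global minimum observed intensity."""
    m.require_scale("raw")
    vals = m.values.to_numpy(dtype=float)
    if np.all(np.isnan(vals)):
        raise ValueError("cannot impute an all-missing matrix")
    gmin = np.nanmin(vals)
    out = m.values.fillna(gmin)
    return m.with_values(out)


def log2p1_median_normalize(m: AbundanceMatrix) -> AbundanceMatrix:
    """log2(x+1) transform, then shift each sample so its median equals the
    grand median of sample medians."""
    m.require_scale("raw")
    vals = m.values.to_numpy(dtype=float)
    if np.nanmin(vals) < 0:
        raise ValueError("negative intensities cannot be log2(x+1)-transformed")
    logged = np.log2(m.values + 1.0)
    col_medians = logged.median(axis=0, skipna=True)
    target = float(np.median(col_medians))
    shifted = logged - (col_medians - target)
    return m.with_values(shifted, scale="log2p1")


def lognormalize(m: AbundanceMatrix, scale_factor: float = 10_000.0) -> AbundanceMatrix:
    """Seurat-style LogNormalize: ln(1 + scale_factor * x / column_sum).

    Missing values are treated as zero for the column sum and stay missing
    in the output.
    """
    m.require_scale("raw")
    colsums = m.values.sum(axis=0, skipna=True)
    if (colsums <= 0).any():
        bad = colsums.index[colsums <= 0].tolist()[:3]
        raise ValueError(f"zero column sum for samples {bad}")
    out = np.log1p(m.values / colsums * scale_factor)
    return m.with_values(out, scale="lognorm")


def collapse_replicates(m: AbundanceMatrix) -> AbundanceMatrix:
    """Average replicate columns into one column per cell line."""
    m.require_scale("log2", "log2p1", "lognorm")
    groups = m.line_columns()
    for line, samples in groups.items():
        if len(samples) == 0:  # pragma: no cover - defensive
            raise ValueError(f"cell line {line!r} has no replicates")
    collapsed = pd.DataFrame(
        {line: m.values[samples].mean(axis=1) for line, samples in groups.items()}
    )
    meta = collapsed_meta(list(groups), m.lineage_of_line())
    return AbundanceMatrix(values=collapsed, meta=meta, scale="collapsed")


def compute_cv(
    m: AbundanceMatrix, line: str, threshold: float = 0.20
) -> tuple[pd.Series, float]:
    """Per-feature coefficient of variation across one cell line's replicates.

    CV = sample SD / mean on the linear (raw) scale. Features with any
    missing replicate in that line are excluded. Returns the CV series and
    the fraction of features with CV below ``threshold``.
    """
    m.require_scale("raw")
    samples = m.line_columns().get(line)
    if samples is None:
        raise KeyError(f"unknown cell line {line!r}")
    if len(samples) < 2:
        raise ValueError(f"cell line {line!r} has fewer than 2 replicates")
    sub = m.values[samples]
    complete = sub.notna().all(axis=1) & (sub > 0).all(axis=1)
    sub = sub.loc[complete]
    cv = sub.std(axis=1, ddof=1) / sub.mean(axis=1)
    frac_below = float((cv < threshold).mean()) if len(cv) else float("nan")
    return cv.rename("cv"), frac_below


def group_fold_change(m: AbundanceMatrix, group: list[str] | set[str]) -> pd.Series:
    """log2 fold change = mean over ``group`` cell lines minus mean over the rest."""
    m.require_scale("collapsed")
    group = [g for g in m.values.columns if g in set(group)]
    rest = [c for c in m.values.columns if c not in set(group)]
    if not group:
        raise ValueError("group is empty or shares no cell lines with the matrix")
    if not rest:
        raise ValueError("group must be a proper subset of cell lines")
    fc = m.values[group].mean(axis=1) - m.values[rest].mean(axis=1)
    return fc.rename("log2_fc")


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

@dataclass
class DEResult:
    """One-vs-rest differential expression table.

    ``table`` columns: feature, group, log2_fc, p, p_adj, significant.
    Bonferroni uses the total feature count of the matrix; significance is
    the joint rule |log2_fc| > fc_threshold and p_adj < alpha.
    """

    table: pd.DataFrame
    n_features: int


def wilcoxon_de(
    m: AbundanceMatrix,
    groups: pd.Series | dict,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
) -> DEResult:
    """Two-sided Wilcoxon rank-sum test, one group vs all others, per feature.

    ``groups`` maps sample -> group label. Constant features (identical
    values in both arms) get p = 1 by convention. p_adj = min(1, p * number
    of features).
    """
    m.require_scale("log2", "log2p1", "lognorm", "collapsed")
    labels = pd.Series(groups).reindex(m.samples)
    if labels.isna().any():
        raise KeyError("every sample needs a group label")
    uniq = list(dict.fromkeys(labels))
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    counts = labels.value_counts()
    if (counts < 2).any():
        small = counts.index[counts < 2].tolist()
        raise ValueError(f"groups with fewer than 2 samples: {small}")

    X = m.values.to_numpy(dtype=float)
    n_feat = X.shape[0]
    rows = []
    for g in uniq:
        in_g = (labels == g).to_numpy()
        xg, xr = X[:, in_g], X[:, ~in_g]
        with np.errstate(invalid="ignore"):
            # exact distribution for small groups without ties, normal
            # approximation (tie-corrected) otherwise
            res = stats.mannwhitneyu(
                xg, xr, axis=1, alternative="two-sided", method="auto"
            )
            p = np.asarray(res.pvalue, dtype=float)
        constant = (np.nanmax(X, axis=1) - np.nanmin(X, axis=1)) == 0
        p[constant | ~np.isfinite(p)] = 1.0
        fc = np.nanmean(xg, axis=1) - np.nanmean(xr, axis=1)
        p_adj = np.minimum(1.0, p * n_feat)
        sig = (np.abs(fc) > fc_threshold) & (p_adj < alpha)
        rows.append(
            pd.DataFrame(
                {
                    "feature": m.features,
                    "group": g,
                    "log2_fc": fc,
                    "p": p,
                    "p_adj": p_adj,
                    "significant": sig,
                }
            )
        )
    return DEResult(table=pd.concat(rows, ignore_index=True), n_features=n_feat)


# ---------------------------------------------------------------------------
# COSG marker scoring
# ---------------------------------------------------------------------------

def cosine_marker_score(
    m: AbundanceMatrix,
    groups: pd.Series | dict | None = None,
    mu: float = 1.0,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """COSG marker score per (feature, group).

    Let c_k be the cosine similarity between a feature's expression vector
    across samples and the L2-normalized indicator vector of group k. The
    score is::

        score_k = c_k * c_k^2 / ((1 - mu) * c_k^2 + mu * sum_j c_j^2)

    With mu = 1 this is c_k^3 / sum_j c_j^2: out-of-group expression enters
    through the other groups' cosines and drags the score down. A feature
    expressed only and evenly in group k scores exactly 1 for any mu.
    Zero-norm features score 0 by convention. Markers are flagged at
    score > ``threshold``.

    Expects non-negative (linear-scale) values; missing values count as 0.
    """
    if groups is None:
        groups = m.meta["lineage"]
    labels = pd.Series(groups).reindex(m.samples)
    if labels.isna().any():
        raise KeyError("every sample needs a group label")
    uniq = list(dict.fromkeys(labels))
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")

    X = m.values.fillna(0.0).to_numpy(dtype=float)
    if X.min() < 0:
        raise ValueError("cosine marker scoring expects non-negative values")
    norms = np.linalg.norm(X, axis=1)
    safe = norms.copy()
    safe[safe == 0] = 1.0
    Xn = X / safe[:, None]

    ind = np.stack(
        [(labels == g).to_numpy(dtype=float) for g in uniq]
    )  # groups x samples
    ind /= np.linalg.norm(ind, axis=1, keepdims=True)

    C = Xn @ ind.T  # features x groups; >= 0 since data non-negative
    C2 = C * C
    tot = C2.sum(axis=1, keepdims=True)
    denom = (1.0 - mu) * C2 + mu * tot
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(denom > 0, C * C2 / denom, 0.0)
    score[norms == 0, :] = 0.0

    out = pd.DataFrame(score, index=m.features, columns=uniq)
    long = out.reset_index(names="feature").melt(
        id_vars="feature", var_name="group", value_name="score"
    )
    long["is_marker"] = long["score"] > threshold
    return long
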