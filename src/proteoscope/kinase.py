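"""Phosphosite filtering, KSEA kinase-activity inference, the kinase-driver
screen, and phospho-protein correlation.

KSEA (kinase-substrate enrichment analysis) scores a kinase in a cell line
by comparing the mean log2 fold change of its measured substrate
phosphosites against the mean log2 fold change of *all* phosphosites in
that line::

    z = (mean_substrates - mean_all) * sqrt(m) / sd_all

with a two-sided normal p-value and Benjamini-Hochberg FDR across kinases
within each line. A kinase is called active when FDR < 0.05 and it has more
than five matched substrates (m >= 6).

The driver screen looks for proteins whose total abundance AND summed
phosphorylation are both at least ``fold`` (default 1.5) times higher in
one cell line than in any other, and whose lowest replicate in that top
line still exceeds ``floor_frac`` (default 50%) of the highest replicate
elsewhere — a guard against single-replicate spikes.

Site IDs are strings ``"<protein>:<residue><position>"``, e.g. ``"P00519:Y393"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrices import AbundanceMatrix

VALID_RESIDUES = ("S", "T", "Y")


def site_id(protein: str, residue: str, position: int) -> str:
    return f"{protein}:{residue}{int(position)}"


def protein_of_site(site: str) -> str:
    return site.rsplit(":", 1)[0]


# ---------------------------------------------------------------------------
# Localization filter
# ---------------------------------------------------------------------------

def filter_localization(
    sites: pd.DataFrame,
    cutoff: float = 0.75,
    keep_missing: bool = False,
) -> pd.DataFrame:
    """Keep phosphosites with localization probability strictly > ``cutoff``.

    ``sites`` must carry a ``localization_prob`` column; any other columns
    (metadata or per-sample intensities) pass through untouched. Rows with
    missing probability are dropped by default (``keep_missing=False``).
    """
    if "localization_prob" not in sites.columns:
        raise KeyError("sites table has no 'localization_prob' column")
    prob = sites["localization_prob"]
    bad = prob.dropna()
    if ((bad < 0) | (bad > 1)).any():
        raise ValueError("localization probabilities must lie in [0, 1]")
    keep = prob > cutoff
    if keep_missing:
        keep = keep | prob.isna()
    return sites.loc[keep]


# ---------------------------------------------------------------------------
# Kinase-substrate map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KinaseSubstrateMap:
    """kinase -> frozenset of substrate site IDs (duplicates collapsed)."""

    relations: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        if not self.relations:
            raise ValueError("kinase-substrate map is empty")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "KinaseSubstrateMap":
        """Build from a 3-column frame (kinase, substrate, site_label).

        ``site_label`` is "S473"-style: residue letter + 1-based position.
        """
        for col in ("kinase", "substrate", "site_label"):
            if col not in df.columns:
                raise KeyError(f"kinase-substrate table is missing column {col!r}")
        rel: dict[str, set[str]] = {}
        for kinase, sub, label in df[["kinase", "substrate", "site_label"]].itertuples(index=False):
            label = str(label).strip()
            if not label or label[0].upper() not in VALID_RESIDUES:
                raise ValueError(f"bad site label {label!r} for kinase {kinase!r}")
            rel.setdefault(str(kinase), set()).add(f"{sub}:{label[0].upper()}{int(label[1:])}")
        return cls({k: frozenset(v) for k, v in rel.items()})

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for kinase in sorted(self.relations):
            for site in sorted(self.relations[kinase]):
                protein, label = site.rsplit(":", 1)
                rows.append((kinase, protein, label))
        return pd.DataFrame(rows, columns=["kinase", "substrate", "site_label"])

    @property
    def kinases(self) -> list[str]:
        return sorted(self.relations)

    def substrates(self, kinase: str) -> frozenset[str]:
        return self.relations[kinase]


# ---------------------------------------------------------------------------
# KSEA
# ---------------------------------------------------------------------------

def ksea(
    site_fc: pd.Series,
    ks_map: KinaseSubstrateMap,
    min_substrates: int = 5,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """KSEA Z-scores for one cell line.

    Parameters
    ----------
    site_fc
        Per-site log2 fold change for one cell line, indexed by site ID.
    ks_map
        Kinase -> substrate site IDs. Kinases with zero matched sites are
        omitted.
    min_substrates
        Activity requires strictly more than this many substrates.

    Returns
    -------
    DataFrame with columns kinase, m, mean_s, z, p, fdr, active, sorted by z.
    """
    site_fc = site_fc.dropna()
    if site_fc.empty:
        raise ValueError("site_fc is empty")
    mean_p = float(site_fc.mean())
    sd_p = float(site_fc.std(ddof=1))
    if sd_p == 0:
        raise ValueError("population SD of site fold changes is zero")

    measured = set(site_fc.index)
    rows = []
    for kinase in ks_map.kinases:
        subs = [s for s in ks_map.substrates(kinase) if s in measured]
        m = len(subs)
        if m == 0:
            continue
        mean_s = float(site_fc.loc[subs].mean())
        z = (mean_s - mean_p) * np.sqrt(m) / sd_p
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append((kinase, m, mean_s, z, p))
    if not rows:
        return pd.DataFrame(columns=["kinase", "m", "mean_s", "z", "p", "fdr", "active"])
    out = pd.DataFrame(rows, columns=["kinase", "m", "mean_s", "z", "p"])
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    out["active"] = (out["fdr"] < fdr_alpha) & (out["m"] > min_substrates)
    return out.sort_values("z", ascending=False, ignore_index=True)


def ksea_all_lines(
    fc_matrix: pd.DataFrame,
    ks_map: KinaseSubstrateMap,
    min_substrates: int = 5,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """KSEA per cell line; ``fc_matrix`` is sites x lines of log2 FC.

    FDR is computed within each line across kinases.
    """
    frames = []
    for line in fc_matrix.columns:
        res = ksea(fc_matrix[line], ks_map, min_substrates, fdr_alpha)
        res.insert(1, "cell_line", line)
        frames.append(res)
    return pd.concat(frames, ignore_index=True)


def per_line_fold_changes(collapsed: AbundanceMatrix) -> pd.DataFrame:
    """One-vs-rest log2 FC of every feature for every cell line.

    For line l: FC = value in l minus the mean over all other lines,
    on the collapsed log2 matrix. This is the per-line input to KSEA.
    """
    collapsed.require_scale("collapsed")
    V = collapsed.values
    n = V.shape[1]
    if n < 2:
        raise ValueError("need at least 2 cell lines")
    total = V.sum(axis=1)
    fc = pd.DataFrame(index=V.index, columns=V.columns, dtype=float)
    for line in V.columns:
        rest_mean = (total - V[line]) / (n - 1)
        fc[line] = V[line] - rest_mean
    return fc


# ---------------------------------------------------------------------------
# Driver screen
# ---------------------------------------------------------------------------

def sum_phospho_by_protein(phospho: AbundanceMatrix) -> AbundanceMatrix:
    """Sum site intensities to one row per protein (linear scale).

    Site IDs must be ``"<protein>:<label>"``; missing values count as zero
    within a protein that has at least one measured site in the sample.
    """
    phospho.require_scale("raw")
    proteins = [protein_of_site(s) for s in phospho.features]
    summed = phospho.values.groupby(proteins, sort=True).sum(min_count=1)
    summed.index.name = "feature"
    return AbundanceMatrix(values=summed, meta=phospho.meta.copy(), scale="raw")


def screen_driver_kinases(
    protein_m: AbundanceMatrix,
    phospho_m: AbundanceMatrix,
    fold: float = 1.5,
    floor_frac: float = 0.5,
    floor_reference: str = "other_lines",
) -> pd.DataFrame:
    """Screen for cell-line-specific kinase drivers.

    A feature is a hit in its top cell line (by linear mean) when, at BOTH
    the total-protein and the summed-phosphorylation level:

    a. top-line mean >= ``fold`` x every other line's mean, and
    b. the minimum replicate value in the top line strictly exceeds
       ``floor_frac`` x the maximum replicate value in any other line
       (``floor_reference="other_lines"``, the default) or within the top
       line itself (``floor_reference="same_line"``).

    Both matrices must be raw (linear) with replicate columns and share
    their cell lines; features are matched by ID (run
    :func:`sum_phospho_by_protein` on the phospho matrix first). The top
    line must agree between the two levels. Features absent from either
    matrix are skipped and reported in the ``skipped`` attribute of the
    returned frame.
    """
    protein_m.require_scale("raw")
    phospho_m.require_scale("raw")
    if floor_reference not in ("other_lines", "same_line"):
        raise ValueError(f"unknown floor_reference {floor_reference!r}")
    lines = protein_m.cell_lines
    if set(lines) != set(phospho_m.cell_lines):
        raise ValueError("protein and phospho matrices must share cell lines")

    shared = protein_m.features.intersection(phospho_m.features)
    skipped = sorted(
        set(protein_m.features).symmetric_difference(phospho_m.features)
    )

    def level_stats(m: AbundanceMatrix):
        cols = m.line_columns()
        means = pd.DataFrame(
            {l: m.values.loc[shared, cols[l]].mean(axis=1) for l in lines}
        )
        mins = pd.DataFrame(
            {l: m.values.loc[shared, cols[l]].min(axis=1) for l in lines}
        )
        maxs = pd.DataFrame(
            {l: m.values.loc[shared, cols[l]].max(axis=1) for l in lines}
        )
        return means, mins, maxs

    p_means, p_mins, p_maxs = level_stats(protein_m)
    s_means, s_mins, s_maxs = level_stats(phospho_m)

    rows = []
    for feat in shared:
        pm, sm = p_means.loc[feat], s_means.loc[feat]
        if pm.isna().any() or sm.isna().any():
            continue
        top = pm.idxmax()
        if sm.idxmax() != top:
            continue
        others = [l for l in lines if l != top]
        p_best_other = pm[others].max()
        s_best_other = sm[others].max()
        if p_best_other <= 0 or s_best_other <= 0:
            continue
        p_fold = pm[top] / p_best_other
        s_fold = sm[top] / s_best_other
        if p_fold < fold or s_fold < fold:
            continue
        if floor_reference == "other_lines":
            floor_ok = (
                p_mins.loc[feat, top] > floor_frac * p_maxs.loc[feat, others].max()
                and s_mins.loc[feat, top] > floor_frac * s_maxs.loc[feat, others].max()
            )
        else:
            floor_ok = (
                p_mins.loc[feat, top] > floor_frac * p_maxs.loc[feat, top]
                and s_mins.loc[feat, top] > floor_frac * s_maxs.loc[feat, top]
            )
        if not floor_ok:
            continue
        runner_up = pm[others].idxmax()
        rows.append(
            (feat, top, float(p_fold), float(s_fold), True, runner_up)
        )

    hits = pd.DataFrame(
        rows,
        columns=[
            "feature",
            "cell_line",
            "protein_fold",
            "phospho_fold",
            "replicate_floor_ok",
            "runner_up",
        ],
    )
    hits.attrs["skipped"] = skipped
    return hits


# ---------------------------------------------------------------------------
# Phospho vs protein correlation
# ---------------------------------------------------------------------------

CORRELATION_BINS = ("strong", "moderate", "weak", "none")


def _bin_r(r: float) -> str:
    if r > 0.6:
        return "strong"
    if r > 0.4:
        return "moderate"
    if r > 0.2:
        return "weak"
    return "none"


def phospho_protein_correlation(
    phospho_m: AbundanceMatrix,
    protein_m: AbundanceMatrix,
    min_shared: int = 5,
) -> pd.DataFrame:
    """Spearman correlation of each phosphosite with its parent protein
    across cell lines, with bin labels strong / moderate / weak / none.

    Both matrices must be collapsed to cell-line columns. Sites with fewer
    than ``min_shared`` jointly observed lines, or without a measured
    parent protein, get NaN r and bin ``"excluded"``.
    """
    phospho_m.require_scale("collapsed")
    protein_m.require_scale("collapsed")
    shared_lines = [l for l in phospho_m.samples if l in set(protein_m.samples)]
    if len(shared_lines) < min_shared:
        raise ValueError("matrices share fewer cell lines than min_shared")

    P = protein_m.values[shared_lines]
    S = phospho_m.values[shared_lines]
    rows = []
    for site in S.index:
        parent = protein_of_site(site)
        if parent not in P.index:
            rows.append((site, parent, 0, np.nan, "excluded"))
            continue
        x, y = S.loc[site], P.loc[parent]
        ok = x.notna() & y.notna()
        n = int(ok.sum())
        if n < min_shared:
            rows.append((site, parent, n, np.nan, "excluded"))
            continue
        r = stats.spearmanr(x[ok], y[ok]).statistic
        rows.append((site, parent, n, float(r), _bin_r(float(r))))
    return pd.DataFrame(rows, columns=["site", "protein", "n", "r", "bin"])


def adjust_phospho_by_protein(
    phospho_m: AbundanceMatrix, protein_m: AbundanceMatrix
) -> tuple[AbundanceMatrix, list[str]]:
    """Subtract parent-protein log2 abundance from each site's log2 value.

    Both matrices must be on a log scale with matching columns. Sites whose
    parent protein is absent are dropped and returned as the second element.
    """
    phospho_m.require_scale("log2", "log2p1", "lognorm", "collapsed")
    protein_m.require_scale("log2", "log2p1", "lognorm", "collapsed")
    if list(phospho_m.samples) != list(protein_m.samples):
        raise ValueError("matrices must share identical sample columns")
    parents = pd.Series(
        [protein_of_site(s) for s in phospho_m.features], index=phospho_m.features
    )
    have = parents.isin(protein_m.features)
    dropped = parents.index[~have].tolist()
    kept = parents[have]
    adjusted = (
        phospho_m.values.loc[kept.index].to_numpy(dtype=float)
        - protein_m.values.loc[kept.values].to_numpy(dtype=float)
    )
    out = pd.DataFrame(adjusted, index=kept.index, columns=phospho_m.samples)
    return phospho_m.with_values(out), dropped
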