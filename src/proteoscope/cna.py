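"""Copy-number association with proteome and phosphoproteome.

Copy number is carried as log2(CN ratio + 1) per gene per cell line (a
diploid CN ratio of 1 maps to exactly 1). Associations are Spearman
correlations between a gene's copy number and a feature's abundance across
cell lines; *cis* pairs couple a gene with its own product, *trans* pairs
couple different genes. Hotspots are summarized per chromosome arm.

Phosphosite features should be protein-adjusted
(:func:`proteoscope.kinase.adjust_phospho_by_protein`) before correlation
so that CNA-phosphorylation signal is not just CNA-protein signal seen
through the site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrices import AbundanceMatrix

#: Chromosome arm labels used for round-robin annotation in synthetic data.
ARM_LABELS = tuple(
    f"{c}{a}" for c in list(range(1, 23)) + ["X"] for a in ("p", "q")
)


@dataclass
class CNAMatrix:
    """Gene x cell-line copy-number matrix with chromosome-arm labels.

    ``values`` holds log2(CN ratio + 1), so values are >= 0 and diploid is 1.
    ``arms`` maps each gene to an arm label (NaN allowed: such genes are
    excluded from per-arm summaries with a warning upstream).
    """

    values: pd.DataFrame
    arms: pd.Series

    def __post_init__(self) -> None:
        if (self.values.to_numpy(dtype=float) < 0).any():
            raise ValueError("log2(CN ratio + 1) values must be non-negative")
        self.arms = self.arms.reindex(self.values.index)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def lines(self) -> pd.Index:
        return self.values.columns


def cna_feature_correlation(
    cna: CNAMatrix,
    features: AbundanceMatrix,
    feature_gene_map: pd.Series | dict | None = None,
    trans_genes: list[str] | int | None = None,
    trans_features: list[str] | int | None = None,
    min_shared: int = 5,
) -> pd.DataFrame:
    """Spearman correlation of copy number against feature abundance.

    All cis pairs (gene == mapped gene of the feature) are always
    computed. The trans cross-product is restricted to ``trans_genes`` x
    ``trans_features``; each may be an explicit list, an integer n (top-n
    by variance), or None. ``trans_genes=None`` with ``trans_features=None``
    skips trans entirely unless one of them is given; pass integers or
    lists for the full/partial scan.

    ``feature_gene_map`` maps feature ID -> gene symbol; the default is the
    identity (protein features named by gene).

    Returns a long frame: gene, feature, n, r, cis, arm.
    """
    features.require_scale("collapsed", "log2", "log2p1", "lognorm")
    lines = [l for l in cna.lines if l in set(features.samples)]
    if len(lines) < min_shared:
        raise ValueError("fewer shared cell lines than min_shared")

    if feature_gene_map is None:
        gene_of = pd.Series(features.features, index=features.features)
    else:
        gene_of = pd.Series(feature_gene_map).reindex(features.features)

    C = cna.values[lines]
    F = features.values[lines]
    # rank once; Spearman = Pearson on ranks (average ranks for ties)
    C_rank = C.rank(axis=1)
    F_rank = F.rank(axis=1)

    def pair_r(gene: str, feat: str) -> tuple[int, float]:
        x, y = C.loc[gene], F.loc[feat]
        ok = x.notna() & y.notna()
        n = int(ok.sum())
        if n < min_shared:
            return n, float("nan")
        if ok.all():
            xr, yr = C_rank.loc[gene], F_rank.loc[feat]
        else:
            xr, yr = x[ok].rank(), y[ok].rank()
        r = np.corrcoef(xr, yr)[0, 1]
        return n, float(r)

    rows = []
    # cis pairs
    for feat, gene in gene_of.items():
        if gene in C.index:
            n, r = pair_r(gene, feat)
            rows.append((gene, feat, n, r, True))

    # trans pairs
    def resolve(spec, index, variance_src):
        if spec is None:
            return None
        if isinstance(spec, int):
            var = variance_src.var(axis=1)
            return list(var.sort_values(ascending=False).index[:spec])
        return [g for g in spec if g in index]

    tg = resolve(trans_genes, C.index, C)
    tf = resolve(trans_features, F.index, F)
    if tg is not None or tf is not None:
        tg = tg if tg is not None else list(C.index)
        tf = tf if tf is not None else list(F.index)
        for gene in tg:
            for feat in tf:
                if gene_of.get(feat) == gene:
                    continue
                n, r = pair_r(gene, feat)
                rows.append((gene, feat, n, r, False))

    out = pd.DataFrame(rows, columns=["gene", "feature", "n", "r", "cis"])
    out["arm"] = cna.arms.reindex(out["gene"]).to_numpy()
    return out


def cis_trans_summary(
    corr: pd.DataFrame, threshold: float = 0.6
) -> pd.DataFrame:
    """Per-arm counts of associations with |r| > ``threshold``, split cis/trans.

    Returns one row per (arm, cis) with columns n_passing and fraction (of
    all passing pairs in that cis/trans stratum). Genes without an arm label
    are grouped under "unannotated" and only counted as trans.
    """
    df = corr.copy()
    df["arm"] = df["arm"].fillna("unannotated")
    df.loc[df["arm"] == "unannotated", "cis"] = False
    passing = df.loc[df["r"].abs() > threshold]
    counts = (
        passing.groupby(["arm", "cis"], sort=True).size().rename("n_passing").reset_index()
    )
    totals = passing.groupby("cis").size()
    counts["fraction"] = [
        row.n_passing / totals.loc[row.cis] for row in counts.itertuples()
    ]
    return counts
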