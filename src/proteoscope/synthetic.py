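"""Synthetic multi-layer proteomics data with known ground truth.

Every downstream stage of the pipeline is testable without any download:
this module fabricates the tables a 54-cell-line MS + RPPA study would
deposit — a label-free proteome matrix with lineage markers, a
phosphoproteome with planted kinase activities, a Byonic-style glycopeptide
PSM table exploded from known site-glycan counts, an RPPA panel correlated
to MS at a configurable strength, and a copy-number matrix with planted cis
effects — together with the ground truth needed to score recovery.

Model sketch (all on the log2 scale unless noted):

* protein base abundance ~ N(20, 2), a typical LFQ dynamic range;
* per-(protein, lineage) effects ~ N(0, lineage_effect_sd) give every
  protein some real between-lineage fold change;
* designated marker proteins gain +log2(marker_fold) in their lineage;
* cell-line effects ~ N(0, biological_sd), replicate noise ~ N(0, noise_sd);
* missingness is left-censored: the dropout probability is a logistic
  function of log-intensity rescaled so its average equals dropout_rate;
* planted kinases add kinase_effect to all their substrate sites in one
  cell line;
* RPPA values are per-protein standardized MS line means plus Gaussian
  noise, so the planted MS-RPPA Spearman correlation is set exactly via
  the Gaussian copula (see :func:`noise_sd_for_spearman`);
* copy number is log2(CN ratio + 1) centered at the diploid value 1, with
  cis genes coupled to their protein's abundance the same way.

One global seed fans out to independent per-table child streams, so adding
one generator never perturbs another's output; identical configs are
bit-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .cna import ARM_LABELS, CNAMatrix
from .glyco import classify_glycan, GlycanComposition
from .kinase import KinaseSubstrateMap, site_id
from .matrices import AbundanceMatrix, ConfigError, make_meta

# child-stream keys; fixed so streams never shift when generators are added
_STREAMS = {
    "lineage": 0,
    "proteome": 1,
    "phospho": 2,
    "glyco": 3,
    "rppa": 4,
    "cna": 5,
    "ksmap": 6,
    "panel": 7,
}

#: Lineage group sizes of the emulated 54-line panel
#: (breast, esophagus/stomach, lymphoid, lung, ovary, large bowel, other).
DEFAULT_LINEAGE_SIZES = (7, 8, 8, 5, 5, 5, 16)


def pearson_for_spearman(rho_s: float) -> float:
    """Pearson correlation of a bivariate Gaussian whose Spearman is ``rho_s``."""
    return float(2.0 * np.sin(np.pi * rho_s / 6.0))


def noise_sd_for_spearman(rho_s: float) -> float:
    """SD of additive Gaussian noise on a standard normal signal that yields
    Spearman correlation ``rho_s`` between signal and signal + noise."""
    rho_p = pearson_for_spearman(rho_s)
    return float(np.sqrt(1.0 / rho_p**2 - 1.0))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults emulate the profiled panel: 54 cell lines in 7 lineage groups
    of sizes 7/8/8/5/5/5/16, 3 replicates each, 6,810 quantified proteins,
    33,161 phosphosites and 56,320 site-specific glycans, with glycan
    classes mixed 49.72% sialylated / 25.16% fucosylated / 25.11%
    high-mannose. Dropout of 0.35 reproduces a per-sample detection rate
    around two-thirds of the filtered proteome. The RPPA noise default
    targets a median per-protein MS-RPPA Spearman of 0.6 and ``cis_corr``
    targets a cis CNA-protein Spearman of 0.6.
    """

    n_lines: int = 54
    n_reps_per_line: int = 3
    n_proteins: int = 6810
    n_phosphosites: int = 33161
    n_lineages: int = 7
    lineage_sizes: Optional[tuple[int, ...]] = DEFAULT_LINEAGE_SIZES
    marker_fold: float = 4.0
    n_markers_per_lineage: int = 20
    kinase_effect: float = 1.5
    n_active_kinases: int = 3
    noise_sd: float = 0.2
    biological_sd: float = 0.8
    lineage_effect_sd: float = 0.5
    dropout_rate: float = 0.35
    loc_below_frac: float = 0.1
    rppa_noise_sd: float = noise_sd_for_spearman(0.6)
    rppa_rep_noise_sd: float = 0.1
    cis_corr: float = 0.6
    n_cis_genes: int = 50
    n_site_glycans: int = 56320
    class_mixture: tuple[float, float, float, float] = (0.4972, 0.2516, 0.2511, 0.0001)
    glyco_line_presence: float = 0.01
    glyco_rep_detect: float = 0.25
    glyco_extra_counts: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_lines", "n_reps_per_line", "n_proteins", "n_phosphosites",
            "n_lineages", "n_markers_per_lineage",
        ):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("dropout_rate", "loc_below_frac", "glyco_line_presence",
                     "glyco_rep_detect"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if not -1 <= self.cis_corr <= 1:
            raise ConfigError("cis_corr must lie in [-1, 1]")
        if self.marker_fold <= 1:
            raise ConfigError("marker_fold must exceed 1")
        if self.lineage_sizes is not None:
            if len(self.lineage_sizes) != self.n_lineages:
                raise ConfigError("lineage_sizes length must equal n_lineages")
            if sum(self.lineage_sizes) != self.n_lines:
                raise ConfigError("lineage_sizes must sum to n_lines")
        if abs(sum(self.class_mixture) - 1.0) > 1e-9:
            raise ConfigError("class_mixture must sum to 1")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=int(self.seed) % (2**31),
                                   spawn_key=(_STREAMS[stream],))
        )

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruth:
    """What was planted, for recovery scoring."""

    marker_assignments: dict[str, str] = field(default_factory=dict)
    active_kinases: list[tuple[str, str, float]] = field(default_factory=list)
    true_site_glycan_counts: Optional[pd.DataFrame] = None
    glycan_classes: Optional[pd.Series] = None
    true_platform_fc: Optional[dict[str, float]] = None
    cis_genes: list[str] = field(default_factory=list)
    hotspot_pairs: list[tuple[str, str]] = field(default_factory=list)
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Shared scaffolding
# ---------------------------------------------------------------------------

def _line_names(config: SimConfig) -> list[str]:
    return [f"CL{i + 1:02d}" for i in range(config.n_lines)]


def lineage_of_lines(config: SimConfig) -> dict[str, str]:
    """Deterministic line -> lineage assignment from configured group sizes."""
    lines = _line_names(config)
    if config.lineage_sizes is not None:
        sizes = config.lineage_sizes
    else:  # spread as evenly as possible
        base = config.n_lines // config.n_lineages
        sizes = tuple(
            base + (1 if i < config.n_lines % config.n_lineages else 0)
            for i in range(config.n_lineages)
        )
    out, idx = {}, 0
    for k, size in enumerate(sizes):
        for _ in range(size):
            out[lines[idx]] = f"LIN{k + 1}"
            idx += 1
    return out


def sample_meta(config: SimConfig) -> pd.DataFrame:
    lines = _line_names(config)
    lineage = lineage_of_lines(config)
    replicates = {
        l: [f"{l}_R{r + 1}" for r in range(config.n_reps_per_line)] for l in lines
    }
    return make_meta(lines, replicates, lineage)


def _dropout_mask(
    log2_vals: np.ndarray, rate: float, rng: np.random.Generator, steepness: float = 1.5
) -> np.ndarray:
    """Abundance-dependent missingness: logistic in log-intensity, rescaled so
    the mean dropout probability equals ``rate``."""
    if rate == 0:
        return np.zeros(log2_vals.shape, dtype=bool)
    center = np.median(log2_vals)
    w = 1.0 / (1.0 + np.exp((log2_vals - center) / steepness))
    p = np.clip(rate * w / w.mean(), 0.0, 1.0)
    return rng.random(log2_vals.shape) < p


def _replicate_expand(
    line_means: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """features x lines -> features x samples with replicate noise."""
    n_feat, n_lines = line_means.shape
    reps = np.repeat(line_means, config.n_reps_per_line, axis=1)
    reps += rng.normal(0.0, config.noise_sd, size=reps.shape)
    return reps


# ---------------------------------------------------------------------------
# Proteome
# ---------------------------------------------------------------------------

def simulate_proteome(config: SimConfig) -> tuple[AbundanceMatrix, GroundTruth]:
    """Label-free proteome matrix (linear scale, NaN missing) with lineage
    markers planted at ``marker_fold``."""
    rng = config.rng("proteome")
    meta = sample_meta(config)
    lineage = lineage_of_lines(config)
    lines = _line_names(config)
    lineages = list(dict.fromkeys(lineage.values()))
    proteins = [f"P{i + 1:05d}" for i in range(config.n_proteins)]

    base = rng.normal(20.0, 2.0, size=config.n_proteins)
    lin_eff = rng.normal(
        0.0, config.lineage_effect_sd, size=(config.n_proteins, len(lineages))
    )

    # markers: disjoint blocks of proteins, one block per lineage
    n_mark = config.n_markers_per_lineage
    if n_mark * len(lineages) > config.n_proteins:
        raise ConfigError("not enough proteins for the requested markers")
    marker_assignments: dict[str, str] = {}
    marker_shift = np.zeros((config.n_proteins, len(lineages)))
    order = rng.permutation(config.n_proteins)
    for k, lin in enumerate(lineages):
        block = order[k * n_mark : (k + 1) * n_mark]
        marker_shift[block, k] = np.log2(config.marker_fold)
        # markers must not carry random lineage effects, or the planted
        # fold would not be exact at zero noise
        lin_eff[block, :] = 0.0
        for idx in block:
            marker_assignments[proteins[idx]] = lin

    lin_index = np.array([lineages.index(lineage[l]) for l in lines])
    line_means = (
        base[:, None]
        + lin_eff[:, lin_index]
        + marker_shift[:, lin_index]
        + rng.normal(0.0, config.biological_sd, size=(config.n_proteins, len(lines)))
    )
    log2_vals = _replicate_expand(line_means, config, rng)
    mask = _dropout_mask(log2_vals, config.dropout_rate, rng)
    linear = np.power(2.0, log2_vals)
    linear[mask] = np.nan

    values = pd.DataFrame(linear, index=proteins, columns=meta.index)
    matrix = AbundanceMatrix(values=values, meta=meta, scale="raw")
    return matrix, GroundTruth(marker_assignments=marker_assignments)


# ---------------------------------------------------------------------------
# Kinase-substrate map and phosphoproteome
# ---------------------------------------------------------------------------

def _site_pool(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Deterministic phosphosite pool: protein, residue, position."""
    proteins = rng.integers(1, config.n_proteins + 1, size=config.n_phosphosites)
    residues = rng.choice(["S", "T", "Y"], p=[0.85, 0.13, 0.02],
                          size=config.n_phosphosites)
    positions = rng.integers(2, 1200, size=config.n_phosphosites)
    df = pd.DataFrame(
        {
            "protein": [f"P{p:05d}" for p in proteins],
            "residue": residues,
            "position": positions,
        }
    )
    df["site"] = [site_id(p, r, q) for p, r, q in
                  zip(df["protein"], df["residue"], df["position"])]
    df = df.drop_duplicates("site").set_index("site")
    return df


def simulate_ks_map(
    config: SimConfig, n_kinases: int = 50, substrates_per_kinase: int = 10
) -> KinaseSubstrateMap:
    """Kinase -> substrate-site map over the phosphosite pool."""
    rng = config.rng("ksmap")
    pool = _site_pool(config, config.rng("phospho"))
    sites = pool.index.to_numpy()
    rel = {}
    for k in range(n_kinases):
        chosen = rng.choice(sites, size=min(substrates_per_kinase, len(sites)),
                            replace=False)
        rel[f"KIN{k + 1:02d}"] = frozenset(chosen.tolist())
    return KinaseSubstrateMap(rel)


class PhosphoSim(NamedTuple):
    matrix: AbundanceMatrix
    sites: pd.DataFrame
    truth: GroundTruth


def simulate_phospho(
    config: SimConfig,
    ks_map: KinaseSubstrateMap,
    active_kinases: Optional[Sequence[tuple[str, str]]] = None,
) -> PhosphoSim:
    """Phosphoproteome with substrate shifts planted for active kinases.

    ``active_kinases`` is a list of (kinase, cell line) pairs; if None,
    ``config.n_active_kinases`` kinases and lines are drawn at random. Each
    planted pair adds ``kinase_effect`` (log2) to every substrate site of
    that kinase in that line's replicates.
    """
    rng = config.rng("phospho")
    pool = _site_pool(config, rng)  # consumes the same leading draws as simulate_ks_map
    meta = sample_meta(config)
    lines = _line_names(config)

    map_sites = sorted(set().union(*[ks_map.substrates(k) for k in ks_map.kinases]))
    extra = [s for s in map_sites if s not in pool.index]
    if extra:
        add = pd.DataFrame(
            {
                "protein": [s.rsplit(":", 1)[0] for s in extra],
                "residue": [s.rsplit(":", 1)[1][0] for s in extra],
                "position": [int(s.rsplit(":", 1)[1][1:]) for s in extra],
            },
            index=pd.Index(extra, name="site"),
        )
        pool = pd.concat([pool, add])

    n_sites = len(pool)
    base = rng.normal(18.0, 2.0, size=n_sites)
    line_means = base[:, None] + rng.normal(
        0.0, config.biological_sd, size=(n_sites, len(lines))
    )

    if active_kinases is None:
        kinases = list(ks_map.kinases)
        picked_k = rng.choice(kinases,
                              size=min(config.n_active_kinases, len(kinases)),
                              replace=False)
        picked_l = rng.choice(lines, size=len(picked_k), replace=True)
        active = list(zip(picked_k.tolist(), picked_l.tolist()))
    else:
        active = list(active_kinases)
        for kinase, line in active:
            if kinase not in ks_map.relations:
                raise KeyError(f"kinase {kinase!r} absent from the substrate map")
            if line not in lines:
                raise KeyError(f"unknown cell line {line!r}")

    site_pos = {s: i for i, s in enumerate(pool.index)}
    for kinase, line in active:
        rows = [site_pos[s] for s in ks_map.substrates(kinase) if s in site_pos]
        line_means[rows, lines.index(line)] += config.kinase_effect

    log2_vals = _replicate_expand(line_means, config, rng)
    mask = _dropout_mask(log2_vals, config.dropout_rate, rng)
    linear = np.power(2.0, log2_vals)
    linear[mask] = np.nan

    n_low = int(round(config.loc_below_frac * n_sites))
    loc = np.empty(n_sites)
    low_idx = rng.choice(n_sites, size=n_low, replace=False)
    loc[:] = rng.uniform(0.7501, 1.0, size=n_sites)
    loc[low_idx] = rng.uniform(0.0, 0.75, size=n_low)

    sites = pool.copy()
    sites["localization_prob"] = loc
    values = pd.DataFrame(linear, index=pool.index, columns=meta.index)
    matrix = AbundanceMatrix(values=values, meta=meta, scale="raw")
    truth = GroundTruth(
        active_kinases=[(k, l, config.kinase_effect) for k, l in active]
    )
    return PhosphoSim(matrix=matrix, sites=sites, truth=truth)


# ---------------------------------------------------------------------------
# Glycopeptide PSMs
# ---------------------------------------------------------------------------

_AA = np.array(list("ACDEFGHIKLMPQRSTVWY"))


def _draw_composition(cls: str, rng: np.random.Generator) -> GlycanComposition:
    if cls == "sialylated":
        d = {
            "HexNAc": int(rng.integers(3, 7)),
            "Hex": int(rng.integers(4, 8)),
            "NeuAc": int(rng.integers(1, 4)),
        }
        if rng.random() < 0.3:
            d["Fuc"] = 1
    elif cls == "fucosylated":
        d = {
            "HexNAc": int(rng.integers(3, 7)),
            "Hex": int(rng.integers(3, 7)),
            "Fuc": int(rng.integers(1, 3)),
        }
    elif cls == "high_mannose":
        d = {"HexNAc": 2, "Hex": int(rng.integers(5, 10))}
    else:  # other: paucimannose-like, must evade the high-mannose rule
        d = {"HexNAc": 2, "Hex": int(rng.integers(2, 5))}
    comp = GlycanComposition.from_dict(d)
    assert classify_glycan(comp) == cls
    return comp


def simulate_glyco_psms(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Byonic-style glycopeptide PSM table exploded from known counts.

    First draws ``true_site_glycan_counts`` — for each (protein, site,
    composition) key, the lines it appears in, the replicates detected
    within those lines (at least one), and a spectral count per detected
    replicate — then emits exactly that many PSM rows per key, randomizing
    peptide sequence/length, missed cleavages (0-2) and charge (2-4).
    """
    rng = config.rng("glyco")
    meta = sample_meta(config)
    lines = _line_names(config)
    classes = np.array(["sialylated", "fucosylated", "high_mannose", "other"])

    # unique keys
    keys: dict[tuple[str, int, str], str] = {}
    while len(keys) < config.n_site_glycans:
        need = config.n_site_glycans - len(keys)
        prot = rng.integers(1, max(2, config.n_proteins // 5), size=need)
        pos = rng.integers(30, 900, size=need)
        cls_draw = rng.choice(classes, p=np.asarray(config.class_mixture), size=need)
        for p, q, c in zip(prot, pos, cls_draw):
            comp = _draw_composition(str(c), rng)
            key = (f"GP{p:05d}", int(q), comp.canonical())
            if key not in keys:
                keys[key] = str(c)

    key_list = list(keys)
    truth_rows = []
    psm_rows = []
    rep_names = {
        l: [f"{l}_R{r + 1}" for r in range(config.n_reps_per_line)] for l in lines
    }
    spectrum = 0
    for (protein, position, comp), cls in zip(key_list, keys.values()):
        n_extra_lines = rng.binomial(config.n_lines - 1, config.glyco_line_presence)
        present_lines = rng.choice(lines, size=1 + n_extra_lines, replace=False)
        for line in present_lines:
            det = rng.random(config.n_reps_per_line) < config.glyco_rep_detect
            if not det.any():
                det[rng.integers(config.n_reps_per_line)] = True
            for r, on in enumerate(det):
                if not on:
                    continue
                sample = rep_names[line][r]
                count = 1 + rng.poisson(config.glyco_extra_counts)
                truth_rows.append((protein, position, comp, cls, sample, count))
                for _ in range(count):
                    spectrum += 1
                    pep_len = int(rng.integers(8, 26))
                    pep = "".join(rng.choice(_AA, size=pep_len))
                    # glycosite residue is N by construction
                    pep = pep[: pep_len // 2] + "N" + pep[pep_len // 2 + 1 :]
                    psm_rows.append(
                        (
                            f"SPEC{spectrum:07d}", protein, position, "N", pep,
                            int(rng.integers(2, 5)), int(rng.integers(0, 3)),
                            comp, sample, line, r + 1,
                        )
                    )

    psms = pd.DataFrame(
        psm_rows,
        columns=[
            "spectrum_id", "protein", "site", "residue", "peptide", "charge",
            "missed_cleavages", "composition", "sample", "cell_line", "replicate",
        ],
    )
    truth_counts = pd.DataFrame(
        truth_rows,
        columns=["protein", "site", "composition", "glycan_class", "sample", "count"],
    )
    key_classes = (
        truth_counts.drop_duplicates(["protein", "site", "composition"])
        .set_index(["protein", "site", "composition"])["glycan_class"]
    )
    truth = GroundTruth(
        true_site_glycan_counts=truth_counts, glycan_classes=key_classes
    )
    truth.extras["sample_meta"] = meta
    return psms, truth


# ---------------------------------------------------------------------------
# RPPA
# ---------------------------------------------------------------------------

def simulate_panel(
    ms: AbundanceMatrix,
    config: SimConfig,
    n_antibodies: int = 231,
    n_phospho: int = 74,
    n_absent: int = 19,
) -> pd.DataFrame:
    """Antibody panel: protein antibodies (some multi-target, ``n_absent`` of
    them targeting proteins the MS matrix never saw) plus phospho antibodies."""
    rng = config.rng("panel")
    n_mapped = n_antibodies - n_absent
    if n_mapped > len(ms.features):
        raise ConfigError("MS matrix has too few proteins for the requested panel")
    targets = rng.choice(ms.features.to_numpy(), size=n_mapped, replace=False)
    rows = []
    for i, t in enumerate(targets):
        multi = rng.random() < 0.1
        tgt = f"{t};{rng.choice(ms.features.to_numpy())}" if multi else str(t)
        rows.append((f"AB{i + 1:03d}", tgt, str(t), False, ""))
    for j in range(n_absent):
        acc = f"ABS{j + 1:03d}"
        rows.append((f"AB{n_mapped + j + 1:03d}", acc, acc, False, ""))
    for k in range(n_phospho):
        t = str(rng.choice(ms.features.to_numpy()))
        label = f"{rng.choice(['S', 'T', 'Y'])}{int(rng.integers(2, 1200))}"
        rows.append((f"ABP{k + 1:03d}", t, t, True, label))
    return pd.DataFrame(
        rows, columns=["antibody", "targets", "representative", "is_phospho", "site_label"]
    )


def simulate_rppa(
    ms_matrix: AbundanceMatrix,
    panel: pd.DataFrame,
    config: SimConfig,
) -> tuple[AbundanceMatrix, GroundTruth]:
    """RPPA log2 matrix (antibody x sample) correlated to MS.

    For a mapped protein antibody, each cell line's RPPA level is that
    protein's standardized MS log2 line mean plus N(0, rppa_noise_sd) at the
    line level and N(0, rppa_rep_noise_sd) per replicate; this pins the
    collapsed MS-RPPA Spearman at the copula target. MS-absent targets (and
    phospho antibodies) get independent values of matching variance, so
    they exist on the array but carry no MS signal.
    """
    ms_matrix.require_scale("raw")
    rng = config.rng("rppa")
    meta = ms_matrix.meta
    lines = ms_matrix.cell_lines
    cols = ms_matrix.line_columns()

    log2 = np.log2(ms_matrix.values + 1.0)
    line_mean = pd.DataFrame({l: log2[cols[l]].mean(axis=1) for l in lines})
    mu = line_mean.mean(axis=1)
    sd = line_mean.std(axis=1, ddof=1).replace(0.0, 1.0)
    Z = line_mean.sub(mu, axis=0).div(sd, axis=0)  # proteins x lines

    n_reps = config.n_reps_per_line
    values = {}
    for row in panel.itertuples(index=False):
        rep = str(row.representative)
        mapped = (not bool(row.is_phospho)) and rep in Z.index
        if mapped:
            z = Z.loc[rep].to_numpy(dtype=float)
            z = np.where(np.isfinite(z), z, rng.normal(size=len(lines)))
            line_vals = z + rng.normal(0.0, config.rppa_noise_sd, size=len(lines))
        else:
            total_sd = np.sqrt(1.0 + config.rppa_noise_sd**2)
            line_vals = rng.normal(0.0, total_sd, size=len(lines))
        reps = np.repeat(line_vals, n_reps) + rng.normal(
            0.0, config.rppa_rep_noise_sd, size=len(lines) * n_reps
        )
        values[str(row.antibody)] = reps

    sample_order = [s for l in lines for s in cols[l]]
    df = pd.DataFrame(values, index=sample_order).T
    df = df[list(meta.index)]
    matrix = AbundanceMatrix(values=df, meta=meta.copy(), scale="log2")
    truth = GroundTruth(
        extras={
            "absent_antibodies": panel.loc[
                ~panel["representative"].isin(Z.index) & ~panel["is_phospho"].astype(bool),
                "antibody",
            ].tolist(),
            "target_spearman_total_noise": float(
                np.sqrt(config.rppa_noise_sd**2 + config.rppa_rep_noise_sd**2 / n_reps)
            ),
        }
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Copy number
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransHotspot:
    """A planted trans-acting arm: ``n_pairs`` extra genes on ``arm``, each
    rank-correlated at ``rho`` with one distinct (non-cis) feature."""

    arm: str = "5p"
    n_pairs: int = 20
    rho: float = 0.9


def simulate_cna(
    config: SimConfig,
    collapsed_proteome: AbundanceMatrix,
    trans_hotspot: Optional[TransHotspot] = None,
) -> tuple[CNAMatrix, GroundTruth]:
    """Gene x line log2(CN ratio + 1) matrix with planted cis effects.

    The first ``n_cis_genes`` genes (drawn at random from the collapsed
    proteome's features) are coupled to their own protein's abundance at a
    Spearman correlation of ``cis_corr`` via the Gaussian copula; all other
    genes are independent noise around the diploid value 1. Chromosome arms
    are assigned round-robin. An optional :class:`TransHotspot` appends
    extra genes forced onto one arm, each driving one feature.
    """
    collapsed_proteome.require_scale("collapsed")
    rng = config.rng("cna")
    V = collapsed_proteome.values
    lines = list(V.columns)
    genes = list(V.index)
    n_genes = len(genes)

    mu = V.mean(axis=1)
    sd = V.std(axis=1, ddof=1).replace(0.0, 1.0)
    Zp = V.sub(mu, axis=0).div(sd, axis=0).fillna(0.0)

    Z = rng.normal(size=(n_genes, len(lines)))
    n_cis = min(config.n_cis_genes, n_genes)
    cis_idx = rng.choice(n_genes, size=n_cis, replace=False)
    rho_p = pearson_for_spearman(config.cis_corr)
    Z[cis_idx] = rho_p * Zp.to_numpy()[cis_idx] + np.sqrt(1 - rho_p**2) * Z[cis_idx]
    cis_genes = [genes[i] for i in sorted(cis_idx)]

    arms = [ARM_LABELS[i % len(ARM_LABELS)] for i in range(n_genes)]

    hotspot_pairs: list[tuple[str, str]] = []
    if trans_hotspot is not None:
        cis_set = set(cis_genes)
        candidates = [g for g in genes if g not in cis_set]
        feats = rng.choice(candidates, size=trans_hotspot.n_pairs, replace=False)
        rho_h = pearson_for_spearman(trans_hotspot.rho)
        for j, feat in enumerate(feats):
            gname = f"HOT{j + 1:03d}"
            z = rho_h * Zp.loc[feat].to_numpy() + np.sqrt(1 - rho_h**2) * rng.normal(
                size=len(lines)
            )
            Z = np.vstack([Z, z[None, :]])
            genes.append(gname)
            arms.append(trans_hotspot.arm)
            hotspot_pairs.append((gname, str(feat)))

    vals = np.clip(1.0 + 0.25 * Z, 0.0, None)
    cna = CNAMatrix(
        values=pd.DataFrame(vals, index=pd.Index(genes, name="gene"), columns=lines),
        arms=pd.Series(arms, index=genes, name="arm"),
    )
    truth = GroundTruth(cis_genes=cis_genes, hotspot_pairs=hotspot_pairs)
    return cna, truth
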