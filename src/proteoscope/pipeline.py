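"""End-to-end pipeline orchestration.

``run_pipeline`` executes the stages in dependency order on synthetic
inputs — simulate, proteome prep, glyco quantification, kinase analysis,
RPPA comparison, CNA association, report — writing every stage's outputs
as TSV plus a JSON manifest recording the config hash, seed, thresholds
and per-stage row counts. Reruns with the same config are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cna as cna_mod
from . import glyco, io, kinase, prep, rppa
from .matrices import ConfigError
from .synthetic import (
    GroundTruth,
    SimConfig,
    simulate_cna,
    simulate_glyco_psms,
    simulate_ks_map,
    simulate_panel,
    simulate_phospho,
    simulate_proteome,
    simulate_rppa,
)

log = logging.getLogger("proteoscope")

STAGES = (
    "simulate",
    "proteome_prep",
    "glyco_quant",
    "kinase_activity",
    "crossplatform_rppa",
    "cna_assoc",
    "report",
)


@dataclass
class PipelineConfig:
    """Thresholds and run parameters for one pipeline execution.

    Defaults are the study's stated constants: 5% detection, localization
    > 0.75, 1.5-fold driver rule with a 50% replicate floor, KSEA FDR 0.05
    with > 5 substrates, DE |log2FC| > 2 at Bonferroni-adjusted 0.05.
    """

    seed: int = 0
    out_dir: str = "proteoscope_run"
    detection_min_frac: float = 0.05
    localization_cutoff: float = 0.75
    driver_fold: float = 1.5
    driver_floor_frac: float = 0.5
    ksea_min_substrates: int = 5
    fdr_alpha: float = 0.05
    de_fc_threshold: float = 2.0
    sim: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.detection_min_frac <= 1:
            raise ConfigError("detection_min_frac must lie in (0, 1]")
        if not 0 <= self.localization_cutoff <= 1:
            raise ConfigError("localization_cutoff must lie in [0, 1]")
        if self.driver_fold < 1:
            raise ConfigError("driver_fold must be >= 1")
        if not 0 <= self.driver_floor_frac <= 1:
            raise ConfigError("driver_floor_frac must lie in [0, 1]")
        if not 0 < self.fdr_alpha < 1:
            raise ConfigError("fdr_alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def sim_config(self) -> SimConfig:
        return SimConfig(seed=self.seed, **self.sim)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on synthetic data; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "thresholds": {
            "detection_min_frac": config.detection_min_frac,
            "localization_cutoff": config.localization_cutoff,
            "driver_fold": config.driver_fold,
            "driver_floor_frac": config.driver_floor_frac,
            "ksea_min_substrates": config.ksea_min_substrates,
            "fdr_alpha": config.fdr_alpha,
            "de_fc_threshold": config.de_fc_threshold,
        },
        "stages": {},
    }

    def stage(name):
        def deco(fn):
            log.info("stage %s", name)
            try:
                counts = fn()
            except Exception as exc:  # noqa: BLE001 - reraise with stage context
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"][name] = counts
            return counts

        return deco

    sim = config.sim_config()
    state: dict = {}

    @stage("simulate")
    def _simulate():
        proteome, truth_p = simulate_proteome(sim)
        ks_map = simulate_ks_map(sim)
        phospho = simulate_phospho(sim, ks_map)
        psms, truth_g = simulate_glyco_psms(sim)
        panel = simulate_panel(
            proteome,
            sim,
            n_antibodies=min(231, max(10, len(proteome.features) // 2)),
            n_phospho=min(74, max(2, len(proteome.features) // 10)),
            n_absent=min(19, max(1, len(proteome.features) // 20)),
        )
        rppa_m, truth_r = simulate_rppa(proteome, panel, sim)
        state.update(
            proteome=proteome, ks_map=ks_map, phospho=phospho, psms=psms,
            panel=panel, rppa=rppa_m,
            truth={"proteome": truth_p, "glyco": truth_g, "rppa": truth_r},
        )
        io.write_abundance(proteome, out / "proteome_raw.tsv")
        io.write_table(psms, out / "glyco_psms.tsv")
        io.write_table(ks_map.to_frame(), out / "kinase_substrate_map.tsv")
        io.write_table(panel, out / "rppa_panel.tsv")
        io.write_abundance(rppa_m, out / "rppa_rawlog2.tsv")
        return {
            "proteome_features": len(proteome.features),
            "phosphosites": len(phospho.matrix.features),
            "psm_rows": len(psms),
            "panel_antibodies": len(panel),
        }

    @stage("proteome_prep")
    def _prep():
        filtered, dropped = prep.filter_low_detection(
            state["proteome"], config.detection_min_frac
        )
        imputed = prep.impute_global_min(filtered)
        normalized = prep.log2p1_median_normalize(imputed)
        collapsed = prep.collapse_replicates(normalized)
        state.update(prot_norm=normalized, prot_collapsed=collapsed)
        io.write_abundance(collapsed, out / "proteome_collapsed.tsv")
        return {"kept_features": len(collapsed.features), "dropped": len(dropped)}

    @stage("glyco_quant")
    def _glyco():
        table = glyco.aggregate_site_glycans(state["psms"])
        rep_map = state["proteome"].meta
        kept, n_lines = glyco.consistency_filter(table, rep_map)
        fractions = glyco.class_fractions(table)
        state.update(glyco_table=table, glyco_kept=kept)
        io.write_site_glycans(table, out / "site_glycans.tsv")
        fractions.to_csv(out / "glycan_class_fractions.tsv", sep="\t")
        return {
            "site_glycans": table.n_keys,
            "consistent": kept.n_keys,
            "total_psms": table.total_counts(),
        }

    @stage("kinase_activity")
    def _kinase():
        phospho = state["phospho"]
        sites = kinase.filter_localization(
            phospho.sites, config.localization_cutoff
        )
        pmat = phospho.matrix.with_values(phospho.matrix.values.loc[sites.index])
        imputed = prep.impute_global_min(pmat)
        normalized = prep.log2p1_median_normalize(imputed)
        collapsed = prep.collapse_replicates(normalized)
        fc = kinase.per_line_fold_changes(collapsed)
        ksea_res = kinase.ksea_all_lines(
            fc, state["ks_map"], config.ksea_min_substrates, config.fdr_alpha
        )
        summed = kinase.sum_phospho_by_protein(prep.impute_global_min(pmat))
        prot_raw = prep.impute_global_min(
            prep.filter_low_detection(state["proteome"], config.detection_min_frac)[0]
        )
        hits = kinase.screen_driver_kinases(
            prot_raw, summed, config.driver_fold, config.driver_floor_frac
        )
        adjusted, _ = kinase.adjust_phospho_by_protein(collapsed, state["prot_collapsed"])
        state.update(phospho_collapsed=collapsed, phospho_adjusted=adjusted)
        io.write_table(ksea_res, out / "ksea.tsv")
        io.write_table(hits, out / "driver_hits.tsv")
        return {
            "sites_after_localization": len(sites),
            "ksea_rows": len(ksea_res),
            "driver_hits": len(hits),
        }

    @stage("crossplatform_rppa")
    def _rppa():
        normalized = rppa.rppa_normalize(state["rppa"])
        coverage = rppa.detection_coverage(state["panel"], state["proteome"])
        collapsed = prep.collapse_replicates(normalized)
        mapping = rppa.map_panel(state["panel"], state["prot_collapsed"])
        mapped = mapping.loc[
            mapping["ms_feature"].notna() & ~mapping["is_phospho"].astype(bool)
        ].drop_duplicates("ms_feature")
        rppa_prot = collapsed.with_values(
            collapsed.values.loc[mapped["antibody"]].set_axis(
                mapped["ms_feature"].tolist()
            )
        )
        report = rppa.per_protein_correlation(state["prot_collapsed"], rppa_prot)
        lineages = state["prot_collapsed"].meta.groupby("lineage").groups
        lin_names = sorted(lineages)
        fc_report = rppa.foldchange_concordance(
            state["prot_collapsed"], rppa_prot,
            list(lineages[lin_names[0]]), list(lineages[lin_names[1]]),
        )
        io.write_table(coverage.per_antibody, out / "rppa_coverage.tsv")
        io.write_table(report.per_protein, out / "rppa_correlation.tsv")
        return {
            "coverage": coverage.counts.to_dict(),
            "median_r": report.summary["median_r"],
            "fc_spearman": fc_report.summary["fc_spearman"],
        }

    @stage("cna_assoc")
    def _cna():
        cna_matrix, truth_c = simulate_cna(sim, state["prot_collapsed"])
        corr = cna_mod.cna_feature_correlation(
            cna_matrix, state["prot_collapsed"],
        )
        summary = cna_mod.cis_trans_summary(corr)
        io.write_cna(cna_matrix, out / "cna.tsv")
        io.write_table(corr, out / "cna_correlations.tsv")
        io.write_table(summary, out / "cna_summary.tsv")
        return {"cis_pairs": int(corr["cis"].sum()), "genes": len(cna_matrix.genes)}

    @stage("report")
    def _report():
        return {"stages_completed": len(manifest["stages"])}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
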