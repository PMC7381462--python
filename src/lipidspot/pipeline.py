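"""End-to-end pipeline orchestration and the reproducible run manifest.

``run_pipeline`` sequences: simulate (or load) two cohorts → ppm matching →
four QC filters + TIC normalization + per-cohort mean centering → per-
lipoprotein random-forest panel discovery in the plasma-like cohort →
translation and retraining in the DBS-like cohort → per-lipid GLM
associations with Bonferroni control and cross-cohort concordance →
clinical/quartile stratification with permutation chance baselines. Every
random draw flows from named seeds derived from the single config seed, and
all artifacts are written as text (TSV/JSON) with checksums recorded in the
manifest.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as lio
from .crosscohort import PanelValidator, TranslationRecord
from .panel import PanelGrower, RFConfig, SplitSpec
from .qc import FilterReport, run_qc_pipeline
from .simulate import (
    DBS_COHORT,
    LIPOPROTEINS,
    PLASMA_COHORT,
    Cohort,
    CohortSpec,
    make_paired_cohorts,
)
from .spectra import Role, build_matrix, match_spectra
from .stratify import (
    DEFAULT_CUTOFFS,
    assign_clinical,
    assign_quartiles,
    chance_baseline,
    overlap_table,
)
from .univariate import apply_bonferroni, concordance, glm_per_lipid, results_frame

logger = logging.getLogger("lipidspot")

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "default_config"]


@dataclass
class PipelineConfig:
    """Everything a reproducible run needs, loadable from YAML."""

    seed: int = 0
    discovery: CohortSpec = field(default_factory=lambda: replace(PLASMA_COHORT))
    validation: CohortSpec = field(default_factory=lambda: replace(DBS_COHORT))
    panel_dropout: list[str] = field(default_factory=list)
    window_ppm: float = 10.0
    qc_enabled: bool = True
    max_ppm: float = 5.0
    min_blank_ratio: float = 5.0
    max_zero_frac: float = 0.10
    min_qc_r: float = 0.9
    train_fraction: float = 0.70
    tolerance: float = 0.01
    stop_on: str = "test"
    max_panel: int | None = None
    rf: RFConfig = field(default_factory=RFConfig)
    n_reps_chance: int = 1000
    bonferroni_n_override: int | None = None
    write_spectra: bool = False

    def with_seed(self, seed: int) -> "PipelineConfig":
        cfg = replace(
            self,
            seed=seed,
            discovery=replace(self.discovery, seed=seed),
            validation=replace(self.validation, seed=seed + 1000),
            rf=replace(self.rf, seed=seed + 2000),
        )
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, default in (("discovery", PLASMA_COHORT), ("validation", DBS_COHORT)):
            if key in d and isinstance(d[key], dict):
                base = asdict(default)
                base.update(d[key])
                d[key] = CohortSpec(**base)
        if "rf" in d and isinstance(d["rf"], dict):
            base = asdict(RFConfig())
            base.update(d["rf"])
            d["rf"] = RFConfig(**base)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> Path:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
        return Path(path)


def default_config(seed: int = 0, demo: bool = False) -> PipelineConfig:
    """Full-scale study configuration, or a small fast demo (n=200/220)."""
    cfg = PipelineConfig().with_seed(seed)
    if demo:
        cfg = replace(
            cfg,
            discovery=replace(cfg.discovery, n_subjects=200, n_lipids_detectable=80),
            validation=replace(cfg.validation, n_subjects=220, n_lipids_detectable=60),
            rf=replace(cfg.rf, n_estimators=120),
            n_reps_chance=300,
        )
    return cfg


@dataclass
class RunManifest:
    """Auditable record of one pipeline run."""

    config: dict
    version: str
    seeds: dict
    counts: dict = field(default_factory=dict)
    filter_reports: dict = field(default_factory=dict)
    panel_models: dict = field(default_factory=dict)
    translations: dict = field(default_factory=dict)
    univariate: dict = field(default_factory=dict)
    overlap_tables: dict = field(default_factory=dict)
    chance: dict = field(default_factory=dict)
    checksums: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _cohort_matrices(cohort: Cohort, window_ppm: float):
    signals = match_spectra(cohort.spectra, cohort.library, window_ppm)
    roles = cohort.roles
    samples = build_matrix(signals, roles, Role.SAMPLE, cohort.cohort_id)
    blanks = build_matrix(signals, roles, Role.BLANK, cohort.cohort_id)
    qc = build_matrix(
        signals, roles, {Role.QC100, Role.QC50, Role.QC25}, cohort.cohort_id
    )
    return samples, blanks, qc


def process_cohort(cohort: Cohort, cfg: PipelineConfig):
    """Match and QC-filter one cohort; returns (processed matrix, report)."""
    samples, blanks, qc = _cohort_matrices(cohort, cfg.window_ppm)
    logger.info(
        "%s: matched %d samples x %d lipids (%d blanks, %d QC spectra)",
        cohort.cohort_id, len(samples.samples), len(samples.lipids),
        len(blanks.samples), len(qc.samples),
    )
    processed, report = run_qc_pipeline(
        samples,
        blanks,
        qc,
        max_ppm=cfg.max_ppm,
        min_blank_ratio=cfg.min_blank_ratio,
        max_zero_frac=cfg.max_zero_frac,
        min_qc_r=cfg.min_qc_r,
        enabled=cfg.qc_enabled,
    )
    logger.info(
        "%s: %d lipids passed quality control", cohort.cohort_id, len(processed.lipids)
    )
    return processed, report


def run_pipeline(cfg: PipelineConfig, outdir: str | Path | None = None) -> RunManifest:
    from . import __version__

    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    seeds = {
        "config": cfg.seed,
        "discovery_cohort": cfg.discovery.seed,
        "validation_cohort": cfg.validation.seed,
        "rf": cfg.rf.seed,
        "discovery_split": cfg.seed + 3000,
        "validation_split": cfg.seed + 4000,
        "chance": cfg.seed + 5000,
    }
    manifest = RunManifest(config=cfg.to_dict(), version=__version__, seeds=seeds)

    # --- simulate ---------------------------------------------------------
    discovery, validation = make_paired_cohorts(
        cfg.discovery, cfg.validation, cfg.panel_dropout
    )
    manifest.counts["discovery_subjects"] = len(discovery.clinical)
    manifest.counts["validation_subjects"] = len(validation.clinical)
    manifest.counts["library_size"] = len(discovery.library)
    shared = set(discovery.detectable) & set(validation.detectable)
    manifest.counts["detectable_shared"] = len(shared)

    # --- match + QC -------------------------------------------------------
    matrices: dict[str, object] = {}
    reports: dict[str, FilterReport] = {}
    for cohort in (discovery, validation):
        processed, report = process_cohort(cohort, cfg)
        matrices[cohort.cohort_id] = processed
        reports[cohort.cohort_id] = report
        manifest.filter_reports[cohort.cohort_id] = report.to_frame().to_dict("records")
        manifest.counts[f"{cohort.cohort_id}_lipids_retained"] = len(processed.lipids)

    d_mat = matrices[discovery.cohort_id]
    v_mat = matrices[validation.cohort_id]
    d_clin = discovery.clinical.loc[d_mat.samples]
    v_clin = validation.clinical.loc[v_mat.samples]

    # --- panel discovery + translation ------------------------------------
    panels: dict[str, PanelGrower] = {}
    translations: dict[str, TranslationRecord] = {}
    for t_i, target in enumerate(LIPOPROTEINS):
        grower = PanelGrower(
            tolerance=cfg.tolerance,
            split=SplitSpec(cfg.train_fraction, seeds["discovery_split"] + t_i),
            rf_config=replace(cfg.rf, seed=cfg.rf.seed + t_i),
            stop_on=cfg.stop_on,
            max_panel=cfg.max_panel,
            target_name=target,
        )
        grower.fit(d_mat.intensities, d_clin[target])
        panels[target] = grower
        manifest.panel_models[target] = grower.panel_model_.summary()
        logger.info(
            "%s panel: %d lipids, test r=%.3f (all-lipid r=%.3f)",
            target, len(grower.panel_), grower.test_r_ or float("nan"),
            grower.all_lipid_test_r_ or float("nan"),
        )
        validator = PanelValidator(
            split=SplitSpec(cfg.train_fraction, seeds["validation_split"] + t_i),
            rf_config=replace(cfg.rf, seed=cfg.rf.seed + 100 + t_i),
        )
        rec = validator.run(
            grower.panel_model_, v_mat.intensities, v_clin[target], target_name=target
        )
        translations[target] = rec
        manifest.translations[target] = {
            "lipids_used": rec.lipids_used,
            "lipids_missing_in_target": rec.lipids_missing_in_target,
            "training_msr": rec.target_model.training_msr,
            "test_r": rec.target_model.test_r,
            "test_p": rec.target_model.test_p,
        }
        logger.info(
            "%s translated: %d/%d lipids, validation test r=%.3f",
            target, len(rec.lipids_used), len(rec.source_panel),
            rec.target_model.test_r or float("nan"),
        )

    # --- univariate associations + concordance ----------------------------
    uni = {}
    pooled_src, pooled_tgt = [], []
    for target in LIPOPROTEINS:
        res_d = glm_per_lipid(
            d_mat.intensities, d_clin[target], target, discovery.cohort_id
        )
        res_v = glm_per_lipid(
            v_mat.intensities, v_clin[target], target, validation.cohort_id
        )
        n_d = cfg.bonferroni_n_override or len(res_d)
        n_v = cfg.bonferroni_n_override or len(res_v)
        thr_d = apply_bonferroni(res_d, n_d)
        thr_v = apply_bonferroni(res_v, n_v)
        r_conc, shared_lipids, unshared = concordance(res_d, res_v)
        uni[target] = {
            "threshold_discovery": thr_d,
            "threshold_validation": thr_v,
            "n_pass_discovery": sum(bool(r.passes_bonferroni) for r in res_d),
            "n_pass_validation": sum(bool(r.passes_bonferroni) for r in res_v),
            "concordance_r": r_conc,
            "n_shared": len(shared_lipids),
        }
        if outdir is not None:
            results_frame(res_d + res_v).to_csv(
                outdir / f"univariate_{target}.tsv", sep="\t", index=False
            )
        # panel-lipid associations measured in both cohorts, pooled across targets
        corr_d = {r.lipid: r.correlation for r in res_d}
        corr_v = {r.lipid: r.correlation for r in res_v}
        for lip in translations[target].lipids_used:
            if lip in corr_d and lip in corr_v:
                pooled_src.append(corr_d[lip])
                pooled_tgt.append(corr_v[lip])
    if len(pooled_src) >= 3 and np.std(pooled_src) > 0 and np.std(pooled_tgt) > 0:
        uni["panel_concordance_r"] = float(np.corrcoef(pooled_src, pooled_tgt)[0, 1])
        uni["panel_concordance_n"] = len(pooled_src)
    manifest.univariate = uni

    # --- stratification ----------------------------------------------------
    for target in LIPOPROTEINS:
        g = panels[target]
        test_idx = g.test_idx_
        measured = d_clin[target].to_numpy()[test_idx]
        predicted = g.model_.predict(d_mat.intensities.iloc[test_idx][g.panel_])
        m_lab = assign_clinical(measured, target)
        p_lab = assign_clinical(np.maximum(predicted, 1e-6), target)
        tab = overlap_table(
            m_lab, p_lab, categories=["Desirable", "Borderline", "Poor"], scheme="clinical"
        )
        manifest.overlap_tables[f"{target}_clinical_discovery"] = {
            "counts": tab.counts,
            "denominators": tab.denominators,
            "percentages": tab.percentages,
            "total_accuracy": tab.total_accuracy,
        }

        rec = translations[target]
        v_test = rec.extras["test_idx"]
        v_measured = v_clin[target].to_numpy()[v_test]
        v_predicted = rec.extras["forest"].predict(
            v_mat.intensities.iloc[v_test][rec.lipids_used]
        )
        tab_q = overlap_table(
            assign_quartiles(v_measured),
            assign_quartiles(v_predicted),
            categories=["Q1", "Q2", "Q3", "Q4"],
            scheme="quartile",
        )
        manifest.overlap_tables[f"{target}_quartile_validation"] = {
            "counts": tab_q.counts,
            "denominators": tab_q.denominators,
            "percentages": tab_q.percentages,
            "total_accuracy": tab_q.total_accuracy,
        }
    mean_pct, ci = chance_baseline(
        n=len(v_clin), n_categories=4, n_reps=cfg.n_reps_chance, seed=seeds["chance"]
    )
    manifest.chance = {"quartile_pct": mean_pct, "ci95": list(ci)}

    # --- artifacts ---------------------------------------------------------
    if outdir is not None:
        lio.write_library(discovery.library, outdir / "library.tsv")
        lio.write_clinical(discovery.clinical, outdir / "clinical_discovery.tsv")
        lio.write_clinical(validation.clinical, outdir / "clinical_validation.tsv")
        lio.write_matrix(d_mat, outdir / "matrix_discovery")
        lio.write_matrix(v_mat, outdir / "matrix_validation")
        if cfg.write_spectra:
            lio.write_spectra(discovery.spectra, outdir / "spectra_discovery")
            lio.write_spectra(validation.spectra, outdir / "spectra_validation")
        for fp in sorted(outdir.glob("*.tsv")):
            manifest.checksums[fp.name] = _checksum(fp)
        for fp in sorted(outdir.glob("matrix_*.tsv")):
            manifest.checksums[fp.name] = _checksum(fp)
        lio.write_json(manifest.to_dict(), outdir / "run_manifest.json")
    return manifest
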