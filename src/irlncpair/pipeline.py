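"""End-to-end orchestration with a config file, seeding and a run manifest.

A run executes: (simulate or read inputs) -> merge -> batch adjust ->
biotype partition -> irlncRNA co-expression screen -> differential
expression -> pair construction + valid-match filter -> univariate screen +
lasso Cox -> risk scores -> ROC/Youden stratification -> evaluation
(log-rank, prognostic independence, clinical / drug / immune contrasts).

Every stage's output is persisted under the run directory and the manifest
records the config hash, the seed and per-stage row counts, so that two
runs with identical config and seed produce byte-identical manifests.  All
randomness (simulation, CV folds) derives from the single top-level seed.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as _io
from . import coexpression, diffexpr, evaluate, pairs, preprocess, signature, stratify
from .errors import ConfigError, IrlncpairError, PipelineStageError
from .synthetic import SimulationConfig, simulate_expression, simulate_survival, simulate_drug_scores, immune_cell_gene_sets

logger = logging.getLogger("irlncpair")


@dataclass
class PipelineConfig:
    """Flat-key configuration of one pipeline run."""

    seed: int = 0
    simulate: bool = True
    sim: dict = field(default_factory=dict)  # SimulationConfig overrides
    # input paths, used when simulate is False
    expression: str | None = None
    sample_labels: str | None = None
    annotation: str | None = None
    immune_genes: str | None = None
    clinical: str | None = None
    drug_scores: str | None = None
    gene_sets: str | None = None
    # thresholds (defaults follow the published screen except FDR, see diffexpr)
    corr_min: float = coexpression.R_MIN_DEFAULT
    corr_p: float = coexpression.P_MAX_DEFAULT
    corr_absolute: bool = False
    log2fc: float = diffexpr.FC_MIN_DEFAULT
    fdr: float = diffexpr.FDR_MAX_DEFAULT
    valid_low: float = pairs.VALID_LOW_DEFAULT
    valid_high: float = pairs.VALID_HIGH_DEFAULT
    screen_p: float = signature.SCREEN_P_DEFAULT
    folds: int = signature.K_FOLDS_DEFAULT
    lambda_rule: str = "min"
    horizons: tuple[float, ...] = stratify.HORIZONS_DEFAULT
    batch_adjust: bool = True
    plots: bool = False

    def validate(self) -> None:
        if not (0 <= self.valid_low < self.valid_high <= 1):
            raise ConfigError(
                f"need 0 <= valid_low < valid_high <= 1, got ({self.valid_low}, {self.valid_high})"
            )
        if not (0 < self.corr_p <= 1) or not (0 < self.fdr <= 1):
            raise ConfigError("corr_p and fdr must lie in (0, 1]")
        if not (0 < self.screen_p <= 1):
            raise ConfigError("screen_p must lie in (0, 1]")
        if self.folds < 2:
            raise ConfigError("folds must be >= 2")
        if not self.horizons:
            raise ConfigError("at least one horizon required")
        if not self.simulate:
            required = ("expression", "annotation", "immune_genes", "clinical")
            missing = [k for k in required if getattr(self, k) is None]
            if missing:
                raise ConfigError(f"simulate=false requires input paths: {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.horizons, list):
            cfg.horizons = tuple(float(h) for h in cfg.horizons)
        return cfg

    def canonical_json(self) -> str:
        d = asdict(self)
        d["horizons"] = list(self.horizons)
        return json.dumps(d, sort_keys=True)

    def hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def _simulation_config(cfg: PipelineConfig) -> SimulationConfig:
    kwargs = dict(cfg.sim)
    if "pair_betas" in kwargs:
        kwargs["pair_betas"] = tuple(kwargs["pair_betas"])
    kwargs.setdefault("seed", cfg.seed)
    return SimulationConfig(**kwargs)


def run_pipeline(config: PipelineConfig | str | Path, out_dir: str | Path) -> dict:
    """Execute every stage, persist artifacts, return (and write) the manifest."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "config": json.loads(config.canonical_json()),
        "stages": {},
    }

    def record(stage: str, **counts) -> None:
        manifest["stages"][stage] = counts
        logger.info("stage %-12s %s", stage, counts)

    def fail(stage: str, exc: Exception):
        _write_manifest(manifest, out)  # retain partial outputs + manifest
        raise PipelineStageError(stage, str(exc)) from exc

    # ---- inputs ---------------------------------------------------------
    truth = None
    try:
        if config.simulate:
            sim_cfg = _simulation_config(config)
            expr, ann, immune_genes, truth = simulate_expression(sim_cfg)
            gsc = immune_cell_gene_sets(immune_genes)
            drug_table = None  # built after survival below
        else:
            expr = _io.read_expression_matrix(
                config.expression, labels_path=config.sample_labels
            )
            ann = _io.read_gtf_annotation(config.annotation)
            immune_genes = _io.read_gene_list(config.immune_genes)
            gsc = _io.read_gmt(config.gene_sets) if config.gene_sets else None
            drug_table = (
                _io.read_drug_scores(config.drug_scores) if config.drug_scores else None
            )
        record("input", n_genes=expr.n_genes, n_samples=expr.n_samples,
               n_immune_genes=len(immune_genes))
    except IrlncpairError as exc:
        fail("input", exc)

    # ---- preprocess -----------------------------------------------------
    try:
        if config.batch_adjust:
            expr = preprocess.batch_adjust(expr)
        mrna, lnc = preprocess.partition_by_biotype(expr, ann)
        record("preprocess", n_mrna=mrna.n_genes, n_lnc=lnc.n_genes,
               batch_adjusted=bool(config.batch_adjust))
    except IrlncpairError as exc:
        fail("preprocess", exc)

    # ---- irlncRNA extraction -------------------------------------------
    try:
        immune_present = [g for g in immune_genes if g in set(mrna.gene_ids)]
        if not immune_present:
            raise ConfigError("no immune gene found in the mRNA matrix")
        irlnc_ids, corr = coexpression.extract_irlncrnas(
            mrna.values.loc[immune_present],
            lnc.values,
            r_min=config.corr_min,
            p_max=config.corr_p,
            absolute=config.corr_absolute,
        )
        coexpression.write_correlations(corr, out / "correlations.tsv")
        _io.write_gene_list(sorted(irlnc_ids), out / "irlncRNAs.txt")
        record("extract", n_irlnc=len(irlnc_ids), n_correlations=len(corr))
        if not irlnc_ids:
            raise ConfigError("correlation screen retained no lncRNAs")
    except IrlncpairError as exc:
        fail("extract", exc)

    # ---- differential expression ---------------------------------------
    try:
        de_res = diffexpr.de_table(lnc, genes=sorted(irlnc_ids))
        diffexpr.write_de_table(de_res, out / "de_table.tsv")
        de_ids = diffexpr.select_deirlncrnas(de_res, fc_min=config.log2fc, fdr_max=config.fdr)
        _io.write_gene_list(de_ids, out / "DEirlncRNAs.txt")
        n_up = int((de_res.loc[de_ids, "direction"] == diffexpr.UP).sum())
        record("de", n_de=len(de_ids), n_up=n_up, n_down=len(de_ids) - n_up)
    except IrlncpairError as exc:
        fail("de", exc)

    # ---- survival inputs ------------------------------------------------
    try:
        if config.simulate:
            pair_genes = sorted({g for p in truth.planted_pairs for g in p})
            pm_truth = pairs.build_pair_matrix(expr.values.loc[pair_genes], expr.tumor_samples())
            surv = simulate_survival(pm_truth, truth, sim_cfg)
            drug_table = simulate_drug_scores(truth, expr.tumor_samples(), sim_cfg)
            _io.write_clinical_table(surv, out / "clinical.tsv")
            truth.to_json(out / "ground_truth.json")
        else:
            surv = _io.read_clinical_table(config.clinical)
        record("survival", n_subjects=len(surv.sample_ids), n_events=int(surv.event.sum()))
    except IrlncpairError as exc:
        fail("survival", exc)

    # ---- pair features --------------------------------------------------
    try:
        modelling = [s for s in lnc.tumor_samples() if s in set(surv.sample_ids)]
        if not modelling:
            raise ConfigError("no tumor sample with survival data")
        pm = pairs.build_pair_matrix(lnc.values.loc[de_ids], modelling)
        pm = pairs.filter_valid_pairs(pm, low=config.valid_low, high=config.valid_high)
        pairs.write_pair_matrix(pm, out / "pair_matrix.tsv")
        record("pairs", n_candidate=len(de_ids) * (len(de_ids) - 1) // 2,
               n_valid=pm.n_pairs, n_samples=len(modelling))
    except IrlncpairError as exc:
        fail("pairs", exc)

    # ---- signature ------------------------------------------------------
    try:
        surv_model = surv.subset(modelling)
        pm_screened, fits = signature.screen_pairs(pm, surv_model, p_max=config.screen_p)
        model = signature.fit_lasso_cox(
            pm_screened, surv_model, k_folds=config.folds, seed=config.seed,
            lambda_rule=config.lambda_rule,
        )
        model.to_json(out / "signature_model.json")
        scores = signature.compute_risk_score(model, pm)
        signature.write_risk_scores(scores, out / "risk_scores.tsv")
        record("fit", n_screened=pm_screened.n_pairs, n_signature=len(model.pair_names))
    except IrlncpairError as exc:
        fail("fit", exc)

    # ---- stratification -------------------------------------------------
    try:
        strat, roc = stratify.stratify_samples(scores, surv_model, horizons=config.horizons)
        stratify.write_stratification(strat, out / "stratification.tsv")
        roc.table().to_csv(out / f"roc_{int(roc.horizon)}d.tsv", sep="\t", index=False,
                           float_format="%.6g")
        record("stratify", horizon=float(roc.horizon), auc=round(float(roc.auc), 6),
               cutoff=round(float(strat.cutoff), 6),
               n_high=len(strat.high_samples), n_low=len(strat.low_samples))
    except IrlncpairError as exc:
        fail("stratify", exc)

    # ---- evaluation -----------------------------------------------------
    try:
        lr = evaluate.logrank_test(strat, surv_model)
        km_rows = []
        for grp, ids in (("high", strat.high_samples), ("low", strat.low_samples)):
            km = evaluate.km_estimate(surv_model.subset(ids))
            km_rows.append(pd.DataFrame({
                "group": grp, "time": km.times, "survival": km.survival,
                "at_risk": km.at_risk,
            }))
        pd.concat(km_rows).to_csv(out / "km_curves.tsv", sep="\t", index=False,
                                  float_format="%.6g")

        cov = evaluate.encode_clinical(surv_model)
        cov["risk_score"] = scores.reindex(cov.index)
        cov = cov.drop(columns=[c for c in cov.columns if cov[c].dropna().nunique() < 2])
        mv = evaluate.multivariate_cox(surv_model, cov)
        mv_df = pd.DataFrame([vars(f) for f in mv])
        mv_df.to_csv(out / "multivariate_cox.tsv", sep="\t", index=False,
                     float_format="%.6g")

        clin_vals = evaluate.encode_clinical(surv_model)
        clin_vals["vital_dead"] = (surv_model.data["vital"] == "Dead").astype(float)
        contrasts = evaluate.contrast_table(
            pd.DataFrame({"risk_score": scores.reindex(clin_vals.index)}).join(clin_vals),
            strat,
        )
        contrasts.to_csv(out / "clinical_contrasts.tsv", sep="\t", index=False,
                         float_format="%.6g")

        n_drug = n_sets = 0
        if drug_table is not None:
            drug_contrasts = evaluate.contrast_table(
                drug_table.scores.reindex(scores.index), strat
            )
            drug_contrasts.to_csv(out / "drug_contrasts.tsv", sep="\t", index=False,
                                  float_format="%.6g")
            n_drug = len(drug_contrasts)
        if gsc is not None:
            tumor_mrna = mrna.subset(samples=modelling)
            enr = evaluate.ssgsea_scores(tumor_mrna.values, gsc)
            enr.to_csv(out / "immune_enrichment.tsv", sep="\t", float_format="%.6g")
            immune_contrasts = evaluate.contrast_table(enr, strat)
            immune_contrasts.to_csv(out / "immune_contrasts.tsv", sep="\t", index=False,
                                    float_format="%.6g")
            n_sets = enr.shape[1]

        risk_fit = next(f for f in mv if f.covariate == "risk_score")
        record("evaluate", logrank_p=float(f"{lr.p:.6g}"),
               risk_hr=round(risk_fit.hr, 6), n_drug_contrasts=n_drug,
               n_immune_sets=n_sets)
        if config.plots:
            from . import plots
            plots.km_plot(surv_model, strat, out / "km_curves.png")
    except IrlncpairError as exc:
        fail("evaluate", exc)

    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
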