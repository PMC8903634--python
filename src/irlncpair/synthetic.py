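"""Synthetic two-cohort transcriptome + survival generator with planted structure.

The generator emulates the statistical structure the pipeline is designed to
detect, without any external downloads:

* a single latent per-sample immune activity factor drives co-expression
  between a curated immune-gene panel and a planted subset of lncRNAs
  (the "immune-related" lncRNAs);
* a subset of those irlncRNAs receives an additive tumor-only log2 shift
  (the differential-expression signal);
* survival follows a proportional-hazards model whose log-hazard is a linear
  combination of planted binary pair features (within-sample expression
  comparisons of planted differentially expressed genes), with exponential
  baseline hazard and uniform administrative censoring.

Everything is deterministic given the config seed.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from . import io as _io
from .io import (
    DrugScoreTable,
    ExpressionMatrix,
    GeneAnnotation,
    GeneSetCollection,
    SurvivalTable,
    LNCRNA,
    NORMAL,
    PROTEIN_CODING,
    TUMOR,
)

logger = logging.getLogger("irlncpair")

#: drugs written into the synthetic IC50 table with their per-unit-risk effect
#: on the (log) IC50-like score; positive = higher score (less sensitive) in
#: high-risk patients, as observed for conventional ovarian-cancer agents.
DRUG_EFFECTS = {
    "cisplatin": 0.6,
    "paclitaxel": 0.4,
    "olaparib": 0.3,
    "vinblastine": 0.5,
    "camptothecin": 0.6,
    "docetaxel": 0.15,
}

IMMUNE_CELL_TYPES = (
    "B_cells",
    "T_cells_CD4",
    "T_cells_CD8",
    "NK_cells",
    "neutrophils",
    "macrophages",
    "mast_cells",
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort (defaults = desk-scale study conditions)."""

    n_normal: int = 60
    n_tumor: int = 300
    n_mrna: int = 500
    n_immune: int = 100
    n_lnc: int = 300
    n_irlnc: int = 40
    n_de: int = 20
    de_shift: float = 3.0  # log2 units added to DE genes in tumor samples
    n_planted_pairs: int = 5
    pair_betas: tuple[float, ...] = (0.8, 0.8, 0.8, 0.8, 0.8)
    baseline_hazard: float = 2e-4  # events per day at zero risk score
    censor_max: float = 3650.0  # days; censoring ~ Uniform(0, censor_max)
    batch_shifts: dict = field(default_factory=lambda: {"A": 0.0, "B": 1.0})
    noise_sd: float = 0.5  # log2 units
    immune_loading: float = 1.0  # latent-factor loading of immune genes
    lnc_loading: float = 1.0  # latent-factor loading of planted irlncRNAs
    seed: int = 0

    def validate(self) -> None:
        counts = dict(
            n_normal=self.n_normal,
            n_tumor=self.n_tumor,
            n_mrna=self.n_mrna,
            n_immune=self.n_immune,
            n_lnc=self.n_lnc,
            n_irlnc=self.n_irlnc,
            n_de=self.n_de,
            n_planted_pairs=self.n_planted_pairs,
        )
        for name, v in counts.items():
            if int(v) <= 0:
                raise ConfigError(f"{name} must be positive, got {v}")
        if self.n_immune > self.n_mrna:
            raise ConfigError("n_immune must be <= n_mrna")
        if not (self.n_de <= self.n_irlnc <= self.n_lnc):
            raise ConfigError("need n_de <= n_irlnc <= n_lnc")
        if 2 * self.n_planted_pairs > self.n_de:
            raise ConfigError("need n_de >= 2 * n_planted_pairs (pairs use disjoint genes)")
        if len(self.pair_betas) != self.n_planted_pairs:
            raise ConfigError("pair_betas length must equal n_planted_pairs")
        if not all(np.isfinite(self.pair_betas)):
            raise ConfigError("pair_betas must be finite")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if self.baseline_hazard <= 0 or self.censor_max <= 0:
            raise ConfigError("baseline_hazard and censor_max must be > 0")
        if not self.batch_shifts:
            raise ConfigError("batch_shifts must name at least one batch")


@dataclass
class GroundTruth:
    """Planted structure of one simulated cohort."""

    irlnc_ids: list[str]
    de_ids: list[str]
    planted_pairs: list[tuple[str, str]]
    betas: list[float]
    latent_factor: pd.Series | None = None  # per-sample immune activity f
    latent_risk: pd.Series | None = None  # per-sample linear predictor (set by survival sim)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "irlnc_ids": self.irlnc_ids,
            "de_ids": self.de_ids,
            "planted_pairs": [list(p) for p in self.planted_pairs],
            "betas": self.betas,
            "latent_risk": None
            if self.latent_risk is None
            else {k: float(v) for k, v in self.latent_risk.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        risk = d.get("latent_risk")
        return cls(
            irlnc_ids=d["irlnc_ids"],
            de_ids=d["de_ids"],
            planted_pairs=[tuple(p) for p in d["planted_pairs"]],
            betas=d["betas"],
            latent_risk=None if risk is None else pd.Series(risk),
        )


def _gene_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(1, n + 1)]


def simulate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, GeneAnnotation, list[str], GroundTruth]:
    """Simulate the merged normal+tumor expression matrix with planted structure.

    Returns the merged :class:`ExpressionMatrix`, a matching annotation
    (mRNAs protein_coding, lncRNAs lncRNA-class), the immune gene list
    (a subset of the mRNAs) and the :class:`GroundTruth` bookkeeping object.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])

    normal_ids = [f"NORM{i:04d}" for i in range(1, config.n_normal + 1)]
    tumor_ids = [f"TUM{i:04d}" for i in range(1, config.n_tumor + 1)]
    samples = normal_ids + tumor_ids
    n_samples = len(samples)
    cohort = pd.Series([NORMAL] * config.n_normal + [TUMOR] * config.n_tumor, index=samples)
    # balanced batch assignment within each cohort, cycling over batch labels
    batch_names = sorted(config.batch_shifts)
    batch = pd.Series(
        [batch_names[i % len(batch_names)] for i in range(config.n_normal)]
        + [batch_names[i % len(batch_names)] for i in range(config.n_tumor)],
        index=samples,
    )

    mrna_ids = _gene_ids("MRNA", config.n_mrna)
    lnc_ids = _gene_ids("LNC", config.n_lnc)
    immune_ids = mrna_ids[: config.n_immune]
    irlnc_ids = lnc_ids[: config.n_irlnc]
    de_ids = irlnc_ids[: config.n_de]
    planted_pairs = [
        (de_ids[2 * k], de_ids[2 * k + 1]) for k in range(config.n_planted_pairs)
    ]

    f = rng.standard_normal(n_samples)  # latent immune activity per sample

    mu_mrna = rng.uniform(2.0, 8.0, size=config.n_mrna)
    mu_lnc = rng.uniform(2.0, 8.0, size=config.n_lnc)
    # genes of one planted pair share a mean so the pair indicator is ~Bernoulli(1/2)
    for a, b in planted_pairs:
        mu_lnc[lnc_ids.index(b)] = mu_lnc[lnc_ids.index(a)]

    sd = config.noise_sd
    X_mrna = mu_mrna[:, None] + rng.normal(0.0, sd, size=(config.n_mrna, n_samples))
    X_mrna[: config.n_immune] += config.immune_loading * f[None, :]

    X_lnc = mu_lnc[:, None] + rng.normal(0.0, sd, size=(config.n_lnc, n_samples))
    X_lnc[: config.n_irlnc] += config.lnc_loading * f[None, :]
    # non-planted lncRNAs: independent noise, variance matched to the planted ones
    extra_sd = config.lnc_loading
    X_lnc[config.n_irlnc:] += rng.normal(
        0.0, extra_sd, size=(config.n_lnc - config.n_irlnc, n_samples)
    )

    is_tumor = (cohort == TUMOR).to_numpy()
    X_lnc[: config.n_de, is_tumor] += config.de_shift

    values = pd.DataFrame(
        np.vstack([X_mrna, X_lnc]), index=mrna_ids + lnc_ids, columns=samples
    )
    for name, shift in config.batch_shifts.items():
        values.loc[:, (batch == name).to_numpy()] += float(shift)

    ann = GeneAnnotation(
        pd.DataFrame(
            {
                "symbol": mrna_ids + lnc_ids,
                "biotype": [PROTEIN_CODING] * config.n_mrna + [LNCRNA] * config.n_lnc,
            },
            index=mrna_ids + lnc_ids,
        )
    )
    truth = GroundTruth(
        irlnc_ids=list(irlnc_ids),
        de_ids=list(de_ids),
        planted_pairs=planted_pairs,
        betas=list(config.pair_betas),
        latent_factor=pd.Series(f, index=samples),
    )
    return ExpressionMatrix(values, cohort, batch), ann, list(immune_ids), truth


#: fixed sampling frequencies for the synthetic clinical covariates
_GRADE_LEVELS = (("G1", 0.05), ("G2", 0.15), ("G3", 0.55), ("G4", 0.25))
_STAGE_LEVELS = (("I", 0.05), ("II", 0.10), ("III", 0.55), ("IV", 0.30))
_RESIDUAL_LEVELS = (("R0", 0.40), ("R1", 0.60))


def _sample_categorical(rng: np.random.Generator, levels, n: int) -> np.ndarray:
    names = [x[0] for x in levels]
    probs = np.array([x[1] for x in levels])
    return rng.choice(names, size=n, p=probs / probs.sum())


def simulate_survival(pair_matrix, truth: GroundTruth, config: SimulationConfig) -> SurvivalTable:
    """Draw survival outcomes whose hazard depends on the planted pair features.

    Event times are exponential with rate ``baseline_hazard * exp(sum_k beta_k
    x_ik)`` where ``x_ik`` is the binary value of planted pair *k* in sample
    *i*, taken from ``pair_matrix``.  Censoring times are Uniform(0,
    censor_max); observed time is the minimum (floored at 0.5 days), event = 1
    iff the event came first.  Clinical covariates are drawn from fixed
    frequency tables; vital status mirrors the event indicator.
    """
    config.validate()
    from .pairs import pair_name  # local import to avoid a cycle

    wanted = [pair_name(a, b) for a, b in truth.planted_pairs]
    missing = [p for p in wanted if p not in pair_matrix.values.columns]
    if missing:
        raise ConfigError(f"planted pair(s) missing from pair matrix: {missing}")

    rng = np.random.default_rng([config.seed, 1])
    samples = list(pair_matrix.values.index)
    X = pair_matrix.values[wanted].to_numpy(dtype=float)
    lp = X @ np.asarray(truth.betas, dtype=float)
    rate = config.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    t_censor = rng.uniform(0.0, config.censor_max, size=len(samples))
    time = np.maximum(np.minimum(t_event, t_censor), 0.5)
    event = (t_event <= t_censor).astype(int)

    n = len(samples)
    df = pd.DataFrame(
        {
            "time": time,
            "event": event,
            "age": np.round(rng.normal(60.0, 10.0, size=n)),
            "grade": _sample_categorical(rng, _GRADE_LEVELS, n),
            "stage": _sample_categorical(rng, _STAGE_LEVELS, n),
            "residual": _sample_categorical(rng, _RESIDUAL_LEVELS, n),
            "vital": np.where(event == 1, "Dead", "Alive"),
        },
        index=pd.Index(samples, name="sample_id"),
    )
    truth.latent_risk = pd.Series(lp, index=samples)
    return SurvivalTable(df)


def simulate_drug_scores(
    truth: GroundTruth, samples: list[str], config: SimulationConfig
) -> DrugScoreTable:
    """IC50-like scores: drug-specific baseline + effect * latent risk + noise."""
    if truth.latent_risk is None:
        raise ConfigError("simulate_survival must run before drug scores (latent risk unset)")
    rng = np.random.default_rng([config.seed, 2])
    lp = truth.latent_risk.reindex(samples).to_numpy()
    cols = {}
    for i, (drug, effect) in enumerate(DRUG_EFFECTS.items()):
        base = rng.uniform(1.0, 4.0)
        cols[drug] = base + effect * lp + rng.normal(0.0, 0.5, size=len(samples))
    return DrugScoreTable(pd.DataFrame(cols, index=pd.Index(samples, name="sample_id")))


def immune_cell_gene_sets(immune_genes: list[str]) -> GeneSetCollection:
    """Partition the immune panel into disjoint synthetic immune-cell signatures."""
    n_types = len(IMMUNE_CELL_TYPES)
    chunks = np.array_split(np.asarray(immune_genes, dtype=object), n_types)
    sets = {name: list(chunk) for name, chunk in zip(IMMUNE_CELL_TYPES, chunks) if len(chunk)}
    return GeneSetCollection(sets, {name: "synthetic immune-cell signature" for name in sets})


def generate_fixture_bundle(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write a complete, reader-compatible input bundle plus ground truth JSON.

    Files written: expression.tsv + sample_labels.tsv, annotation.gtf,
    immune_genes.txt, clinical.tsv, drug_scores.tsv, immune_cell_sets.gmt,
    ground_truth.json.  Deterministic (byte-identical) under a fixed seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    expr, ann, immune, truth = simulate_expression(config)

    # planted pair features are observable comparisons of the simulated values
    from .pairs import build_pair_matrix

    tumor = expr.tumor_samples()
    pair_genes = sorted({g for p in truth.planted_pairs for g in p})
    pm = build_pair_matrix(expr.values.loc[pair_genes], tumor)
    surv = simulate_survival(pm, truth, config)
    drugs = simulate_drug_scores(truth, tumor, config)
    gsc = immune_cell_gene_sets(immune)

    paths = {
        "expression": out / "expression.tsv",
        "sample_labels": out / "sample_labels.tsv",
        "annotation": out / "annotation.gtf",
        "immune_genes": out / "immune_genes.txt",
        "clinical": out / "clinical.tsv",
        "drug_scores": out / "drug_scores.tsv",
        "gene_sets": out / "immune_cell_sets.gmt",
        "ground_truth": out / "ground_truth.json",
    }
    _io.write_expression_matrix(expr, paths["expression"], paths["sample_labels"])
    _io.write_gtf_annotation(ann, paths["annotation"])
    _io.write_gene_list(immune, paths["immune_genes"])
    _io.write_clinical_table(surv, paths["clinical"])
    _io.write_drug_scores(drugs, paths["drug_scores"])
    _io.write_gmt(gsc, paths["gene_sets"])
    truth.to_json(paths["ground_truth"])
    logger.info("fixture bundle written to %s (%d files)", out, len(paths))
    return paths
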