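"""Time-dependent ROC, horizon selection, Youden cutoff, risk groups.

The ROC at horizon t uses the cumulative-case / dynamic-control definition:
cases are subjects with an event by t, controls are subjects still event-free
past t.  Censoring is handled by Kaplan-Meier weighting of the subgroup
survival above each score threshold (the classic product-limit-based
estimator of time-dependent sensitivity/specificity).  That estimator is not
guaranteed monotone under heavy censoring, so the raw curves are isotonized
(running max/min along descending thresholds); without censoring it reduces
exactly to empirical fractions and the AUC equals the Mann-Whitney statistic
of the binary status indicator.

The stratification cutoff maximizes the Youden index J = sensitivity +
specificity - 1 at the horizon with the largest AUC among 1/3/5 years
(ties toward the longest horizon); samples with score strictly above the
cutoff form the high-risk group.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import km_survival_at
from .errors import DegenerateFitError, FormatError
from .io import SurvivalTable

logger = logging.getLogger("irlncpair")

HORIZONS_DEFAULT = (365.0, 1095.0, 1825.0)

HIGH = "high"
LOW = "low"


@dataclass
class TimeROC:
    """ROC curve at one horizon: thresholds (descending), sens/spec, AUC."""

    horizon: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        for name in ("thresholds", "sensitivity", "specificity"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError(f"AUC out of range: {self.auc}")

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


@dataclass
class RiskStratification:
    """Risk scores with the chosen horizon, cutoff and group assignment."""

    scores: pd.Series
    horizon: float | None
    cutoff: float
    group: pd.Series  # sample_id -> "high" | "low"

    def __post_init__(self) -> None:
        counts = self.group.value_counts()
        if counts.get(HIGH, 0) == 0 or counts.get(LOW, 0) == 0:
            raise DegenerateFitError("both risk groups must be non-empty")

    @property
    def high_samples(self) -> list[str]:
        return list(self.group.index[self.group == HIGH])

    @property
    def low_samples(self) -> list[str]:
        return list(self.group.index[self.group == LOW])

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({"risk_score": self.scores, "group": self.group})


def _align(scores: pd.Series, surv: SurvivalTable):
    common = [s for s in scores.index if s in set(surv.sample_ids)]
    if not common:
        raise ValueError("scores and survival table share no samples")
    return (
        scores.loc[common].to_numpy(dtype=float),
        surv.time.loc[common].to_numpy(dtype=float),
        surv.event.loc[common].to_numpy(dtype=int),
    )


def time_dependent_roc(scores: pd.Series, surv: SurvivalTable, horizon: float) -> TimeROC:
    """Cumulative/dynamic time-dependent ROC with KM-weighted censoring handling."""
    s, time, event = _align(scores, surv)
    n_cases = int(((time <= horizon) & (event == 1)).sum())
    n_controls = int((time > horizon).sum())
    if n_cases == 0 or n_controls == 0:
        raise DegenerateFitError(
            f"horizon {horizon:g}: need >= 1 case and >= 1 control "
            f"(got {n_cases} cases, {n_controls} controls)"
        )

    surv_all = km_survival_at(time, event, horizon)
    if not (0.0 < surv_all < 1.0):
        raise DegenerateFitError(f"horizon {horizon:g}: degenerate overall survival {surv_all}")

    thresholds = np.unique(s)[::-1]  # descending
    sens = np.empty(len(thresholds))
    spec = np.empty(len(thresholds))
    for i, c in enumerate(thresholds):
        mask = s > c
        p_c = mask.mean()
        if p_c == 0.0:
            sens[i], spec[i] = 0.0, 1.0
            continue
        s_c = km_survival_at(time[mask], event[mask], horizon)
        sens[i] = (1.0 - s_c) * p_c / (1.0 - surv_all)
        spec[i] = 1.0 - s_c * p_c / surv_all
    sens = np.clip(sens, 0.0, 1.0)
    spec = np.clip(spec, 0.0, 1.0)
    # isotonize: sens non-decreasing, spec non-increasing as thresholds descend
    sens = np.maximum.accumulate(sens)
    spec = np.minimum.accumulate(spec)

    fpr = np.concatenate([[0.0], 1.0 - spec, [1.0]])
    tpr = np.concatenate([[0.0], sens, [1.0]])
    auc = float(np.trapezoid(tpr, fpr))
    return TimeROC(horizon, thresholds, sens, spec, min(max(auc, 0.0), 1.0))


def select_horizon(
    scores: pd.Series,
    surv: SurvivalTable,
    horizons: tuple[float, ...] = HORIZONS_DEFAULT,
) -> tuple[float, TimeROC]:
    """Return the horizon with the maximal AUC (ties toward the longest).

    Horizons that cannot be computed (no cases or no controls) are skipped
    with a warning; all-incomputable raises.
    """
    best: tuple[float, TimeROC] | None = None
    for h in horizons:
        try:
            roc = time_dependent_roc(scores, surv, h)
        except DegenerateFitError as exc:
            logger.warning("horizon %g skipped: %s", h, exc)
            continue
        if best is None or roc.auc > best[1].auc or (
            roc.auc == best[1].auc and h > best[0]
        ):
            best = (h, roc)
    if best is None:
        raise DegenerateFitError("no horizon admits a time-dependent ROC")
    logger.info("selected horizon %g days (AUC %.3f)", best[0], best[1].auc)
    return best


def youden_cutoff(roc: TimeROC) -> float:
    """Score threshold maximizing J = sensitivity + specificity - 1.

    Ties break toward the lower threshold (the larger high-risk group).  A
    flat curve (J = 0 everywhere) falls back to the median observed score
    with a warning.
    """
    j = roc.sensitivity + roc.specificity - 1.0
    if np.all(j <= 0.0):
        logger.warning("Youden index flat at 0; falling back to the median score")
        return float(np.median(roc.thresholds))
    best_j = j.max()
    # thresholds are descending; the last argmax is the lowest tied threshold
    idx = np.where(j == best_j)[0][-1]
    return float(roc.thresholds[idx])


def assign_groups(
    scores: pd.Series, cutoff: float, horizon: float | None = None
) -> RiskStratification:
    """High-risk iff score > cutoff (strict); errors when a group is empty."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    group = pd.Series(np.where(scores > cutoff, HIGH, LOW), index=scores.index, name="group")
    counts = group.value_counts()
    logger.info(
        "risk groups at cutoff %.4g: high=%d, low=%d",
        cutoff,
        counts.get(HIGH, 0),
        counts.get(LOW, 0),
    )
    return RiskStratification(scores=scores, horizon=horizon, cutoff=cutoff, group=group)


def stratify_samples(
    scores: pd.Series,
    surv: SurvivalTable,
    horizons: tuple[float, ...] = HORIZONS_DEFAULT,
) -> tuple[RiskStratification, TimeROC]:
    """Full stratification: best-AUC horizon, Youden cutoff, group assignment."""
    horizon, roc = select_horizon(scores, surv, horizons)
    cutoff = youden_cutoff(roc)
    strat = assign_groups(scores, cutoff, horizon)
    return strat, roc


def write_stratification(strat: RiskStratification, path) -> None:
    df = strat.table()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.10g")
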