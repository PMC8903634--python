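"""Penalized Cox signature: univariate screen, lasso with CV, risk scores.

The modelling chain is the one used throughout pair-signature studies:
(1) each candidate pair feature is screened with a univariate Cox
proportional-hazards fit and a Wald test; (2) survivors enter an
L1-penalized Cox model whose penalty weight is chosen by k-fold
cross-validated partial-likelihood deviance; (3) the per-sample risk score
is the linear predictor sum(beta_n * x_n) over the selected pairs, with x_n
the binary pair value.

Unpenalized fits are delegated to lifelines; the lasso path to
scikit-survival's coxnet.  Held-out deviance is computed with the Breslow
partial log-likelihood in :mod:`irlncpair._stats`.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from sklearn.model_selection import StratifiedKFold
from sksurv.linear_model import CoxnetSurvivalAnalysis

from ._stats import breslow_partial_loglik
from .errors import DegenerateFitError, NonConvergenceError, FormatError
from .io import SurvivalTable
from .pairs import PairMatrix

logger = logging.getLogger("irlncpair")

SCREEN_P_DEFAULT = 0.05
K_FOLDS_DEFAULT = 10


@dataclass(frozen=True)
class CoxFit:
    """One covariate's Cox fit: coefficient, Wald inference, hazard ratio."""

    covariate: str
    beta: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    n_events: int


@dataclass
class SignatureModel:
    """Selected pair features with their lasso-Cox coefficients."""

    pair_names: list[str]
    betas: np.ndarray
    lambda_: float
    cv: dict = field(default_factory=dict)  # folds, seed, lambda path, mean deviance

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        if len(self.pair_names) != len(self.betas):
            raise ValueError("pair_names and betas length mismatch")
        if np.any(self.betas == 0):
            raise ValueError("SignatureModel stores only nonzero coefficients")
        if self.lambda_ < 0:
            raise ValueError("lambda must be >= 0")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "pairs": self.pair_names,
            "betas": [float(b) for b in self.betas],
            "lambda": float(self.lambda_),
            "cv": {
                k: (list(map(float, v)) if isinstance(v, (list, np.ndarray)) else v)
                for k, v in self.cv.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SignatureModel":
        d = json.loads(Path(path).read_text())
        return cls(d["pairs"], np.asarray(d["betas"]), d["lambda"], d.get("cv", {}))


def _aligned(pm: PairMatrix, surv: SurvivalTable) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    common = [s for s in pm.sample_ids if s in set(surv.sample_ids)]
    if not common:
        raise ValueError("pair matrix and survival table share no samples")
    X = pm.values.loc[common].astype(float)
    t = surv.time.loc[common]
    e = surv.event.loc[common]
    return X, t, e


def univariate_cox(x: pd.Series, surv: SurvivalTable) -> CoxFit:
    """Univariate Cox PH fit of one covariate with Wald se/CI/p.

    Raises :class:`DegenerateFitError` for constant covariates or <2 events,
    :class:`NonConvergenceError` when the partial likelihood is monotone
    (e.g. perfect separation).
    """
    name = str(x.name) if x.name is not None else "x"
    common = [s for s in x.index if s in set(surv.sample_ids)]
    df = pd.DataFrame(
        {
            "time": surv.time.loc[common],
            "event": surv.event.loc[common],
            name: x.loc[common].astype(float),
        }
    )
    n_events = int(df["event"].sum())
    if n_events < 2:
        raise DegenerateFitError(f"{name}: need >= 2 events, got {n_events}")
    if df[name].nunique() < 2:
        raise DegenerateFitError(f"{name}: covariate is constant")
    cph = CoxPHFitter()
    try:
        # tight Newton tolerance: downstream oracles compare at 1e-4
        cph.fit(df, duration_col="time", event_col="event",
                fit_options={"precision": 1e-9})
    except ConvergenceError as exc:
        raise NonConvergenceError(
            f"{name}: Cox fit did not converge (monotone likelihood / separation?): {exc}"
        ) from exc
    s = cph.summary.loc[name]
    return CoxFit(
        covariate=name,
        beta=float(s["coef"]),
        se=float(s["se(coef)"]),
        hr=float(s["exp(coef)"]),
        ci_low=float(np.exp(s["coef lower 95%"])),
        ci_high=float(np.exp(s["coef upper 95%"])),
        p=float(s["p"]),
        n=len(df),
        n_events=n_events,
    )


def screen_pairs(
    pm: PairMatrix, surv: SurvivalTable, p_max: float = SCREEN_P_DEFAULT
) -> tuple[PairMatrix, dict[str, CoxFit]]:
    """Keep pairs whose univariate Cox Wald p is < p_max.

    Degenerate or non-converging fits are dropped with a warning.  Returns
    the filtered matrix and the per-pair fits of the survivors.
    """
    if not 0 < p_max <= 1:
        raise ValueError(f"p_max must lie in (0, 1], got {p_max}")
    kept: dict[str, CoxFit] = {}
    n_degenerate = 0
    for name in pm.pair_names:
        try:
            fit = univariate_cox(pm.values[name], surv)
        except (DegenerateFitError, NonConvergenceError) as exc:
            n_degenerate += 1
            logger.warning("screen: dropping pair %s (%s)", name, exc)
            continue
        if fit.p < p_max:
            kept[name] = fit
    if n_degenerate:
        logger.warning("screen: %d pairs dropped for degenerate fits", n_degenerate)
    if not kept:
        raise DegenerateFitError(f"no pair passes the univariate screen at p < {p_max}")
    logger.info("univariate screen: %d/%d pairs pass at p < %g", len(kept), pm.n_pairs, p_max)
    return pm.subset(pairs=list(kept)), kept


def _cv_deviance(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    alphas: np.ndarray,
    k_folds: int,
    seed: int,
) -> np.ndarray:
    """Mean held-out deviance (-2 * Breslow partial log-lik) per penalty weight."""
    from sksurv.util import Surv

    k_eff = min(k_folds, int(event.sum()), int((1 - event).sum()) or k_folds)
    if k_eff < 2:
        raise DegenerateFitError("too few events for cross-validation")
    if k_eff < k_folds:
        logger.warning("cross-validation: reducing folds %d -> %d", k_folds, k_eff)
    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    dev = np.zeros((k_eff, len(alphas)))
    for f, (tr, te) in enumerate(skf.split(X, event)):
        y_tr = Surv.from_arrays(event=event[tr].astype(bool), time=time[tr])
        model = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, alphas=alphas, fit_baseline_model=False
        )
        model.fit(X[tr], y_tr)
        fitted = np.asarray(model.alphas_)
        coefs = model.coef_  # p x n_alphas
        for a_idx, alpha in enumerate(alphas):
            j = int(np.argmin(np.abs(fitted - alpha)))
            lp = X[te] @ coefs[:, j]
            dev[f, a_idx] = -2.0 * breslow_partial_loglik(lp, time[te], event[te])
    return dev.mean(axis=0), dev.std(axis=0, ddof=1) / np.sqrt(k_eff)


def lasso_path(
    pm: PairMatrix,
    surv: SurvivalTable,
    alphas: np.ndarray | list[float] | None = None,
    n_alphas: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Coefficient path of the L1-penalized Cox model.

    Returns ``(alphas, coefs)`` with ``coefs`` of shape (n_features,
    n_alphas), alphas descending.  When ``alphas`` is None the solver picks
    its own descending sequence.
    """
    from sksurv.util import Surv

    X_df, t, e = _aligned(pm, surv)
    y = Surv.from_arrays(event=e.to_numpy(dtype=bool), time=t.to_numpy(dtype=float))
    kwargs = {"alphas": list(alphas)} if alphas is not None else {"n_alphas": n_alphas}
    model = CoxnetSurvivalAnalysis(l1_ratio=1.0, fit_baseline_model=False, **kwargs)
    model.fit(X_df.to_numpy(dtype=float), y)
    return np.asarray(model.alphas_), np.asarray(model.coef_)


def fit_lasso_cox(
    pm: PairMatrix,
    surv: SurvivalTable,
    k_folds: int = K_FOLDS_DEFAULT,
    seed: int = 0,
    lambda_rule: str = "min",
    n_alphas: int = 100,
    alphas: np.ndarray | list[float] | None = None,
) -> SignatureModel:
    """L1-penalized Cox fit with the penalty chosen by cross-validation.

    The lasso path is fit by coordinate descent over a descending sequence of
    penalty weights; the weight minimizing the mean k-fold held-out
    partial-likelihood deviance is selected (``lambda_rule="1se"`` picks the
    sparsest model within one standard error of the minimum).  Folds are
    stratified by event status and seeded.  Raises when the selected model
    has no nonzero coefficient.
    """
    from sksurv.util import Surv

    if lambda_rule not in ("min", "1se"):
        raise ValueError("lambda_rule must be 'min' or '1se'")
    X_df, t, e = _aligned(pm, surv)
    X = X_df.to_numpy(dtype=float)
    time = t.to_numpy(dtype=float)
    event = e.to_numpy(dtype=int)
    if event.sum() < 2:
        raise DegenerateFitError("need >= 2 events to fit the lasso Cox model")
    if X.shape[1] < 1:
        raise DegenerateFitError("need >= 1 feature")

    y = Surv.from_arrays(event=event.astype(bool), time=time)
    if alphas is None:
        path = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, n_alphas=n_alphas, fit_baseline_model=False
        )
        path.fit(X, y)
        alphas = np.asarray(path.alphas_)
    else:
        alphas = np.asarray(sorted(alphas, reverse=True), dtype=float)

    if len(alphas) == 1:
        mean_dev, se_dev = np.zeros(1), np.zeros(1)
    else:
        mean_dev, se_dev = _cv_deviance(X, time, event, alphas, k_folds, seed)
    i_min = int(np.argmin(mean_dev))
    if lambda_rule == "1se":
        # alphas are descending: the sparsest acceptable model is the largest alpha
        ok = np.where(mean_dev <= mean_dev[i_min] + se_dev[i_min])[0]
        i_sel = int(ok[0])
    else:
        i_sel = i_min
    alpha_sel = float(alphas[i_sel])

    final = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, alphas=[alpha_sel], fit_baseline_model=False
    )
    final.fit(X, y)
    coefs = np.asarray(final.coef_)[:, 0]
    nz = np.nonzero(coefs)[0]
    if nz.size == 0:
        raise DegenerateFitError(
            f"lasso at lambda={alpha_sel:.4g} selected no pairs; extend the penalty path"
        )
    model = SignatureModel(
        pair_names=[X_df.columns[i] for i in nz],
        betas=coefs[nz],
        lambda_=alpha_sel,
        cv={
            "folds": int(min(k_folds, len(mean_dev))),
            "seed": int(seed),
            "lambda_path": alphas.tolist(),
            "mean_deviance": mean_dev.tolist(),
            "lambda_rule": lambda_rule,
        },
    )
    logger.info(
        "lasso Cox: lambda=%.4g selects %d/%d pairs", alpha_sel, nz.size, X.shape[1]
    )
    return model


def compute_risk_score(model: SignatureModel, pm: PairMatrix) -> pd.Series:
    """Per-sample risk score sum(beta_n * x_n) over the signature pairs."""
    missing = [p for p in model.pair_names if p not in pm.values.columns]
    if missing:
        raise FormatError(f"pair matrix lacks signature pair(s): {missing}")
    X = pm.values[model.pair_names].to_numpy(dtype=float)
    scores = pd.Series(X @ model.betas, index=pm.values.index, name="risk_score")
    if not np.isfinite(scores).all():
        raise ValueError("non-finite risk scores")
    return scores


def write_risk_scores(scores: pd.Series, path: str | Path) -> None:
    df = scores.rename("risk_score").to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_risk_scores(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df["risk_score"].astype(float)
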