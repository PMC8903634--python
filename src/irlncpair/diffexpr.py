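"""Tumor-vs-normal differential expression of irlncRNAs.

Group location difference is reported as log2 fold change on the already
log2-scaled values (mean tumor minus mean normal); significance comes from
the Wilcoxon rank-sum test and multiplicity is controlled with
Benjamini-Hochberg FDR across the screened irlncRNA family.  Defaults follow
|log2FC| > 2 with FDR < 0.05.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._stats import ranksum_p
from .errors import FormatError
from .io import ExpressionMatrix, TUMOR, NORMAL

logger = logging.getLogger("irlncpair")

FC_MIN_DEFAULT = 2.0
FDR_MAX_DEFAULT = 0.05

UP = "up"
DOWN = "down"


@dataclass(frozen=True)
class DEResult:
    """Differential-expression record for one gene."""

    gene: str
    log2fc: float
    p: float
    fdr: float

    @property
    def direction(self) -> str:
        return UP if self.log2fc > 0 else DOWN


def two_group_test(tumor: np.ndarray, normal: np.ndarray) -> tuple[float, float]:
    """log2 fold change (mean difference of log2 values) and Wilcoxon p.

    Exact rank-sum enumeration when both groups have n <= 12 and the pooled
    values are tie-free; otherwise the normal approximation with tie and
    continuity correction.
    """
    tumor = np.asarray(tumor, dtype=float)
    normal = np.asarray(normal, dtype=float)
    if tumor.size < 2 or normal.size < 2:
        raise ValueError("two_group_test requires >= 2 samples per group")
    log2fc = float(tumor.mean() - normal.mean())
    _, p = ranksum_p(tumor, normal)
    return log2fc, p


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_table(lnc_expr: ExpressionMatrix, genes: list[str] | None = None) -> pd.DataFrame:
    """Per-gene DE results over the tumor/normal cohorts of ``lnc_expr``.

    Returns a DataFrame indexed by gene with columns log2fc, p, fdr,
    direction; FDR is computed across all tested genes (the screened family).
    """
    m = lnc_expr if genes is None else lnc_expr.subset(genes=genes)
    tumor_cols = m.cohort == TUMOR
    normal_cols = m.cohort == NORMAL
    if tumor_cols.sum() < 2 or normal_cols.sum() < 2:
        raise ValueError("differential expression requires >= 2 samples per cohort")
    Xt = m.values.loc[:, tumor_cols.to_numpy()].to_numpy()
    Xn = m.values.loc[:, normal_cols.to_numpy()].to_numpy()

    log2fc = Xt.mean(axis=1) - Xn.mean(axis=1)
    pvals = np.array([ranksum_p(Xt[i], Xn[i])[1] for i in range(Xt.shape[0])])
    fdr = bh_adjust(pvals)
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": pvals,
            "fdr": fdr,
            "direction": np.where(log2fc > 0, UP, DOWN),
        },
        index=pd.Index(m.values.index, name="gene"),
    )
    return out


def select_deirlncrnas(
    results: pd.DataFrame,
    fc_min: float = FC_MIN_DEFAULT,
    fdr_max: float = FDR_MAX_DEFAULT,
) -> list[str]:
    """Retain genes with |log2fc| > fc_min and fdr < fdr_max (two-sided filter).

    Raises when the selection is empty, with advice to relax thresholds.
    Up/down counts are logged, mirroring how such signatures are reported.
    """
    keep = results[(results["log2fc"].abs() > fc_min) & (results["fdr"] < fdr_max)]
    if keep.empty:
        raise FormatError(
            f"no genes pass |log2FC| > {fc_min} and FDR < {fdr_max}; "
            "consider relaxing the thresholds"
        )
    n_up = int((keep["direction"] == UP).sum())
    n_down = int((keep["direction"] == DOWN).sum())
    logger.info("DE selection: %d genes (%d up, %d down)", len(keep), n_up, n_down)
    return list(keep.index)


def write_de_table(results: pd.DataFrame, path: str | Path) -> None:
    results.to_csv(path, sep="\t", float_format="%.6g")
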