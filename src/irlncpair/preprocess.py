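"""Cohort merging, simplified batch adjustment, and biotype partition.

Batch adjustment is a per-gene location-scale correction: within each batch
the gene is standardized, then rescaled to the gene's grand mean and pooled
within-batch standard deviation.  This removes additive and multiplicative
batch effects exactly on simulated data; it deliberately does not attempt
empirical-Bayes shrinkage across genes.  Tumor/normal status is never used
as a covariate here — batches confounded with cohort (>95% one cohort) are
detected and flagged instead.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import FormatError
from .io import ExpressionMatrix, GeneAnnotation, LNCRNA, PROTEIN_CODING, OTHER

logger = logging.getLogger("irlncpair")

#: a batch is flagged as cohort-confounded when more than this fraction of
#: its samples carry a single cohort label
CONFOUNDING_FRACTION = 0.95


def merge_cohorts(matrices: list[ExpressionMatrix]) -> ExpressionMatrix:
    """Column-concatenate matrices over an identical gene set.

    Gene order follows the first input; later matrices are realigned to it.
    Sample ids must be disjoint across inputs.
    """
    if not matrices:
        raise ValueError("merge_cohorts needs at least one matrix")
    first = matrices[0]
    ref_genes = first.values.index
    ref_set = set(ref_genes)
    for m in matrices[1:]:
        other = set(m.values.index)
        if other != ref_set:
            diff = len(ref_set.symmetric_difference(other))
            raise FormatError(
                f"gene sets differ between matrices (symmetric difference: {diff} genes)"
            )
    seen: set[str] = set()
    for m in matrices:
        overlap = seen.intersection(m.values.columns)
        if overlap:
            raise FormatError(f"duplicate sample id(s) across matrices: {sorted(overlap)[:5]}")
        seen.update(m.values.columns)
    values = pd.concat([m.values.reindex(ref_genes) for m in matrices], axis=1)
    cohort = pd.concat([m.cohort for m in matrices])
    batch = pd.concat([m.batch for m in matrices])
    return ExpressionMatrix(values, cohort, batch)


def batch_adjust(m: ExpressionMatrix) -> ExpressionMatrix:
    """Location-scale batch correction per gene.

    For every gene and every batch with >=2 samples: subtract the batch mean
    and divide by the batch standard deviation (when positive), then restore
    the gene's grand mean and pooled within-batch standard deviation.  A
    single-batch matrix is returned unchanged; batches with fewer than two
    samples are passed through with a warning.
    """
    batches = m.batch.unique()
    _warn_if_confounded(m)
    if len(batches) < 2:
        logger.warning("batch_adjust: single batch, identity transform")
        return ExpressionMatrix(m.values.copy(), m.cohort.copy(), m.batch.copy())

    X = m.values.to_numpy(dtype=float).copy()
    grand_mean = X.mean(axis=1)

    groups = {b: (m.batch == b).to_numpy() for b in batches}
    adjustable = {b for b, idx in groups.items() if idx.sum() >= 2}
    for b in batches:
        if b not in adjustable:
            logger.warning("batch_adjust: batch %r has <2 samples, passed through", b)

    # pooled within-batch sd over adjustable batches, per gene
    num = np.zeros(X.shape[0])
    den = 0.0
    stats = {}
    for b in adjustable:
        idx = groups[b]
        nb = int(idx.sum())
        mu = X[:, idx].mean(axis=1)
        sd = X[:, idx].std(axis=1, ddof=1)
        stats[b] = (idx, mu, sd)
        num += (nb - 1) * sd**2
        den += nb - 1
    pooled_sd = np.sqrt(num / den) if den > 0 else np.zeros(X.shape[0])

    for b, (idx, mu, sd) in stats.items():
        centered = X[:, idx] - mu[:, None]
        safe = sd > 0
        centered[safe] /= sd[safe, None]
        X[:, idx] = centered * pooled_sd[:, None] + grand_mean[:, None]

    values = pd.DataFrame(X, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(values, m.cohort.copy(), m.batch.copy())


def _warn_if_confounded(m: ExpressionMatrix) -> None:
    for b in m.batch.unique():
        idx = m.batch == b
        frac = m.cohort[idx].value_counts(normalize=True).max()
        if frac > CONFOUNDING_FRACTION:
            logger.warning(
                "batch %r is %.0f%% one cohort: batch adjustment may absorb "
                "tumor/normal differences",
                b,
                100 * frac,
            )


def partition_by_biotype(
    m: ExpressionMatrix, ann: GeneAnnotation
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Split the matrix into (mRNA, lncRNA) submatrices by annotated biotype.

    Genes absent from the annotation are treated as biotype ``other``;
    ``other`` genes are excluded with a logged count.  Raises when no lncRNA
    remains (the pipeline cannot proceed without them); an empty mRNA matrix
    is allowed here and only errors downstream if mRNAs are required.
    """
    biotypes = ann.table["biotype"].reindex(m.values.index).fillna(OTHER)
    n_unannotated = int(ann.table["biotype"].reindex(m.values.index).isna().sum())
    if n_unannotated:
        logger.warning("partition: %d unannotated genes treated as 'other'", n_unannotated)
    coding = list(biotypes.index[biotypes == PROTEIN_CODING])
    lnc = list(biotypes.index[biotypes == LNCRNA])
    n_excluded = int((biotypes == OTHER).sum())
    if n_excluded:
        logger.info("partition: excluded %d genes of biotype 'other'", n_excluded)
    if not lnc:
        raise FormatError("no lncRNA-class genes after biotype partition")
    return m.subset(genes=coding) if coding else _empty_like(m), m.subset(genes=lnc)


def _empty_like(m: ExpressionMatrix) -> ExpressionMatrix:
    values = m.values.iloc[0:0]
    return ExpressionMatrix(values.copy(), m.cohort.copy(), m.batch.copy())
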