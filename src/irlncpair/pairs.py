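"""Rank-based pair features: the 0/1 within-sample comparison matrix.

Every unordered pair {A, B} of differentially expressed irlncRNAs becomes a
binary feature: 1 when A's expression exceeds B's within the sample, 0
otherwise (ties fall to 0).  Because only the within-sample ordering enters,
the features are invariant to any strictly increasing per-sample transform
of the expression values — the property that makes the downstream signature
portable across platforms and normalizations.

Pairs whose ones-fraction across the modelling cohort lies outside
[20%, 80%] are discarded: a comparison that is (almost) constant across
patients cannot carry prognostic information.
"""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError

logger = logging.getLogger("irlncpair")

VALID_LOW_DEFAULT = 0.20
VALID_HIGH_DEFAULT = 0.80

PAIR_SEP = "|"


def pair_name(a: str, b: str) -> str:
    """Canonical pair name: lexicographically smaller gene first."""
    if a == b:
        raise ValueError(f"a pair needs two distinct genes, got {a!r} twice")
    return f"{a}{PAIR_SEP}{b}" if a < b else f"{b}{PAIR_SEP}{a}"


@dataclass(frozen=True)
class PairFeature:
    """An unordered gene pair in canonical (lexicographic) order."""

    lnc_a: str
    lnc_b: str

    def __post_init__(self) -> None:
        if self.lnc_a == self.lnc_b:
            raise ValueError("pair members must differ")
        if not self.lnc_a < self.lnc_b:
            raise ValueError(
                f"pair not in canonical order: {self.lnc_a!r} !< {self.lnc_b!r}"
            )

    @property
    def name(self) -> str:
        return f"{self.lnc_a}{PAIR_SEP}{self.lnc_b}"

    @classmethod
    def from_name(cls, name: str) -> "PairFeature":
        a, sep, b = name.partition(PAIR_SEP)
        if not sep or not a or not b:
            raise ValueError(f"not a pair name: {name!r}")
        return cls(a, b)


@dataclass
class PairMatrix:
    """Samples x pair-features binary matrix."""

    values: pd.DataFrame  # index sample_id, columns pair names, values in {0,1}

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise FormatError("duplicate pair names")
        if self.values.index.duplicated().any():
            raise FormatError("duplicate sample ids")
        arr = self.values.to_numpy()
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise FormatError("pair matrix values must be 0 or 1")
        self.values = self.values.astype(np.int8)

    @property
    def pairs(self) -> list[PairFeature]:
        return [PairFeature.from_name(c) for c in self.values.columns]

    @property
    def pair_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_pairs(self) -> int:
        return self.values.shape[1]

    def subset(self, samples=None, pairs=None) -> "PairMatrix":
        vals = self.values
        if samples is not None:
            vals = vals.loc[list(samples)]
        if pairs is not None:
            missing = set(pairs) - set(vals.columns)
            if missing:
                raise KeyError(f"pairs not in matrix: {sorted(missing)[:5]}")
            vals = vals[list(pairs)]
        return PairMatrix(vals.copy())


def binarize_pair(expr_a: float, expr_b: float) -> int:
    """1 iff expr_a strictly exceeds expr_b; ties and lower values give 0."""
    if not (math.isfinite(expr_a) and math.isfinite(expr_b)):
        raise ValueError("binarize_pair requires finite expression values")
    return 1 if expr_a > expr_b else 0


def build_pair_matrix(expr: pd.DataFrame, samples: list[str] | None = None) -> PairMatrix:
    """All C(k,2) unordered pair columns over the genes of ``expr``.

    ``expr`` is a genes x samples slice restricted to the selected
    (differentially expressed) irlncRNAs; ``samples`` restricts the columns
    (typically the modelling cohort: tumor samples with survival data).
    Values must be finite.  Column order follows lexicographic gene order.
    """
    if samples is not None:
        missing = set(samples) - set(expr.columns)
        if missing:
            raise KeyError(f"samples missing from expression: {sorted(missing)[:5]}")
        expr = expr[list(samples)]
    genes = sorted(expr.index)
    k = len(genes)
    if k < 2:
        raise FormatError(f"pair construction needs >= 2 genes, got {k}")
    X = expr.loc[genes].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("expression slice contains non-finite values")
    ia, ib = np.triu_indices(k, k=1)
    V = (X[ia] > X[ib]).astype(np.int8)  # pairs x samples
    names = [f"{genes[i]}{PAIR_SEP}{genes[j]}" for i, j in zip(ia, ib)]
    values = pd.DataFrame(V.T, index=expr.columns, columns=names)
    values.index.name = "sample_id"
    logger.info("pair matrix: %d genes -> %d candidate pairs x %d samples", k, len(names), len(expr.columns))
    return PairMatrix(values)


def filter_valid_pairs(
    pm: PairMatrix,
    low: float = VALID_LOW_DEFAULT,
    high: float = VALID_HIGH_DEFAULT,
) -> PairMatrix:
    """Keep pairs whose ones-fraction lies in [low, high] (inclusive bounds)."""
    if not 0 <= low < high <= 1:
        raise ValueError(f"need 0 <= low < high <= 1, got ({low}, {high})")
    if pm.n_pairs == 0:
        raise FormatError("empty pair matrix")
    frac = pm.values.mean(axis=0)
    keep = frac[(frac >= low) & (frac <= high)].index
    if len(keep) == 0:
        raise FormatError(
            f"no pair has a ones-fraction within [{low}, {high}]; nothing to model"
        )
    logger.info("valid-match filter: %d/%d pairs kept", len(keep), pm.n_pairs)
    return PairMatrix(pm.values[list(keep)].copy())


def read_pair_matrix(path: str | Path) -> PairMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return PairMatrix(df)


def write_pair_matrix(pm: PairMatrix, path: str | Path) -> None:
    df = pm.values.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")
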