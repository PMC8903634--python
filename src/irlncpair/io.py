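"""Readers and writers for every external format the pipeline touches.

All tables are tab-separated UTF-8 with ``.`` as the decimal mark and no
thousands separators.  Readers validate their input into the domain
containers defined here and raise :class:`~irlncpair.errors.FormatError`
on malformed content instead of propagating raw pandas errors.

Expression values are expected on a log2(count+1)-like scale; the readers
pass values through unchanged and it is the caller's responsibility to
assert the scale of the input data.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from gffutils.feature import feature_from_line

from .errors import FormatError

logger = logging.getLogger("irlncpair")

NORMAL = "normal"
TUMOR = "tumor"

PROTEIN_CODING = "protein_coding"
LNCRNA = "lncRNA"
OTHER = "other"

#: GTF biotypes collapsed into the lncRNA class by default.  Ensembl has used
#: several labels for long non-coding genes across releases; this set covers
#: the common ones and is configurable per call.
DEFAULT_LNC_BIOTYPES = frozenset(
    {
        "lncRNA",
        "lincRNA",
        "antisense",
        "processed_transcript",
        "sense_intronic",
        "sense_overlapping",
    }
)

#: Optional clinical covariates carried alongside time/event.
CLINICAL_COVARIATES = ("age", "grade", "stage", "residual", "vital")


def _check_unique(ids: pd.Index, what: str) -> None:
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].unique()[:5].tolist()
        raise FormatError(f"duplicate {what} id(s): {dup}")


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """log2-scale genes x samples expression with per-sample cohort/batch labels.

    Parameters
    ----------
    values
        Genes (rows) by samples (columns) matrix of finite floats.
    cohort
        Per-sample label, each ``"normal"`` or ``"tumor"``, indexed by sample id.
    batch
        Per-sample opaque batch label, indexed by sample id.
    """

    values: pd.DataFrame
    cohort: pd.Series
    batch: pd.Series

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr.astype(float, copy=False)).all():
            raise FormatError("expression matrix contains non-finite values")
        self.values = self.values.astype(float)
        samples = self.values.columns
        for name, lab in (("cohort", self.cohort), ("batch", self.batch)):
            missing = samples.difference(lab.index)
            if len(missing):
                raise FormatError(f"{name} labels missing for samples: {list(missing[:5])}")
        self.cohort = self.cohort.reindex(samples).astype(str)
        self.batch = self.batch.reindex(samples).astype(str)
        bad = set(self.cohort.unique()) - {NORMAL, TUMOR}
        if bad:
            raise FormatError(f"cohort labels must be 'normal' or 'tumor', got {sorted(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset(
        self,
        genes: Sequence[str] | None = None,
        samples: Sequence[str] | None = None,
    ) -> "ExpressionMatrix":
        """Return a copy restricted to the given genes and/or samples."""
        vals = self.values
        if genes is not None:
            missing = set(genes) - set(vals.index)
            if missing:
                raise KeyError(f"genes not in matrix: {sorted(missing)[:5]}")
            vals = vals.loc[list(genes)]
        if samples is not None:
            missing = set(samples) - set(vals.columns)
            if missing:
                raise KeyError(f"samples not in matrix: {sorted(missing)[:5]}")
            vals = vals[list(samples)]
        return ExpressionMatrix(
            vals.copy(), self.cohort.loc[vals.columns].copy(), self.batch.loc[vals.columns].copy()
        )

    def tumor_samples(self) -> list[str]:
        return list(self.cohort.index[self.cohort == TUMOR])

    def normal_samples(self) -> list[str]:
        return list(self.cohort.index[self.cohort == NORMAL])


@dataclass
class GeneAnnotation:
    """gene_id -> (symbol, biotype class) with a controlled biotype vocabulary.

    Biotype is always one of :data:`PROTEIN_CODING`, :data:`LNCRNA`, :data:`OTHER`.
    """

    table: pd.DataFrame  # index gene_id, columns: symbol, biotype

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "gene")
        for col in ("symbol", "biotype"):
            if col not in self.table.columns:
                raise FormatError(f"annotation table missing column '{col}'")
        bad = set(self.table["biotype"].unique()) - {PROTEIN_CODING, LNCRNA, OTHER}
        if bad:
            raise FormatError(f"unknown biotype class(es): {sorted(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def biotype(self, gene_id: str) -> str:
        return str(self.table.at[gene_id, "biotype"])

    def ids_of_biotype(self, biotype: str) -> list[str]:
        return list(self.table.index[self.table["biotype"] == biotype])


@dataclass
class SurvivalTable:
    """Per-sample follow-up time (days), event indicator and clinical covariates."""

    data: pd.DataFrame  # index sample_id; columns time, event + CLINICAL_COVARIATES

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        for col in ("time", "event"):
            if col not in self.data.columns:
                raise FormatError(f"survival table missing column '{col}'")
            if self.data[col].isna().any():
                raise FormatError(f"survival column '{col}' may not be missing")
        self.data = self.data.copy()
        self.data["time"] = self.data["time"].astype(float)
        if (self.data["time"] <= 0).any():
            raise FormatError("survival times must be strictly positive")
        ev = self.data["event"].astype(float)
        if not np.isin(ev, (0.0, 1.0)).all():
            raise FormatError("event indicator must be 0 or 1")
        self.data["event"] = ev.astype(int)
        for col in CLINICAL_COVARIATES:
            if col not in self.data.columns:
                self.data[col] = np.nan

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def time(self) -> pd.Series:
        return self.data["time"]

    @property
    def event(self) -> pd.Series:
        return self.data["event"]

    def subset(self, samples: Sequence[str]) -> "SurvivalTable":
        missing = set(samples) - set(self.data.index)
        if missing:
            raise KeyError(f"samples not in survival table: {sorted(missing)[:5]}")
        return SurvivalTable(self.data.loc[list(samples)].copy())


@dataclass
class GeneSetCollection:
    """Named gene sets with GMT semantics (set name -> ordered unique gene ids)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise FormatError(f"gene set '{name}' is empty")
            if len(set(genes)) != len(genes):
                raise FormatError(f"gene set '{name}' contains duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class DrugScoreTable:
    """Per-sample, per-drug IC50-like sensitivity scores (lower = more sensitive)."""

    scores: pd.DataFrame  # index sample_id, columns drug names

    def __post_init__(self) -> None:
        _check_unique(self.scores.index, "sample")
        _check_unique(self.scores.columns, "drug")
        arr = self.scores.to_numpy(dtype=float)
        if arr.size and not np.isfinite(arr).all():
            raise FormatError("drug score table contains non-finite values")
        self.scores = self.scores.astype(float)

    @property
    def drugs(self) -> list[str]:
        return list(self.scores.columns)


# ---------------------------------------------------------------------------
# Expression matrix IO
# ---------------------------------------------------------------------------


def _read_numeric_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise FormatError(f"{path}: cannot parse TSV ({exc})") from exc
    if df.empty and df.columns.empty:
        raise FormatError(f"{path}: empty table")
    _check_unique(df.index, "gene")
    _check_unique(df.columns, "sample")
    num = df.apply(pd.to_numeric, errors="coerce")
    bad = num.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}"
        )
    if num.isna().to_numpy().any():
        r, c = np.argwhere(num.isna().to_numpy())[0]
        raise FormatError(f"{path}: missing value at row {df.index[r]!r}, column {df.columns[c]!r}")
    num.index = num.index.astype(str)
    num.columns = num.columns.astype(str)
    return num


def read_expression_matrix(
    path: str | Path,
    cohort_label: str = TUMOR,
    batch_label: str = "batch0",
    labels_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a genes x samples TSV into an :class:`ExpressionMatrix`.

    The file must have a header row of sample ids and gene ids in the first
    column.  By default every sample receives ``cohort_label``/``batch_label``;
    alternatively ``labels_path`` may name a per-sample label TSV (columns
    ``sample_id``, ``cohort``, ``batch``) as written by
    :func:`write_expression_matrix`, which takes precedence.
    """
    values = _read_numeric_table(path)
    samples = values.columns
    if labels_path is not None:
        lab = pd.read_csv(labels_path, sep="\t", dtype=str)
        for col in ("sample_id", "cohort", "batch"):
            if col not in lab.columns:
                raise FormatError(f"{labels_path}: missing required column '{col}'")
        lab = lab.set_index("sample_id")
        cohort = lab["cohort"].reindex(samples)
        batch = lab["batch"].reindex(samples)
    else:
        cohort = pd.Series(cohort_label, index=samples)
        batch = pd.Series(batch_label, index=samples)
    return ExpressionMatrix(values, cohort, batch)


def write_expression_matrix(
    m: ExpressionMatrix, path: str | Path, labels_path: str | Path | None = None
) -> None:
    """Write the value matrix as TSV; optionally a sample-label sidecar TSV."""
    df = m.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.10g")
    if labels_path is not None:
        lab = pd.DataFrame(
            {"sample_id": m.sample_ids, "cohort": m.cohort.values, "batch": m.batch.values}
        )
        lab.to_csv(labels_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GTF annotation
# ---------------------------------------------------------------------------


def read_gtf_annotation(
    path: str | Path, lnc_biotypes: Iterable[str] = DEFAULT_LNC_BIOTYPES
) -> GeneAnnotation:
    """Parse ``gene`` records of an Ensembl-dialect GTF into a :class:`GeneAnnotation`.

    The raw biotype is taken from the ``gene_biotype`` attribute, falling back
    to ``gene_type`` when absent (``gene_biotype`` wins when both are present).
    Raw biotypes in ``lnc_biotypes`` map to the lncRNA class, ``protein_coding``
    stays, everything else (including missing) maps to ``other``.  Records with
    unparsable attribute fields are skipped with a warning.
    """
    lnc_biotypes = set(lnc_biotypes)
    rows: dict[str, tuple[str, str]] = {}
    n_skipped = 0
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "gene":
                continue
            try:
                feat = feature_from_line(line)
                attrs = feat.attributes
                gene_id = attrs["gene_id"][0]
            except Exception:
                n_skipped += 1
                logger.warning("skipping unparsable GTF gene record: %s", line.strip()[:120])
                continue
            symbol = attrs["gene_name"][0] if "gene_name" in attrs else gene_id
            if "gene_biotype" in attrs:
                raw = attrs["gene_biotype"][0]
            elif "gene_type" in attrs:
                raw = attrs["gene_type"][0]
            else:
                raw = ""
            if raw in lnc_biotypes:
                biotype = LNCRNA
            elif raw == PROTEIN_CODING:
                biotype = PROTEIN_CODING
            else:
                biotype = OTHER
            rows[gene_id] = (symbol, biotype)
    if n_skipped:
        logger.warning("GTF: skipped %d unparsable gene records", n_skipped)
    if not rows:
        raise FormatError(f"{path}: no gene records parsed")
    table = pd.DataFrame.from_dict(rows, orient="index", columns=["symbol", "biotype"])
    table.index.name = "gene_id"
    return GeneAnnotation(table)


def write_gtf_annotation(ann: GeneAnnotation, path: str | Path) -> None:
    """Write one synthetic ``gene`` GTF line per annotated gene.

    Coordinates are placeholders (each gene gets a disjoint 1 kb interval);
    only identity and biotype survive the round trip through the reader.
    """
    with open(path, "wt", encoding="utf-8") as fh:
        for i, (gene_id, row) in enumerate(ann.table.iterrows()):
            start = i * 2000 + 1
            raw = row["biotype"] if row["biotype"] != OTHER else "misc_RNA"
            fh.write(
                f"chr1\tirlncpair\tgene\t{start}\t{start + 999}\t.\t+\t.\t"
                f'gene_id "{gene_id}"; gene_name "{row["symbol"]}"; gene_biotype "{raw}";\n'
            )


# ---------------------------------------------------------------------------
# Gene lists, GMT, clinical and drug tables
# ---------------------------------------------------------------------------


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-gene-per-line list; blank lines and ``#`` comments are ignored."""
    genes: list[str] = []
    seen: set[str] = set()
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            g = line.strip()
            if not g or g.startswith("#"):
                continue
            if g in seen:
                logger.warning("gene list %s: dropping duplicate entry %r", path, g)
                continue
            seen.add(g)
            genes.append(g)
    if not genes:
        raise FormatError(f"{path}: empty gene list")
    return genes


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\n".join(genes) + "\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2...`` per line."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name '{name}'")
            uniq = list(dict.fromkeys(genes))
            if len(uniq) != len(genes):
                logger.warning("GMT set '%s': %d duplicate genes dropped", name, len(genes) - len(uniq))
            sets[name] = uniq
            descriptions[name] = desc
    if not sets:
        raise FormatError(f"{path}: empty GMT file")
    return GeneSetCollection(sets, descriptions)


def write_gmt(gsc: GeneSetCollection, path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for name, genes in gsc.sets.items():
            desc = gsc.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_clinical_table(path: str | Path) -> SurvivalTable:
    """Read the clinical/survival TSV.

    Required columns: ``sample_id``, ``time``, ``event``.  Optional covariates
    (age, grade, stage, residual, vital) may be missing or empty (-> NaN).
    Rows with non-positive time are dropped with a logged count; missing
    time/event is a format error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty:
        raise FormatError(f"{path}: empty clinical table")
    for col in ("sample_id", "time", "event"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    df = df.replace("", np.nan)
    if df["time"].isna().any() or df["event"].isna().any():
        raise FormatError(f"{path}: time/event may not be missing")
    df["time"] = pd.to_numeric(df["time"], errors="raise")
    df["event"] = pd.to_numeric(df["event"], errors="raise")
    n_bad = int((df["time"] <= 0).sum())
    if n_bad:
        logger.warning("clinical table %s: dropped %d rows with non-positive time", path, n_bad)
        df = df[df["time"] > 0]
    if df.empty:
        raise FormatError(f"{path}: no rows with positive follow-up time")
    df = df.set_index("sample_id")
    if "age" in df.columns:
        df["age"] = pd.to_numeric(df["age"], errors="coerce")
    return SurvivalTable(df)


def write_clinical_table(surv: SurvivalTable, path: str | Path) -> None:
    df = surv.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_drug_scores(path: str | Path) -> DrugScoreTable:
    """Read the per-sample drug sensitivity score TSV (samples x drugs)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise FormatError(f"{path}: empty drug score table")
    df.index = df.index.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric drug score ({exc})") from exc
    return DrugScoreTable(df)


def write_drug_scores(t: DrugScoreTable, path: str | Path) -> None:
    df = t.scores.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.10g")
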