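"""Readers, writers and in-memory domain types.

All external tables are plain TSV (expression matrices, sample sheets, qPCR
Ct tables, TargetScan-style context-score tables, miRTarBase-style validated
target tables), GFF3 for miRNA loci, and GMT for term annotations.  Every
downstream stage consumes only the in-memory types defined here.

Genomic coordinates are stored 0-based half-open internally; the GFF3
boundary is the only place where 1-based inclusive coordinates appear.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from gffutils.feature import feature_from_line

AGES = ("P2", "P9", "P23", "P45")
LAYERS = ("LII", "LDeep")
PLATFORMS = ("array", "rnaseq", "qpcr")
TARGET_SOURCES = ("predicted_conserved", "predicted_all", "validated")

#: qPCR cells carrying these strings (case-insensitive) are masked out.
CT_FLAG_TOKENS = frozenset({"undetermined", "unreliable"})

SAMPLE_SHEET_COLUMNS = ("sample_id", "age", "layer", "animal_id", "platform")


class FormatError(ValueError):
    """Raised when an external file violates its format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleAnnotation:
    """Metadata for one profiled sample.

    ``layer`` may be ``"NA"`` only for qPCR samples (FACS-sorted cell
    populations are not laminar dissections); ``group_extra`` carries the
    extra grouping used there (e.g. ``stellate`` / ``rest``).
    """

    sample_id: str
    age: str
    layer: str
    animal_id: str
    platform: str
    group_extra: str | None = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        if self.age not in AGES:
            raise ValueError(f"unknown age {self.age!r}; expected one of {AGES}")
        if self.platform not in PLATFORMS:
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.layer not in LAYERS + ("NA",):
            raise ValueError(f"unknown layer {self.layer!r}")
        if self.layer == "NA" and self.platform != "qpcr":
            raise ValueError("layer may be NA only for qPCR samples")


@dataclass
class ExpressionMatrix:
    """A feature x sample expression matrix plus per-sample annotation.

    ``values`` is a DataFrame indexed by feature id with one column per
    sample, ordered as ``samples``.  ``scale_tag`` distinguishes log2-scale
    values, raw counts and qPCR Ct values.
    """

    values: pd.DataFrame
    samples: list[SampleAnnotation]
    scale_tag: str = "log2"

    def __post_init__(self) -> None:
        if self.scale_tag not in ("log2", "counts", "ct"):
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids")
        if list(self.values.columns) != ids:
            raise ValueError("values columns must match sample annotation order")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dup[:5]}")
        if self.scale_tag == "counts":
            v = self.values.to_numpy()
            if np.any(v < 0) or not np.allclose(v, np.round(v)):
                raise ValueError("counts matrix must hold non-negative integers")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def sample_table(self) -> pd.DataFrame:
        """Annotations as a DataFrame indexed by sample id."""
        rows = [
            {
                "sample_id": s.sample_id,
                "age": s.age,
                "layer": s.layer,
                "animal_id": s.animal_id,
                "platform": s.platform,
                "group_extra": s.group_extra if s.group_extra is not None else "",
            }
            for s in self.samples
        ]
        return pd.DataFrame(rows).set_index("sample_id", drop=False)

    def subset_features(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(feature_ids)].copy(),
                                list(self.samples), self.scale_tag)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        keep = set(sample_ids)
        samples = [s for s in self.samples if s.sample_id in keep]
        cols = [s.sample_id for s in samples]
        return ExpressionMatrix(self.values[cols].copy(), samples, self.scale_tag)

    def with_values(self, values: pd.DataFrame, scale_tag: str | None = None) -> "ExpressionMatrix":
        cols = [s.sample_id for s in self.samples]
        return ExpressionMatrix(values[cols].copy(), list(self.samples),
                                scale_tag or self.scale_tag)


@dataclass(frozen=True)
class GenomicLocus:
    """A miRNA locus; coordinates are 0-based half-open."""

    mirna_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass(frozen=True)
class TargetRecord:
    """One miRNA -> gene link from a prediction or validation database."""

    mirna_id: str
    gene_id: str
    source: str
    context_score: float | None = None

    def __post_init__(self) -> None:
        if self.source not in TARGET_SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        predicted = self.source.startswith("predicted")
        if predicted and self.context_score is None:
            raise ValueError("predicted records require a context score")
        if not predicted and self.context_score is not None:
            raise ValueError("validated records carry no context score")


@dataclass(frozen=True)
class TermAnnotation:
    """One functional term (GO/KEGG/REACTOME style) with its gene set."""

    term_id: str
    term_name: str
    gene_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError(f"term {self.term_id} has an empty gene set")


# ---------------------------------------------------------------------------
# sample sheets and expression tables
# ---------------------------------------------------------------------------

def read_sample_sheet(path) -> list[SampleAnnotation]:
    sheet = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise FormatError(f"sample sheet missing columns {missing}")
    out = []
    for _, row in sheet.iterrows():
        extra = row.get("group_extra", "")
        out.append(SampleAnnotation(
            sample_id=row["sample_id"], age=row["age"],
            layer=row["layer"] if row["layer"] else "NA",
            animal_id=row["animal_id"], platform=row["platform"],
            group_extra=extra if extra else None,
        ))
    ids = [s.sample_id for s in out]
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate sample ids in sample sheet")
    return out


def write_sample_sheet(samples: Sequence[SampleAnnotation], path) -> None:
    rows = [
        [s.sample_id, s.age, s.layer, s.animal_id, s.platform, s.group_extra or ""]
        for s in samples
    ]
    pd.DataFrame(rows, columns=list(SAMPLE_SHEET_COLUMNS) + ["group_extra"]).to_csv(
        path, sep="\t", index=False)


def _read_table(table_path) -> pd.DataFrame:
    table = pd.read_csv(table_path, sep="\t", index_col=0, dtype=str)
    table.index = table.index.astype(str)
    if table.index.has_duplicates:
        dup = table.index[table.index.duplicated()].tolist()
        raise FormatError(f"duplicate feature ids in {table_path}: {dup[:5]}")
    return table


def read_expression(table_path, sample_sheet_path, scale_tag: str = "log2") -> ExpressionMatrix:
    """Read a numeric feature x sample TSV together with its sample sheet.

    Samples are reordered to the sheet order; a sheet sample absent from the
    table is an error, as is any non-numeric cell.
    """
    samples = read_sample_sheet(sample_sheet_path)
    table = _read_table(table_path)
    absent = [s.sample_id for s in samples if s.sample_id not in table.columns]
    if absent:
        raise FormatError(f"samples missing from expression table: {absent}")
    table = table[[s.sample_id for s in samples]]
    try:
        values = table.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric cell in {table_path}: {exc}") from exc
    if scale_tag == "counts":
        values = values.round().astype(np.int64).astype(float)
    return ExpressionMatrix(values, samples, scale_tag)


def write_expression(matrix: ExpressionMatrix, table_path, sample_sheet_path=None) -> None:
    if matrix.scale_tag == "counts":
        matrix.values.astype(np.int64).to_csv(table_path, sep="\t", index_label="feature_id")
    else:
        matrix.values.to_csv(table_path, sep="\t", index_label="feature_id",
                             float_format="%.10g")
    if sample_sheet_path is not None:
        write_sample_sheet(matrix.samples, sample_sheet_path)


# ---------------------------------------------------------------------------
# qPCR Ct tables with reliability flags
# ---------------------------------------------------------------------------

def read_ct(table_path, sample_sheet_path) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Read a Ct table whose cells are numeric or Undetermined/Unreliable.

    Returns the Ct matrix (flagged cells as NaN) and a parallel boolean mask,
    True where the cell was flagged.  Flag strings match case-insensitively.
    """
    samples = read_sample_sheet(sample_sheet_path)
    table = _read_table(table_path)
    absent = [s.sample_id for s in samples if s.sample_id not in table.columns]
    if absent:
        raise FormatError(f"samples missing from Ct table: {absent}")
    table = table[[s.sample_id for s in samples]]

    values = pd.DataFrame(np.nan, index=table.index, columns=table.columns)
    mask = pd.DataFrame(False, index=table.index, columns=table.columns)
    for col in table.columns:
        for idx, cell in table[col].items():
            token = str(cell).strip()
            if token.lower() in CT_FLAG_TOKENS:
                mask.at[idx, col] = True
                continue
            try:
                values.at[idx, col] = float(token)
            except ValueError as exc:
                raise FormatError(
                    f"unknown token {token!r} at ({idx}, {col}) in {table_path}") from exc
    return ExpressionMatrix(values, samples, "ct"), mask


def write_ct(matrix: ExpressionMatrix, mask: pd.DataFrame, table_path,
             sample_sheet_path=None) -> None:
    out = matrix.values.map(lambda v: "" if pd.isna(v) else f"{v:.10g}")
    out = out.where(~mask.astype(bool), "Undetermined")
    out.to_csv(table_path, sep="\t", index_label="feature_id")
    if sample_sheet_path is not None:
        write_sample_sheet(matrix.samples, sample_sheet_path)


# ---------------------------------------------------------------------------
# target tables
# ---------------------------------------------------------------------------

#: Column-name map matching the TargetScan v6.2 context-score table layout.
TARGETSCAN_COLUMNS = {"gene": "Gene Symbol", "mirna": "miRNA", "score": "context+ score"}

MIRTARBASE_COLUMNS = {"gene": "Target Gene", "mirna": "miRNA"}


def read_targetscan_context(path, score_threshold: float = -0.1,
                            column_map: Mapping[str, str] | None = None) -> list[TargetRecord]:
    """Read a TargetScan-style context-score table.

    Every (miRNA, gene) pair yields a ``predicted_all`` record whose score is
    the minimum (best) context score over its sites; pairs strictly below
    ``score_threshold`` additionally yield a ``predicted_conserved`` record.
    """
    cmap = dict(TARGETSCAN_COLUMNS)
    if column_map:
        cmap.update(column_map)
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [v for v in cmap.values() if v not in table.columns]
    if missing:
        raise FormatError(f"context-score table missing mapped columns {missing}")
    scores = table[cmap["score"]].astype(float)
    pairs = (
        pd.DataFrame({"mirna": table[cmap["mirna"]], "gene": table[cmap["gene"]],
                      "score": scores})
        .groupby(["mirna", "gene"], sort=True)["score"].min()
    )
    records: list[TargetRecord] = []
    for (mirna, gene), score in pairs.items():
        records.append(TargetRecord(mirna, gene, "predicted_all", float(score)))
        if score < score_threshold:  # strict "below"
            records.append(TargetRecord(mirna, gene, "predicted_conserved", float(score)))
    return records


def read_mirtarbase(path, column_map: Mapping[str, str] | None = None) -> list[TargetRecord]:
    """Read a miRTarBase-style validated-target table."""
    cmap = dict(MIRTARBASE_COLUMNS)
    if column_map:
        cmap.update(column_map)
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [v for v in cmap.values() if v not in table.columns]
    if missing:
        raise FormatError(f"validated-target table missing mapped columns {missing}")
    seen = set()
    records = []
    for _, row in table.iterrows():
        key = (row[cmap["mirna"]], row[cmap["gene"]])
        if key in seen:
            continue
        seen.add(key)
        records.append(TargetRecord(key[0], key[1], "validated"))
    return records


def write_target_records(records: Iterable[TargetRecord], path) -> None:
    rows = [
        [r.mirna_id, r.gene_id, r.source,
         "" if r.context_score is None else f"{r.context_score:.10g}"]
        for r in records
    ]
    pd.DataFrame(rows, columns=["mirna_id", "gene_id", "source", "context_score"]).to_csv(
        path, sep="\t", index=False)


def read_target_records(path) -> list[TargetRecord]:
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        TargetRecord(row["mirna_id"], row["gene_id"], row["source"],
                     float(row["context_score"]) if row["context_score"] else None)
        for _, row in table.iterrows()
    ]


# ---------------------------------------------------------------------------
# miRNA loci (GFF3)
# ---------------------------------------------------------------------------

def read_mirbase_gff(path, record_types: Sequence[str] = ("miRNA_primary_transcript",),
                     ) -> list[GenomicLocus]:
    """Read miRNA loci from a miRBase-style GFF3 file.

    ``record_types`` selects hairpin (``miRNA_primary_transcript``, the
    default) and/or mature (``miRNA``) records.  1-based inclusive GFF
    coordinates are converted to the internal 0-based half-open convention.
    """
    wanted = set(record_types)
    loci: list[GenomicLocus] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise FormatError(f"{path}:{lineno}: malformed GFF line")
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise FormatError(f"{path}:{lineno}: malformed GFF line: {exc}") from exc
            if feat.featuretype not in wanted:
                continue
            name = (feat.attributes.get("ID") or feat.attributes.get("Name") or [None])[0]
            if name is None:
                raise FormatError(f"{path}:{lineno}: feature without ID/Name attribute")
            loci.append(GenomicLocus(name, feat.seqid, feat.start - 1, feat.end,
                                     feat.strand if feat.strand in "+-" else "."))
    return loci


def write_mirbase_gff(loci: Iterable[GenomicLocus], path,
                      record_type: str = "miRNA_primary_transcript") -> None:
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for locus in loci:
            handle.write("\t".join([
                locus.chrom, "mecmir", record_type,
                str(locus.start + 1), str(locus.end), ".",
                locus.strand, ".",
                f"ID={locus.mirna_id};Name={locus.mirna_id}",
            ]) + "\n")


# ---------------------------------------------------------------------------
# GMT term annotations
# ---------------------------------------------------------------------------

def read_gmt(path) -> list[TermAnnotation]:
    """Read a GMT file: one term per line, ``term<TAB>description<TAB>genes...``."""
    terms: list[TermAnnotation] = []
    seen = set()
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line with fewer than 3 fields")
            term_id, desc = fields[0], fields[1]
            if term_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate term id {term_id}")
            seen.add(term_id)
            genes = frozenset(g for g in fields[2:] if g)
            terms.append(TermAnnotation(term_id, desc, genes))
    return terms


def write_gmt(terms: Iterable[TermAnnotation], path) -> None:
    with open(path, "w") as handle:
        for term in terms:
            handle.write("\t".join([term.term_id, term.term_name] + sorted(term.gene_ids)) + "\n")
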