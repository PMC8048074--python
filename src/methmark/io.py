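"""Readers and writers for the TSV/BED/JSON exchange formats.

TSV is the canonical table dialect (UTF-8, "NA" as the missing-value
token). Matrix files carry the row-id in the first column and sample ids
in the header. Annotation tables are exchanged either in the internal
1-based column layout or in BED-compatible order (0-based half-open
start/end); the coordinate conversion is localized here.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohorts import ANNOTATION_COLUMNS, BetaCohort, ExpressionCohort, StoolStudy, make_annotation

__all__ = [
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_beta_cohort",
    "write_beta_cohort",
    "read_annotation_tsv",
    "write_annotation_tsv",
    "write_annotation_bed",
    "read_annotation_bed",
    "read_stool_study",
    "write_stool_study",
    "load_config",
]

NA = "NA"


class TsvFormatError(ValueError):
    """Malformed tabular input; message carries the offending line number."""


def read_matrix_tsv(path) -> pd.DataFrame:
    """Read an id-by-sample numeric matrix; 'NA' cells become NaN.

    Raises :class:`TsvFormatError` naming the line for duplicate row ids,
    ragged rows and non-numeric cells.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise TsvFormatError(f"{path}: empty file") from None
        columns = header[1:]
        if len(set(columns)) != len(columns):
            raise TsvFormatError(f"{path}: duplicate sample ids in header")
        ids: list[str] = []
        seen: set[str] = set()
        rows: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise TsvFormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}"
                )
            rid = row[0]
            if rid in seen:
                raise TsvFormatError(f"{path}:{lineno}: duplicate row id {rid!r}")
            seen.add(rid)
            vals = []
            for col, cell in zip(columns, row[1:]):
                if cell == NA or cell == "":
                    vals.append(np.nan)
                    continue
                try:
                    vals.append(float(cell))
                except ValueError:
                    raise TsvFormatError(
                        f"{path}:{lineno}: non-numeric cell {cell!r} in column {col!r}"
                    ) from None
            ids.append(rid)
            rows.append(vals)
    return pd.DataFrame(rows, index=ids, columns=columns)


def write_matrix_tsv(matrix: pd.DataFrame, path, id_label: str = "id") -> None:
    matrix = matrix.copy()
    matrix.index.name = id_label
    matrix.to_csv(path, sep="\t", na_rep=NA)


def read_sample_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "age" in meta.columns:
        meta["age"] = pd.to_numeric(meta["age"], errors="coerce")
    return meta


def write_sample_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_beta_cohort(matrix_path, metadata_path) -> BetaCohort:
    return BetaCohort(read_matrix_tsv(matrix_path), read_sample_metadata(metadata_path))


def write_beta_cohort(cohort: BetaCohort, matrix_path, metadata_path) -> None:
    write_matrix_tsv(cohort.beta, matrix_path, id_label="probe_id")
    write_sample_metadata(cohort.samples.reset_index(drop=True), metadata_path)


def read_expression_cohort(matrix_path, metadata_path) -> ExpressionCohort:
    return ExpressionCohort(read_matrix_tsv(matrix_path), read_sample_metadata(metadata_path))


def write_expression_cohort(cohort: ExpressionCohort, matrix_path, metadata_path) -> None:
    write_matrix_tsv(cohort.expr, matrix_path, id_label="gene")
    write_sample_metadata(cohort.samples.reset_index(drop=True), metadata_path)


def read_annotation_tsv(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"chromosome": str, "probe_id": str, "gene": str})
    return make_annotation(ann)


def write_annotation_tsv(annotation: pd.DataFrame, path) -> None:
    annotation.reset_index(drop=True).to_csv(path, sep="\t", index=False, columns=list(ANNOTATION_COLUMNS))


#: BED-compatible column order; start is 0-based half-open
BED_COLUMNS = ("chrom", "start", "end", "probe_id", "gene", "tss", "strand", "island")


def write_annotation_bed(annotation: pd.DataFrame, path) -> None:
    bed = pd.DataFrame(
        {
            "chrom": annotation["chromosome"],
            "start": annotation["position"] - 1,  # 1-based -> 0-based half-open
            "end": annotation["position"],
            "probe_id": annotation["probe_id"],
            "gene": annotation["gene"],
            "tss": annotation["tss_position"],
            "strand": annotation["strand"],
            "island": annotation["in_cpg_island"].astype(int),
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_annotation_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", names=list(BED_COLUMNS), dtype={"chrom": str})
    return make_annotation(
        pd.DataFrame(
            {
                "probe_id": bed["probe_id"],
                "chromosome": bed["chrom"],
                "position": bed["start"] + 1,  # back to 1-based
                "gene": bed["gene"],
                "tss_position": bed["tss"],
                "strand": bed["strand"],
                "in_cpg_island": bed["island"].astype(bool),
            }
        )
    )


def read_stool_study(path) -> StoolStudy:
    table = pd.read_csv(path, sep="\t", na_values=[NA])
    reserved = {"subject_id", "label", "fit_value", "sex", "age", "stage", "location"}
    markers = [c for c in table.columns if c not in reserved]
    return StoolStudy(table, marker_names=markers)


def write_stool_study(study: StoolStudy, path) -> None:
    study.subjects.to_csv(path, sep="\t", index=False, na_rep=NA)


def load_config(path) -> dict:
    """Load a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix in (".json",):
        return json.loads(text)
    return yaml.safe_load(text)


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, set):
            return sorted(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n", encoding="utf-8")
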