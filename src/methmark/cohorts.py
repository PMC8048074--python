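"""Core data containers shared across the pipeline.

A cohort couples a numeric matrix (pandas DataFrame, features in rows,
samples in columns) with per-sample metadata. Beta values are Infinium-style
methylation fractions in [0, 1]; expression values are non-negative
normalized RNA-seq estimates (RSEM-like scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NORMAL = "normal"
TUMOR = "tumor"
STAGES = ("I", "II", "III", "IV")

#: metadata columns every cohort carries
META_COLUMNS = ("sample_id", "tissue", "group", "stage")


def _check_metadata(matrix: pd.DataFrame, samples: pd.DataFrame) -> None:
    missing = [c for c in META_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"sample metadata lacks columns: {missing}")
    if samples["sample_id"].duplicated().any():
        dup = samples.loc[samples["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id in metadata: {dup!r}")
    unknown = set(matrix.columns) - set(samples["sample_id"])
    if unknown:
        raise ValueError(f"matrix columns without metadata: {sorted(unknown)[:5]}")


@dataclass
class BetaCohort:
    """Probes x samples beta-value matrix plus sample metadata."""

    beta: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        _check_metadata(self.beta, self.samples)
        vals = self.beta.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("beta values must lie in [0, 1] (or be missing)")
        self.samples = self.samples.set_index("sample_id", drop=False)

    def sample_ids(self, group: str | None = None, stages: tuple[str, ...] | None = None) -> list[str]:
        meta = self.samples
        mask = pd.Series(True, index=meta.index)
        if group is not None:
            mask &= meta["group"] == group
        if stages is not None:
            mask &= meta["stage"].isin(stages)
        return list(meta.loc[mask, "sample_id"])

    @property
    def normal_ids(self) -> list[str]:
        return self.sample_ids(group=NORMAL)

    @property
    def tumor_ids(self) -> list[str]:
        return self.sample_ids(group=TUMOR)


@dataclass
class ExpressionCohort:
    """Genes x samples normalized expression matrix plus sample metadata."""

    expr: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        _check_metadata(self.expr, self.samples)
        vals = self.expr.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and finite.min() < 0:
            raise ValueError("expression values must be non-negative")
        self.samples = self.samples.set_index("sample_id", drop=False)

    def sample_ids(self, group: str) -> list[str]:
        meta = self.samples
        return list(meta.loc[meta["group"] == group, "sample_id"])


#: annotation table columns, internal 1-based coordinates
ANNOTATION_COLUMNS = (
    "probe_id",
    "chromosome",
    "position",
    "gene",
    "tss_position",
    "strand",
    "in_cpg_island",
)


def make_annotation(records: list[dict] | pd.DataFrame) -> pd.DataFrame:
    """Build and validate a probe-annotation table.

    Columns: probe_id, chromosome, position (1-based), gene, tss_position
    (1-based), strand ('+'/'-'), in_cpg_island (bool). Indexed by probe_id.
    """
    ann = pd.DataFrame(records)
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation lacks columns: {missing}")
    if ann["probe_id"].duplicated().any():
        dup = ann.loc[ann["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValueError(f"duplicate probe_id in annotation: {dup!r}")
    if (ann["position"] < 1).any() or (ann["tss_position"] < 1).any():
        raise ValueError("annotation coordinates are 1-based and must be >= 1")
    bad = set(ann["strand"]) - {"+", "-"}
    if bad:
        raise ValueError(f"invalid strand values: {sorted(bad)}")
    ann = ann.copy()
    ann["in_cpg_island"] = ann["in_cpg_island"].astype(bool)
    return ann.set_index("probe_id", drop=False)


@dataclass
class StoolStudy:
    """Per-subject stool measurements for marker/panel evaluation.

    ``subjects`` has one row per subject with columns: subject_id, label
    ('control'/'case'), fit_value (ng Hb/ml, NaN if missing), one column per
    marker (qMSP copies/ul, NaN if missing), and covariates (sex, age,
    stage, location) for cases.
    """

    subjects: pd.DataFrame
    marker_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        req = {"subject_id", "label"}
        if not req <= set(self.subjects.columns):
            raise ValueError(f"stool table needs columns {sorted(req)}")
        bad = set(self.subjects["label"]) - {"control", "case"}
        if bad:
            raise ValueError(f"labels must be control/case, got {sorted(bad)}")
        for m in self.marker_names:
            if m not in self.subjects.columns:
                raise ValueError(f"marker column missing from table: {m!r}")
            vals = self.subjects[m].to_numpy(dtype=float)
            if np.nanmin(vals, initial=0.0) < 0:
                raise ValueError(f"marker {m!r} has negative values")
        self.subjects = self.subjects.reset_index(drop=True)

    @property
    def labels(self) -> np.ndarray:
        """1 for case, 0 for control, aligned to the subject table rows."""
        return (self.subjects["label"] == "case").to_numpy(dtype=int)

    def marker_values(self, marker: str) -> np.ndarray:
        return self.subjects[marker].to_numpy(dtype=float)
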