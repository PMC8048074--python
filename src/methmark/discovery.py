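"""Promoter-methylation marker discovery cascade.

The cascade mirrors the in silico selection procedure used for 450k-array
colon adenocarcinoma data:

1. restrict to probes in promoter CpG islands (TSS window -1000..+500) that
   are unmethylated in normal colon tissue (median beta < 0.20);
2. stage-stratified differential methylation (normal vs stage I/II and
   normal vs stage III/IV), one-sided shifted rank-sum test (mu = -0.25),
   BH-FDR < 0.05 plus a median-beta difference < -0.25;
3. proximity filter: keep probes with another significant probe within
   750 bp;
4. intersect with genes downregulated in tumors (one-sided shifted
   rank-sum, mu = 1, FDR < 0.05);
5. pan-tissue specificity: drop probes methylated (beta > 0.20) in >= 25%
   of normal samples of any tissue type;

then rank surviving genes by the best probe's sensitivity at 100%
specificity and keep the top 20.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohorts import NORMAL, TUMOR, BetaCohort, ExpressionCohort

__all__ = [
    "DiscoveryParams",
    "DiscoveryReport",
    "select_promoter_island_probes",
    "filter_unmethylated_in_normal",
    "shifted_rank_sum_test",
    "bh_fdr",
    "differential_methylation",
    "proximity_filter",
    "differential_expression",
    "cross_tissue_specificity_filter",
    "sensitivity_at_full_specificity",
    "run_discovery",
]


@dataclass
class DiscoveryParams:
    """Tunable thresholds of the cascade; defaults reproduce the published
    analysis parameters."""

    promoter_upstream_bp: int = 1000
    promoter_downstream_bp: int = 500
    unmeth_median_threshold: float = 0.20
    mw_shift_methylation: float = -0.25
    fdr_threshold: float = 0.05
    delta_median_threshold: float = -0.25
    proximity_window_bp: int = 750
    mw_shift_expression: float = 1.0
    cross_tissue_beta_threshold: float = 0.20
    cross_tissue_max_fraction: float = 0.25
    top_k: int = 20
    #: 'intersection' requires probes significant in both stage comparisons;
    #: 'union' accepts either.
    stage_combination: str = "intersection"
    #: minimum non-missing values per group for a probe/gene to be tested
    min_group_size: int = 3

    def __post_init__(self) -> None:
        if self.promoter_upstream_bp <= 0 or self.promoter_downstream_bp <= 0:
            raise ValueError("promoter window sizes must be positive")
        if not 0 <= self.fdr_threshold <= 1:
            raise ValueError("fdr_threshold must lie in [0, 1]")
        if self.proximity_window_bp <= 0:
            raise ValueError("proximity_window_bp must be positive")
        if self.stage_combination not in ("intersection", "union"):
            raise ValueError("stage_combination must be 'intersection' or 'union'")


@dataclass
class DiscoveryReport:
    """Per-section survivor counts and the final ranked candidate table."""

    section_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    stage_significant: dict[str, set[str]] = field(default_factory=dict)
    downregulated_genes: set[str] = field(default_factory=set)
    candidates: pd.DataFrame = field(default_factory=pd.DataFrame)
    top_genes: list[str] = field(default_factory=list)

    def record(self, section: str, probes: set[str], genes: set[str]) -> None:
        self.section_counts[section] = {"probes": len(probes), "genes": len(genes)}

    def to_dict(self) -> dict:
        return {
            "section_counts": self.section_counts,
            "stage_significant": {k: sorted(v) for k, v in self.stage_significant.items()},
            "downregulated_genes": sorted(self.downregulated_genes),
            "top_genes": list(self.top_genes),
            "candidates": self.candidates.to_dict(orient="records"),
        }


# ---------------------------------------------------------------------------
# statistical primitives


def shifted_rank_sum_test(
    reference,
    alternative_group,
    shift: float = 0.0,
    direction: str = "greater",
) -> float:
    """One-sided Mann-Whitney test of a location shift.

    Tests H0: the alternative group's location exceeds the reference's by
    exactly ``shift``, against the one-sided H1 that it exceeds (or falls
    short of) the reference by more, in the stated ``direction``. The shift
    is subtracted from the alternative group before ranking, the standard
    mu-parameterized rank-sum construction. Exact enumeration is used when
    the combined sample size is <= 12 and there are no ties; otherwise the
    normal approximation with tie and continuity correction.
    """
    ref = np.asarray(reference, dtype=float)
    alt = np.asarray(alternative_group, dtype=float)
    if ref.size == 0 or alt.size == 0:
        raise ValueError("both samples must be non-empty")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    shifted = alt - shift
    pooled = np.concatenate([shifted, ref])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        shifted, ref, alternative=direction, method=method, use_continuity=True
    )
    return float(res.pvalue)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# cascade sections


def promoter_offset(annotation: pd.DataFrame) -> pd.Series:
    """Signed TSS-relative offset, strand-aware: (position - tss) * sign."""
    sign = np.where(annotation["strand"] == "-", -1, 1)
    return (annotation["position"] - annotation["tss_position"]) * sign


def select_promoter_island_probes(
    annotation: pd.DataFrame,
    upstream_bp: int = 1000,
    downstream_bp: int = 500,
) -> set[str]:
    """Probes inside the promoter window [-upstream, +downstream] around the
    TSS (inclusive at both ends, strand-aware) AND inside a CpG island."""
    if annotation.empty:
        raise ValueError("annotation is empty")
    off = promoter_offset(annotation)
    keep = annotation["in_cpg_island"] & (off >= -upstream_bp) & (off <= downstream_bp)
    return set(annotation.loc[keep, "probe_id"])


def _group_matrix(cohort: BetaCohort, probes: set[str], sample_ids: list[str]) -> pd.DataFrame:
    idx = [p for p in cohort.beta.index if p in probes]
    return cohort.beta.loc[idx, sample_ids]


def filter_unmethylated_in_normal(
    cohort: BetaCohort, probes: set[str], threshold: float = 0.20
) -> set[str]:
    """Keep probes with median beta over normal samples strictly < threshold.

    Missing values are excluded from the median.
    """
    normals = cohort.normal_ids
    if not normals:
        raise ValueError("cohort has no normal samples")
    sub = _group_matrix(cohort, probes, normals)
    med = sub.median(axis=1, skipna=True)
    return set(med.index[med < threshold])


def differential_methylation(
    cohort: BetaCohort, probes: set[str], params: DiscoveryParams
) -> dict[str, set[str]]:
    """Stage-stratified hypermethylation calls.

    For each stage group ('I/II', 'III/IV'): per-probe one-sided shifted
    rank-sum p that tumor beta exceeds normal beta by more than
    ``|mw_shift_methylation|``, BH-FDR across tested probes, retained when
    q < fdr_threshold AND median(normal) - median(tumor) <
    delta_median_threshold.
    """
    normals = cohort.normal_ids
    if not normals:
        raise ValueError("cohort has no normal samples")
    shift = abs(params.mw_shift_methylation)
    out: dict[str, set[str]] = {}
    for label, stages in (("I/II", ("I", "II")), ("III/IV", ("III", "IV"))):
        tumor_ids = cohort.sample_ids(group=TUMOR, stages=stages)
        if not tumor_ids:
            raise ValueError(f"no tumor samples in stage group {label}")
        nmat = _group_matrix(cohort, probes, normals).to_numpy(dtype=float)
        tmat = _group_matrix(cohort, probes, tumor_ids).to_numpy(dtype=float)
        index = [p for p in cohort.beta.index if p in probes]
        tested, pvals, deltas = [], [], []
        for i, probe in enumerate(index):
            nv = nmat[i][np.isfinite(nmat[i])]
            tv = tmat[i][np.isfinite(tmat[i])]
            if nv.size < params.min_group_size or tv.size < params.min_group_size:
                continue
            pvals.append(
                shifted_rank_sum_test(nv, tv, shift=shift, direction="greater")
            )
            deltas.append(np.median(nv) - np.median(tv))
            tested.append(probe)
        if not tested:
            out[label] = set()
            continue
        q = bh_fdr(pvals)
        keep = {
            probe
            for probe, qv, d in zip(tested, q, deltas)
            if qv < params.fdr_threshold and d < params.delta_median_threshold
        }
        out[label] = keep
    return out


def proximity_filter(
    significant: set[str], annotation: pd.DataFrame, window_bp: int = 750
) -> set[str]:
    """Keep a probe iff another probe of the same set lies within
    ``window_bp`` (inclusive) on the same chromosome."""
    missing = significant - set(annotation.index)
    if missing:
        raise ValueError(f"annotation lacks probes: {sorted(missing)[:5]}")
    sub = annotation.loc[sorted(significant)]
    keep: set[str] = set()
    for _, grp in sub.groupby("chromosome", sort=False):
        pos = grp["position"].to_numpy()
        ids = grp["probe_id"].to_numpy()
        order = np.argsort(pos)
        pos, ids = pos[order], ids[order]
        for i in range(len(pos)):
            left_ok = i > 0 and pos[i] - pos[i - 1] <= window_bp
            right_ok = i + 1 < len(pos) and pos[i + 1] - pos[i] <= window_bp
            if left_ok or right_ok:
                keep.add(ids[i])
    return keep


def differential_expression(
    cohort: ExpressionCohort, params: DiscoveryParams
) -> set[str]:
    """Genes downregulated in tumors: one-sided shifted rank-sum test that
    normal expression exceeds tumor expression by more than the shift
    (on the normalized scale), BH-FDR < fdr_threshold."""
    normals = cohort.sample_ids(NORMAL)
    tumors = cohort.sample_ids(TUMOR)
    if not normals or not tumors:
        raise ValueError("expression cohort needs both normal and tumor samples")
    nmat = cohort.expr[normals].to_numpy(dtype=float)
    tmat = cohort.expr[tumors].to_numpy(dtype=float)
    tested, pvals = [], []
    for i, gene in enumerate(cohort.expr.index):
        nv = nmat[i][np.isfinite(nmat[i])]
        tv = tmat[i][np.isfinite(tmat[i])]
        if nv.size < params.min_group_size or tv.size < params.min_group_size:
            continue
        pvals.append(
            shifted_rank_sum_test(
                tv, nv, shift=params.mw_shift_expression, direction="greater"
            )
        )
        tested.append(gene)
    if not tested:
        return set()
    q = bh_fdr(pvals)
    return {g for g, qv in zip(tested, q) if qv < params.fdr_threshold}


def cross_tissue_specificity_filter(
    normal_cohorts: dict[str, BetaCohort],
    probes: set[str],
    params: DiscoveryParams,
) -> set[str]:
    """Pan-tissue specificity: per probe and tissue, fraction of normal
    samples with beta > cross_tissue_beta_threshold; keep the probe iff the
    maximum over tissues is strictly < cross_tissue_max_fraction."""
    if not normal_cohorts:
        raise ValueError("at least one tissue cohort is required")
    keep = set(probes)
    for tissue, cohort in normal_cohorts.items():
        missing = probes - set(cohort.beta.index)
        if missing:
            raise ValueError(
                f"tissue {tissue!r} cohort lacks probes: {sorted(missing)[:5]}"
            )
        ids = cohort.normal_ids or list(cohort.beta.columns)
        sub = cohort.beta.loc[sorted(probes), ids]
        frac = (sub > params.cross_tissue_beta_threshold).sum(axis=1) / sub.notna().sum(
            axis=1
        ).clip(lower=1)
        keep &= set(frac.index[frac < params.cross_tissue_max_fraction])
    return keep


def sensitivity_at_full_specificity(cohort: BetaCohort, probe: str) -> float:
    """Sensitivity of a per-probe threshold set at the maximum normal beta.

    The threshold guarantees 100% specificity by construction; sensitivity
    is the fraction of tumor samples strictly above it.
    """
    normals = cohort.normal_ids
    tumors = cohort.tumor_ids
    if not normals or not tumors:
        raise ValueError("cohort needs both normal and tumor samples")
    nvals = cohort.beta.loc[probe, normals].to_numpy(dtype=float)
    tvals = cohort.beta.loc[probe, tumors].to_numpy(dtype=float)
    nvals = nvals[np.isfinite(nvals)]
    tvals = tvals[np.isfinite(tvals)]
    threshold = nvals.max()
    return float((tvals > threshold).sum() / tvals.size)


# ---------------------------------------------------------------------------
# full pipeline


def run_discovery(
    colon_beta: BetaCohort,
    tissue_normals: dict[str, BetaCohort],
    expr: ExpressionCohort,
    annotation: pd.DataFrame,
    params: DiscoveryParams | None = None,
) -> DiscoveryReport:
    """Run the full cascade and return a report with per-section counts and
    the ranked candidate genes."""
    params = params or DiscoveryParams()
    report = DiscoveryReport()
    gene_of = annotation["gene"]

    def genes_of(probe_set: set[str]) -> set[str]:
        return set(gene_of.loc[sorted(probe_set)])

    promoter = select_promoter_island_probes(
        annotation, params.promoter_upstream_bp, params.promoter_downstream_bp
    )
    promoter &= set(colon_beta.beta.index)
    report.record("1_promoter_island", promoter, genes_of(promoter))

    unmeth = filter_unmethylated_in_normal(
        colon_beta, promoter, params.unmeth_median_threshold
    )
    report.record("1_unmethylated_in_normal", unmeth, genes_of(unmeth))

    stage_sets = differential_methylation(colon_beta, unmeth, params)
    report.stage_significant = stage_sets
    for label, s in stage_sets.items():
        report.section_counts[f"2_differential_methylation_{label}"] = {
            "probes": len(s),
            "genes": len(genes_of(s)),
        }

    proximal = {
        label: proximity_filter(s, annotation, params.proximity_window_bp)
        for label, s in stage_sets.items()
    }
    if params.stage_combination == "intersection":
        combined = set.intersection(*proximal.values()) if proximal else set()
    else:
        combined = set.union(*proximal.values()) if proximal else set()
    report.record("2_proximity_and_stage_combined", combined, genes_of(combined))

    down = differential_expression(expr, params)
    report.downregulated_genes = down
    report.section_counts["3_downregulated_genes"] = {
        "probes": 0,
        "genes": len(down),
    }
    with_expr = {p for p in combined if gene_of.loc[p] in down}
    report.record("3_methylated_and_downregulated", with_expr, genes_of(with_expr))

    specific = cross_tissue_specificity_filter(tissue_normals, with_expr, params)
    report.record("4_cross_tissue_specific", specific, genes_of(specific))

    rows = []
    for gene, grp in annotation.loc[sorted(specific)].groupby("gene", sort=True):
        best_probe, best_sens = None, -1.0
        for probe in grp["probe_id"]:
            sens = sensitivity_at_full_specificity(colon_beta, probe)
            if sens > best_sens:
                best_probe, best_sens = probe, sens
        rows.append({"gene": gene, "best_probe": best_probe, "sensitivity": best_sens})
    candidates = pd.DataFrame(rows, columns=["gene", "best_probe", "sensitivity"])
    if not candidates.empty:
        candidates = candidates.sort_values(
            ["sensitivity", "gene"], ascending=[False, True]
        ).reset_index(drop=True)
    report.candidates = candidates
    report.top_genes = list(candidates["gene"].head(params.top_k))
    report.record("5_top_ranked", set(), set(report.top_genes))
    return report
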