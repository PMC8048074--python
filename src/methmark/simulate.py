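"""Synthetic cohorts with planted ground truth.

The generator emulates the data structures of a TCGA-style methylation
biomarker study: a 450k-like beta-value matrix for colon normals and
staged tumors, normal-tissue beta matrices for a panel of other tissue
types, a normalized RNA-seq expression matrix, a stool study with
continuous qMSP marker signals (copies/ul) and quantitative FIT values
(ng Hb/ml), and an ontology catalogue with gene annotations.

Beta values follow the bimodal convention: unmethylated probes draw from
Beta(1, 9) (mean 0.1), methylated probes from Beta(9, 1) (mean 0.9).
Gene classes plant one decoy per discovery-cascade filter, so each
filter's rejection behavior is independently testable:

====================================  =======================================
class                                 designed to be removed by
====================================  =======================================
decoy_methylated_in_colon_normals     unmethylated-in-normal filter
decoy_late_stage_only                 stage I/II differential methylation
                                      (fails the stage intersection)
decoy_isolated_probe                  proximity filter (1 promoter probe)
decoy_not_downregulated               differential-expression intersection
decoy_methylated_in_other_tissue_...  cross-tissue specificity filter
====================================  =======================================

``null`` genes carry no signal anywhere. Default cohort sizes follow the
published discovery analysis (37 colon normals; 146 stage I/II and 116
stage III/IV tumors; 14 tissue types; 50 stool controls and 43 cases).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohorts import NORMAL, TUMOR, BetaCohort, ExpressionCohort, StoolStudy, make_annotation
from .enrichment import OntologyCatalogue

__all__ = [
    "SimulationConfig",
    "TruthLabels",
    "DECOY_CLASSES",
    "GENE_CLASSES",
    "simulate_methylation_cohort",
    "simulate_expression_cohort",
    "simulate_stool_study",
    "simulate_ontology",
]

DECOY_CLASSES = (
    "decoy_late_stage_only",
    "decoy_methylated_in_other_tissue_normals",
    "decoy_not_downregulated",
    "decoy_isolated_probe",
    "decoy_methylated_in_colon_normals",
)
GENE_CLASSES = ("true_marker",) + DECOY_CLASSES + ("null",)

#: tissue panel emulating the cross-tissue specificity check
TISSUE_NAMES = (
    "breast", "lung_squamous", "prostate", "head_neck", "lung_adeno",
    "bladder", "kidney_clear", "kidney_papillary", "liver", "thyroid",
    "uterine", "colorectal", "esophageal",
)


@dataclass
class SimulationConfig:
    """Study-condition parameters for all generators (one seed drives
    everything; identical configs give byte-identical output)."""

    n_normal: int = 37
    n_tumor_per_stage: dict[str, int] = field(
        default_factory=lambda: {"I": 73, "II": 73, "III": 58, "IV": 58}
    )
    n_tissues: int = 14
    n_tissue_normal: int = 80
    n_probes_per_gene: int = 3
    n_genes: int = 60
    n_true_markers: int = 5
    decoy_counts: dict[str, int] = field(
        default_factory=lambda: {c: 5 for c in DECOY_CLASSES}
    )
    beta_params_unmeth: tuple[float, float] = (1.0, 9.0)
    beta_params_meth: tuple[float, float] = (9.0, 1.0)
    n_expr_normal: int = 41
    n_expr_tumor: int = 285
    expr_log_mean: float = 1.5
    expr_log_sd: float = 0.5
    expr_fold_change: float = 4.0
    stool_n_controls: int = 50
    stool_n_cases: int = 43
    marker_signal_location: float = 200.0
    marker_noise_location: float = 10.0
    #: mixture weight of the shifted (signal) component in case stools;
    #: tunes per-marker sensitivity at high specificity
    marker_case_positive_fraction: float = 0.6
    fit_case_location: float = 400.0
    fit_control_location: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for pair, name in (
            (self.beta_params_unmeth, "beta_params_unmeth"),
            (self.beta_params_meth, "beta_params_meth"),
        ):
            if min(pair) <= 0:
                raise ValueError(f"{name} shape parameters must be > 0")
        if self.expr_fold_change <= 0:
            raise ValueError("expr_fold_change must be > 0")
        if self.expr_log_sd <= 0:
            raise ValueError("expr_log_sd must be > 0")
        for n, name in (
            (self.n_normal, "n_normal"),
            (self.n_tissue_normal, "n_tissue_normal"),
            (self.n_probes_per_gene, "n_probes_per_gene"),
            (self.n_genes, "n_genes"),
            (self.n_expr_normal, "n_expr_normal"),
        ):
            if n < 1:
                raise ValueError(f"{name} must be >= 1")
        if any(n < 0 for n in self.n_tumor_per_stage.values()):
            raise ValueError("per-stage tumor counts must be >= 0")
        if sum(self.n_tumor_per_stage.values()) < 1:
            raise ValueError("at least one tumor sample is required")
        unknown = set(self.decoy_counts) - set(DECOY_CLASSES)
        if unknown:
            raise ValueError(f"unknown decoy classes: {sorted(unknown)}")
        n_planted = self.n_true_markers + sum(self.decoy_counts.values())
        if n_planted > self.n_genes:
            raise ValueError("planted classes exceed n_genes")
        if not 0.0 <= self.marker_case_positive_fraction <= 1.0:
            raise ValueError("marker_case_positive_fraction must be in [0, 1]")
        if self.marker_signal_location < 0 or self.marker_noise_location < 0:
            raise ValueError("stool marker locations must be >= 0")


@dataclass
class TruthLabels:
    """Planted class per gene; every simulated gene has exactly one class."""

    classes: dict[str, str]

    def __post_init__(self) -> None:
        bad = set(self.classes.values()) - set(GENE_CLASSES)
        if bad:
            raise ValueError(f"unknown gene classes: {sorted(bad)}")

    def genes_of(self, cls: str) -> list[str]:
        return sorted(g for g, c in self.classes.items() if c == cls)

    @property
    def true_markers(self) -> list[str]:
        return self.genes_of("true_marker")


def _assign_classes(config: SimulationConfig) -> dict[str, str]:
    labels: list[str] = ["true_marker"] * config.n_true_markers
    for cls in DECOY_CLASSES:
        labels += [cls] * config.decoy_counts.get(cls, 0)
    labels += ["null"] * (config.n_genes - len(labels))
    genes = [f"GENE{i:04d}" for i in range(1, config.n_genes + 1)]
    return dict(zip(genes, labels))


def _gene_layout(config: SimulationConfig, truth: dict[str, str]):
    """Probe coordinates: one synthetic chromosome per gene, TSS at a fixed
    offset, strand '+'. Promoter probes sit 100 bp apart starting at
    TSS-200 (pairwise within 750 bp for realistic probe counts); isolated
    decoys get exactly one promoter-island probe, their remaining probes
    placed far downstream of the promoter window."""
    tss = 100_000
    records = []
    for gi, (gene, cls) in enumerate(truth.items()):
        chrom = f"chr_{gene}"
        n_p = config.n_probes_per_gene
        if cls == "decoy_isolated_probe":
            offsets = [0] + [2_000 + 5_000 * j for j in range(n_p - 1)]
        else:
            offsets = [-200 + 100 * j for j in range(n_p)]
        for pi, off in enumerate(offsets):
            records.append(
                {
                    "probe_id": f"cg_{gene}_{pi:02d}",
                    "chromosome": chrom,
                    "position": tss + off,
                    "gene": gene,
                    "tss_position": tss,
                    "strand": "+",
                    "in_cpg_island": True,
                }
            )
    return make_annotation(records)


def _beta_draw(rng: np.random.Generator, params: tuple[float, float], size) -> np.ndarray:
    return rng.beta(params[0], params[1], size=size)


def simulate_methylation_cohort(
    config: SimulationConfig,
) -> tuple[BetaCohort, dict[str, BetaCohort], pd.DataFrame, TruthLabels]:
    """Colon beta cohort, per-tissue normal beta cohorts, probe annotation
    and the planted truth labels."""
    truth_map = _assign_classes(config)
    truth = TruthLabels(truth_map)
    annotation = _gene_layout(config, truth_map)
    rng = np.random.default_rng(config.seed)

    normal_ids = [f"N{i:03d}" for i in range(1, config.n_normal + 1)]
    tumor_meta, tumor_ids = [], []
    k = 0
    for stage in ("I", "II", "III", "IV"):
        for _ in range(config.n_tumor_per_stage.get(stage, 0)):
            k += 1
            sid = f"T{k:03d}"
            tumor_ids.append(sid)
            tumor_meta.append({"sample_id": sid, "tissue": "colon", "group": TUMOR, "stage": stage})
    meta = pd.DataFrame(
        [{"sample_id": s, "tissue": "colon", "group": NORMAL, "stage": "NA"} for s in normal_ids]
        + tumor_meta
    )
    stage_of = {r["sample_id"]: r["stage"] for r in tumor_meta}
    late = np.array([stage_of[s] in ("III", "IV") for s in tumor_ids])

    un, me = config.beta_params_unmeth, config.beta_params_meth
    n_probes = len(annotation)
    probe_ids = list(annotation["probe_id"])
    gene_of = annotation["gene"].to_dict()

    colon = np.empty((n_probes, len(normal_ids) + len(tumor_ids)))
    for i, probe in enumerate(probe_ids):
        cls = truth_map[gene_of[probe]]
        norm_params = me if cls == "decoy_methylated_in_colon_normals" else un
        colon[i, : len(normal_ids)] = _beta_draw(rng, norm_params, len(normal_ids))
        if cls in ("true_marker", "decoy_methylated_in_other_tissue_normals",
                   "decoy_not_downregulated", "decoy_isolated_probe",
                   "decoy_methylated_in_colon_normals"):
            tvals = _beta_draw(rng, me, len(tumor_ids))
        elif cls == "decoy_late_stage_only":
            tvals = _beta_draw(rng, un, len(tumor_ids))
            tvals[late] = _beta_draw(rng, me, int(late.sum()))
        else:  # null
            tvals = _beta_draw(rng, un, len(tumor_ids))
        colon[i, len(normal_ids):] = tvals
    colon_beta = pd.DataFrame(colon, index=probe_ids, columns=normal_ids + tumor_ids)
    colon_cohort = BetaCohort(colon_beta, meta)

    # extra-tissue normals; colon is one of the n_tissues panel members,
    # the remainder come from TISSUE_NAMES
    extra = list(TISSUE_NAMES[: max(0, config.n_tissues - 1)])
    cross_decoys = truth.genes_of("decoy_methylated_in_other_tissue_normals")
    # each cross-tissue decoy is methylated in one designated extra tissue
    decoy_tissue = {g: extra[i % len(extra)] for i, g in enumerate(cross_decoys)} if extra else {}
    tissue_cohorts: dict[str, BetaCohort] = {}
    for tissue in extra:
        ids = [f"{tissue[:4].upper()}{i:03d}" for i in range(1, config.n_tissue_normal + 1)]
        mat = np.empty((n_probes, len(ids)))
        for i, probe in enumerate(probe_ids):
            gene = gene_of[probe]
            params = me if decoy_tissue.get(gene) == tissue else un
            mat[i] = _beta_draw(rng, params, len(ids))
        tmeta = pd.DataFrame(
            [{"sample_id": s, "tissue": tissue, "group": NORMAL, "stage": "NA"} for s in ids]
        )
        tissue_cohorts[tissue] = BetaCohort(
            pd.DataFrame(mat, index=probe_ids, columns=ids), tmeta
        )
    return colon_cohort, tissue_cohorts, annotation, truth


#: classes downregulated in tumor expression
_DOWNREGULATED = {
    "true_marker",
    "decoy_late_stage_only",
    "decoy_methylated_in_other_tissue_normals",
    "decoy_isolated_probe",
    "decoy_methylated_in_colon_normals",
}


def simulate_expression_cohort(
    config: SimulationConfig, truth: TruthLabels
) -> ExpressionCohort:
    """Log-normal expression matrix on a normalized RSEM-like scale; tumor
    samples of downregulated classes divided by ``expr_fold_change``."""
    if config.n_expr_tumor < 1:
        raise ValueError("at least one tumor sample is required")
    rng = np.random.default_rng(config.seed + 1)
    normal_ids = [f"EN{i:03d}" for i in range(1, config.n_expr_normal + 1)]
    stages = ("I", "II", "III", "IV")
    tumor_ids, tumor_meta = [], []
    for k in range(1, config.n_expr_tumor + 1):
        sid = f"ET{k:03d}"
        tumor_ids.append(sid)
        tumor_meta.append(
            {"sample_id": sid, "tissue": "colon", "group": TUMOR, "stage": stages[k % 4]}
        )
    meta = pd.DataFrame(
        [{"sample_id": s, "tissue": "colon", "group": NORMAL, "stage": "NA"} for s in normal_ids]
        + tumor_meta
    )
    genes = sorted(truth.classes)
    mat = np.empty((len(genes), len(normal_ids) + len(tumor_ids)))
    for i, gene in enumerate(genes):
        base = rng.lognormal(config.expr_log_mean, config.expr_log_sd, len(normal_ids) + len(tumor_ids))
        if truth.classes[gene] in _DOWNREGULATED:
            base[len(normal_ids):] /= config.expr_fold_change
        mat[i] = base
    expr = pd.DataFrame(mat, index=genes, columns=normal_ids + tumor_ids)
    return ExpressionCohort(expr, meta)


def simulate_stool_study(
    config: SimulationConfig, marker_names: list[str]
) -> StoolStudy:
    """Stool study with continuous qMSP signals, FIT values and covariates.

    Control markers draw pure background noise (gamma, mean
    ``marker_noise_location``); case markers draw, with probability
    ``marker_case_positive_fraction``, a log-normal signal centered at
    ``marker_signal_location`` and otherwise the control noise, producing
    a right-shifted mixture whose sensitivity at high specificity is
    tunable. FIT values behave analogously on the ng Hb/ml scale.
    """
    if not marker_names:
        raise ValueError("at least one marker is required")
    rng = np.random.default_rng(config.seed + 2)
    n_ctrl, n_case = config.stool_n_controls, config.stool_n_cases
    labels = ["control"] * n_ctrl + ["case"] * n_case

    def noise(n, location):
        if location == 0:
            return np.zeros(n)
        return rng.gamma(2.0, location / 2.0, size=n)

    rows: dict[str, np.ndarray] = {}
    for m in marker_names:
        ctrl = noise(n_ctrl, config.marker_noise_location)
        case = noise(n_case, config.marker_noise_location)
        if config.marker_signal_location > 0:
            sig = rng.lognormal(np.log(config.marker_signal_location), 0.5, n_case)
            pos = rng.random(n_case) < config.marker_case_positive_fraction
            case = np.where(pos, case + sig, case)
        rows[m] = np.concatenate([ctrl, case])

    fit_ctrl = noise(n_ctrl, config.fit_control_location)
    if config.fit_case_location > 0:
        fit_case = rng.lognormal(np.log(config.fit_case_location), 2.0, n_case)
    else:
        fit_case = noise(n_case, config.fit_control_location)
    fit = np.concatenate([fit_ctrl, fit_case])

    sex = np.concatenate([
        rng.choice(["M", "F"], n_ctrl, p=[0.48, 0.52]),
        rng.choice(["M", "F"], n_case, p=[0.67, 0.33]),
    ])
    age = np.concatenate([
        rng.normal(55.5, 3.7, n_ctrl),
        rng.normal(70.5, 10.5, n_case),
    ]).round(1)
    stage = np.concatenate([
        np.repeat("NA", n_ctrl),
        rng.choice(["II", "III", "IV"], n_case, p=[0.18, 0.58, 0.24]),
    ])
    location = np.concatenate([
        np.repeat("NA", n_ctrl),
        rng.choice(["proximal", "distal", "unknown"], n_case, p=[0.34, 0.59, 0.07]),
    ])
    table = pd.DataFrame(
        {
            "subject_id": [f"S{i:03d}" for i in range(1, n_ctrl + n_case + 1)],
            "label": labels,
            "fit_value": fit,
            "sex": sex,
            "age": age,
            "stage": stage,
            "location": location,
            **rows,
        }
    )
    return StoolStudy(table, marker_names=list(marker_names))


_NEURONAL_NAME_STEMS = (
    "axon guidance", "synapse assembly", "neuron differentiation",
    "dendritic spine organization", "synaptic vesicle cycle",
    "nervous system development", "learning or memory", "brain morphogenesis",
    "neural crest migration", "hippocampus development",
)
_NEUTRAL_NAME_STEMS = (
    "lipid metabolic process", "cell cycle checkpoint", "ion transport",
    "protein folding", "DNA repair", "immune response regulation",
    "angiogenesis", "ribosome biogenesis", "glycolytic process",
    "chromatin remodeling",
)


def simulate_ontology(
    n_terms: int,
    n_neuronal: int,
    gene_universe: list[str],
    enrichment_strength: float = 1.0,
    seed: int = 0,
    n_target: int | None = None,
    annotations_per_gene: int = 5,
) -> tuple[OntologyCatalogue, set[str]]:
    """Term catalogue, gene annotations and a planted target gene set.

    Exactly ``n_neuronal`` term names contain a neuronal keyword. Each gene
    is annotated to ``annotations_per_gene`` terms sampled without
    replacement; for planted target genes the odds of picking a neuronal
    term are multiplied by ``enrichment_strength`` (1 = no enrichment).
    """
    if not gene_universe:
        raise ValueError("gene universe must be non-empty")
    if n_neuronal > n_terms:
        raise ValueError("n_neuronal cannot exceed n_terms")
    if enrichment_strength <= 0:
        raise ValueError("enrichment_strength must be > 0")
    rng = np.random.default_rng(seed)
    terms: dict[str, tuple[str, str]] = {}
    neuronal_flags = np.zeros(n_terms, dtype=bool)
    for i in range(n_terms):
        tid = f"GO:{i + 1:07d}"
        if i < n_neuronal:
            stem = _NEURONAL_NAME_STEMS[i % len(_NEURONAL_NAME_STEMS)]
            name = f"{stem} variant {i + 1}"
            neuronal_flags[i] = True
        else:
            stem = _NEUTRAL_NAME_STEMS[i % len(_NEUTRAL_NAME_STEMS)]
            name = f"{stem} variant {i + 1}"
        terms[tid] = (name, "biological_process")

    universe = list(gene_universe)
    if n_target is None:
        n_target = max(5, len(universe) // 10)
    target = set(rng.choice(universe, size=min(n_target, len(universe)), replace=False))

    term_ids = np.array(list(terms))
    base_w = np.ones(n_terms)
    target_w = np.where(neuronal_flags, enrichment_strength, 1.0)
    k = min(annotations_per_gene, n_terms)
    annotations: dict[str, set[str]] = {}
    for gene in universe:
        w = target_w if gene in target else base_w
        p = w / w.sum()
        chosen = rng.choice(term_ids, size=k, replace=False, p=p)
        annotations[gene] = set(chosen)
    return OntologyCatalogue(terms=terms, annotations=annotations), target
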