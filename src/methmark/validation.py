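"""Planted-truth audits of the discovery cascade.

These helpers rerun the cascade on simulated data and check, per
replicate, that every planted decoy class is eliminated at the filter it
was designed to defeat and that the final candidate list recovers the
true markers exactly. They are the package's own end-to-end calibration
instruments (parameter-recovery and null-calibration experiments run on
the synthetic generator).
"""

from __future__ import annotations

from dataclasses import replace

from .discovery import (
    DiscoveryParams,
    cross_tissue_specificity_filter,
    differential_expression,
    differential_methylation,
    filter_unmethylated_in_normal,
    proximity_filter,
    select_promoter_island_probes,
    sensitivity_at_full_specificity,
)
from .simulate import (
    SimulationConfig,
    simulate_expression_cohort,
    simulate_methylation_cohort,
)

__all__ = ["audit_discovery_replicate", "run_recovery_study", "null_methylation_rate"]


def audit_discovery_replicate(
    config: SimulationConfig, params: DiscoveryParams | None = None
) -> dict:
    """Run the cascade on one simulated study and report, per decoy class,
    whether it was eliminated at its designated filter, plus whether the
    final candidate list equals the planted true markers exactly."""
    params = params or DiscoveryParams()
    colon, tissues, ann, truth = simulate_methylation_cohort(config)
    expr = simulate_expression_cohort(config, truth)
    gene_of = ann["gene"]

    def probes_of(genes) -> set[str]:
        return set(ann.index[gene_of.isin(set(genes))])

    promoter = select_promoter_island_probes(
        ann, params.promoter_upstream_bp, params.promoter_downstream_bp
    )
    unmeth = filter_unmethylated_in_normal(colon, promoter, params.unmeth_median_threshold)
    stage_sets = differential_methylation(colon, unmeth, params)
    proximal = {
        label: proximity_filter(s, ann, params.proximity_window_bp)
        for label, s in stage_sets.items()
    }
    combined = set.intersection(*proximal.values())
    down = differential_expression(expr, params)
    with_expr = {p for p in combined if gene_of.loc[p] in down}
    specific = cross_tissue_specificity_filter(tissues, with_expr, params)

    colon_decoy = probes_of(truth.genes_of("decoy_methylated_in_colon_normals"))
    late_decoy = probes_of(truth.genes_of("decoy_late_stage_only"))
    iso_genes = truth.genes_of("decoy_isolated_probe")
    iso_promoter = probes_of(iso_genes) & promoter
    notdown_genes = set(truth.genes_of("decoy_not_downregulated"))
    cross_decoy = probes_of(truth.genes_of("decoy_methylated_in_other_tissue_normals"))

    surviving_genes = {gene_of.loc[p] for p in specific}
    eliminated = {
        # reached the filter, removed by it
        "decoy_methylated_in_colon_normals": bool(colon_decoy)
        and colon_decoy <= promoter
        and not colon_decoy & unmeth,
        "decoy_late_stage_only": bool(late_decoy)
        and not late_decoy & stage_sets["I/II"],
        "decoy_isolated_probe": bool(iso_promoter)
        and not iso_promoter & (proximal["I/II"] | proximal["III/IV"]),
        "decoy_not_downregulated": bool(notdown_genes) and not notdown_genes & down,
        "decoy_methylated_in_other_tissue_normals": bool(cross_decoy)
        and not {gene_of.loc[p] for p in cross_decoy} & surviving_genes,
    }
    ranked = sorted(
        surviving_genes,
        key=lambda g: (
            -max(
                sensitivity_at_full_specificity(colon, p)
                for p in specific
                if gene_of.loc[p] == g
            ),
            g,
        ),
    )[: params.top_k]
    return {
        "exact_recovery": set(ranked) == set(truth.true_markers),
        "eliminated": eliminated,
        "n_candidates": len(surviving_genes),
    }


def run_recovery_study(
    base_config: SimulationConfig,
    n_replicates: int = 100,
    params: DiscoveryParams | None = None,
) -> dict:
    """Repeat the audit over seeded replicates; returns recovery and
    per-class elimination rates (fractions in [0, 1])."""
    recoveries = 0
    elim_counts: dict[str, int] = {}
    for r in range(n_replicates):
        cfg = replace(base_config, seed=base_config.seed + r)
        audit = audit_discovery_replicate(cfg, params)
        recoveries += audit["exact_recovery"]
        for cls, ok in audit["eliminated"].items():
            elim_counts[cls] = elim_counts.get(cls, 0) + ok
    return {
        "n_replicates": n_replicates,
        "exact_recovery_rate": recoveries / n_replicates,
        "elimination_rate": {c: k / n_replicates for c, k in elim_counts.items()},
    }


def null_methylation_rate(
    n_replicates: int = 100,
    seed: int = 0,
    n_genes: int = 20,
    params: DiscoveryParams | None = None,
) -> float:
    """Fraction of no-signal replicates in which the FDR-controlled
    differential-methylation stage returns a non-empty probe set.

    Under the null every gene is unmethylated everywhere, so both the FDR
    gate and the median-difference gate must operate at (or below) their
    nominal level.
    """
    params = params or DiscoveryParams()
    nonempty = 0
    for r in range(n_replicates):
        cfg = SimulationConfig(
            n_normal=20,
            n_tumor_per_stage={"I": 10, "II": 10, "III": 10, "IV": 10},
            n_tissues=2,
            n_genes=n_genes,
            n_true_markers=0,
            decoy_counts={},
            seed=seed + r,
        )
        colon, _, ann, _ = simulate_methylation_cohort(cfg)
        promoter = select_promoter_island_probes(ann)
        unmeth = filter_unmethylated_in_normal(colon, promoter, params.unmeth_median_threshold)
        stage_sets = differential_methylation(colon, unmeth, params)
        nonempty += bool(stage_sets["I/II"] | stage_sets["III/IV"])
    return nonempty / n_replicates
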