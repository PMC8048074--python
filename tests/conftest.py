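import pytest

from methmark import (
    SimulationConfig,
    simulate_expression_cohort,
    simulate_methylation_cohort,
)


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Compact strong-effect configuration for fast unit tests (reduced
    sample counts, same effect structure as the defaults)."""
    kwargs = dict(
        n_normal=15,
        n_tumor_per_stage={"I": 8, "II": 8, "III": 8, "IV": 8},
        n_tissues=4,
        n_tissue_normal=40,
        n_probes_per_gene=3,
        n_genes=22,
        n_true_markers=3,
        decoy_counts={
            "decoy_late_stage_only": 2,
            "decoy_methylated_in_other_tissue_normals": 2,
            "decoy_not_downregulated": 2,
            "decoy_isolated_probe": 2,
            "decoy_methylated_in_colon_normals": 2,
        },
        n_expr_normal=20,
        n_expr_tumor=60,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def sim_small():
    """One small simulated study shared across unit tests."""
    config = small_config(seed=11)
    colon, tissues, annotation, truth = simulate_methylation_cohort(config)
    expr = simulate_expression_cohort(config, truth)
    return {
        "config": config,
        "colon": colon,
        "tissues": tissues,
        "annotation": annotation,
        "truth": truth,
        "expr": expr,
    }
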