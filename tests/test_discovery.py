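"""Filter cascade: per-section behavior, decoy elimination, and the
subset/monotonicity invariants."""

import numpy as np
import pandas as pd
import pytest

from methmark import (
    BetaCohort,
    DiscoveryParams,
    make_annotation,
    run_discovery,
)
from methmark.discovery import (
    cross_tissue_specificity_filter,
    differential_expression,
    differential_methylation,
    filter_unmethylated_in_normal,
    proximity_filter,
    select_promoter_island_probes,
    sensitivity_at_full_specificity,
)


def _annotation(rows):
    recs = []
    for i, (pos, tss, strand, island) in enumerate(rows):
        recs.append(
            {
                "probe_id": f"p{i}",
                "chromosome": "chr1",
                "position": pos,
                "gene": "G",
                "tss_position": tss,
                "strand": strand,
                "in_cpg_island": island,
            }
        )
    return make_annotation(recs)


class TestPromoterSelection:
    def test_window_boundaries_inclusive(self):
        ann = _annotation(
            [
                (5000, 5000, "+", True),   # offset 0 -> kept
                (5501, 5000, "+", True),   # offset +501 -> dropped
                (4000, 5000, "+", False),  # offset -1000 but no island -> dropped
                (4000, 5000, "+", True),   # offset -1000 -> kept
                (5500, 5000, "+", True),   # offset +500 -> kept
            ]
        )
        kept = select_promoter_island_probes(ann)
        assert kept == {"p0", "p3", "p4"}

    def test_strand_aware_offset(self):
        # on '-' strand, a position above the TSS is upstream
        ann = _annotation([(5400, 5000, "-", True), (6200, 5000, "-", True)])
        kept = select_promoter_island_probes(ann)
        # offsets: -(5400-5000) = -400 (kept), -(6200-5000) = -1200 (dropped)
        assert kept == {"p0"}

    def test_empty_annotation_rejected(self):
        with pytest.raises(ValueError):
            select_promoter_island_probes(_annotation([]).iloc[:0])


def _beta_cohort(values_by_probe, groups):
    sample_ids = [f"s{i}" for i in range(len(groups))]
    beta = pd.DataFrame(values_by_probe, index=sample_ids).T
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "tissue": "colon",
            "group": groups,
            "stage": ["NA" if g == "normal" else "II" for g in groups],
        }
    )
    return BetaCohort(beta, meta)


class TestUnmethylatedInNormal:
    def test_median_rule_by_hand(self):
        cohort = _beta_cohort(
            {"a": [0.10, 0.15, 0.30], "b": [0.25, 0.10, 0.30], "c": [0.20, 0.20, 0.20]},
            ["normal"] * 3,
        )
        kept = filter_unmethylated_in_normal(cohort, {"a", "b", "c"}, 0.20)
        assert kept == {"a"}  # medians 0.15 kept, 0.25 dropped, 0.20 dropped (strict)

    def test_missing_values_excluded_from_median(self):
        cohort = _beta_cohort({"a": [0.1, np.nan, 0.9]}, ["normal"] * 3)
        kept = filter_unmethylated_in_normal(cohort, {"a"}, 0.20)
        # median of [0.1, 0.9] is 0.5 -> dropped
        assert kept == set()

    def test_no_normals_is_an_error(self):
        cohort = _beta_cohort({"a": [0.1, 0.1]}, ["tumor", "tumor"])
        with pytest.raises(ValueError):
            filter_unmethylated_in_normal(cohort, {"a"}, 0.2)


class TestProximityFilter:
    def test_pairwise_distances(self):
        ann = make_annotation(
            [
                {"probe_id": p, "chromosome": "chr1", "position": pos, "gene": "G",
                 "tss_position": 1, "strand": "+", "in_cpg_island": True}
                for p, pos in [("a", 100), ("b", 700), ("c", 2000)]
            ]
        )
        assert proximity_filter({"a", "b", "c"}, ann, 750) == {"a", "b"}

    def test_singleton_empty_and_inclusive_boundary(self):
        ann = make_annotation(
            [
                {"probe_id": p, "chromosome": "chr1", "position": pos, "gene": "G",
                 "tss_position": 1, "strand": "+", "in_cpg_island": True}
                for p, pos in [("a", 100), ("b", 850)]
            ]
        )
        assert proximity_filter({"a"}, ann, 750) == set()
        assert proximity_filter({"a", "b"}, ann, 750) == {"a", "b"}  # 750 bp apart

    def test_different_chromosomes_never_partner(self):
        ann = make_annotation(
            [
                {"probe_id": "a", "chromosome": "chr1", "position": 100, "gene": "G",
                 "tss_position": 1, "strand": "+", "in_cpg_island": True},
                {"probe_id": "b", "chromosome": "chr2", "position": 150, "gene": "G",
                 "tss_position": 1, "strand": "+", "in_cpg_island": True},
            ]
        )
        assert proximity_filter({"a", "b"}, ann, 750) == set()


class TestSensitivityAtFullSpecificity:
    def test_threshold_is_normal_maximum(self):
        cohort = _beta_cohort(
            {"a": [0.05, 0.10, 0.20, 0.30, 0.05]},
            ["normal", "normal", "tumor", "tumor", "tumor"],
        )
        assert sensitivity_at_full_specificity(cohort, "a") == pytest.approx(2 / 3)

    def test_degenerate_extremes(self):
        low = _beta_cohort({"a": [0.5, 0.4, 0.1]}, ["normal", "normal", "tumor"])
        assert sensitivity_at_full_specificity(low, "a") == 0.0
        high = _beta_cohort({"a": [0.1, 0.2, 0.9]}, ["normal", "normal", "tumor"])
        assert sensitivity_at_full_specificity(high, "a") == 1.0


class TestCrossTissueFilter:
    def _tissue(self, name, fracs_by_probe, n=20):
        vals = {}
        for probe, frac in fracs_by_probe.items():
            k = int(round(frac * n))
            vals[probe] = [0.9] * k + [0.05] * (n - k)
        ids = [f"{name}{i}" for i in range(n)]
        beta = pd.DataFrame(vals, index=ids).T
        meta = pd.DataFrame(
            {"sample_id": ids, "tissue": name, "group": "normal", "stage": "NA"}
        )
        return BetaCohort(beta, meta)

    def test_max_fraction_rule(self):
        params = DiscoveryParams()
        cohorts = {
            "t1": self._tissue("t1", {"a": 0.30, "b": 0.0, "c": 0.25}),
            "t2": self._tissue("t2", {"a": 0.10, "b": 0.0, "c": 0.0}),
            "t3": self._tissue("t3", {"a": 0.00, "b": 0.0, "c": 0.0}),
        }
        kept = cross_tissue_specificity_filter(cohorts, {"a", "b", "c"}, params)
        # a: max 0.30 >= 0.25 dropped; b: all 0 kept; c: exactly 0.25 dropped (strict)
        assert kept == {"b"}

    def test_missing_probe_named_in_error(self):
        params = DiscoveryParams()
        cohorts = {"t1": self._tissue("t1", {"a": 0.0})}
        with pytest.raises(ValueError, match="t1"):
            cross_tissue_specificity_filter(cohorts, {"a", "zz"}, params)


class TestCascadeOnSimulation:
    """Each decoy class is eliminated by exactly its designated filter."""

    def test_colon_normal_decoy_fails_unmethylated_filter(self, sim_small):
        colon, ann, truth = sim_small["colon"], sim_small["annotation"], sim_small["truth"]
        promoter = select_promoter_island_probes(ann)
        kept = filter_unmethylated_in_normal(colon, promoter, 0.20)
        decoy_probes = set(ann.index[ann["gene"].isin(truth.genes_of("decoy_methylated_in_colon_normals"))])
        assert decoy_probes & promoter
        assert not decoy_probes & kept

    def test_late_stage_decoy_fails_early_stage_comparison(self, sim_small):
        colon, ann, truth = sim_small["colon"], sim_small["annotation"], sim_small["truth"]
        params = DiscoveryParams()
        promoter = select_promoter_island_probes(ann)
        unmeth = filter_unmethylated_in_normal(colon, promoter, 0.20)
        stage_sets = differential_methylation(colon, unmeth, params)
        late_probes = set(ann.index[ann["gene"].isin(truth.genes_of("decoy_late_stage_only"))])
        assert late_probes <= stage_sets["III/IV"]
        assert not late_probes & stage_sets["I/II"]

    def test_true_marker_retained_in_both_comparisons(self, sim_small):
        colon, ann, truth = sim_small["colon"], sim_small["annotation"], sim_small["truth"]
        params = DiscoveryParams()
        promoter = select_promoter_island_probes(ann)
        unmeth = filter_unmethylated_in_normal(colon, promoter, 0.20)
        stage_sets = differential_methylation(colon, unmeth, params)
        true_probes = set(ann.index[ann["gene"].isin(truth.true_markers)])
        assert true_probes <= stage_sets["I/II"]
        assert true_probes <= stage_sets["III/IV"]

    def test_isolated_probe_decoy_fails_proximity(self, sim_small):
        ann, truth = sim_small["annotation"], sim_small["truth"]
        isolated_genes = truth.genes_of("decoy_isolated_probe")
        promoter = select_promoter_island_probes(ann)
        iso_promoter = {
            p for p in promoter if ann.loc[p, "gene"] in isolated_genes
        }
        # exactly one promoter-island probe per isolated gene by construction
        assert len(iso_promoter) == len(isolated_genes)
        assert proximity_filter(iso_promoter, ann, 750) == set()

    def test_not_downregulated_decoy_fails_expression(self, sim_small):
        expr, truth = sim_small["expr"], sim_small["truth"]
        down = differential_expression(expr, DiscoveryParams())
        assert set(truth.true_markers) <= down
        assert not set(truth.genes_of("decoy_not_downregulated")) & down

    def test_full_pipeline_recovers_exactly_true_markers(self, sim_small):
        report = run_discovery(
            sim_small["colon"], sim_small["tissues"], sim_small["expr"],
            sim_small["annotation"], DiscoveryParams(),
        )
        assert set(report.top_genes) == set(sim_small["truth"].true_markers)

    def test_probe_counts_monotone_through_filter_sections(self, sim_small):
        report = run_discovery(
            sim_small["colon"], sim_small["tissues"], sim_small["expr"],
            sim_small["annotation"], DiscoveryParams(),
        )
        seq = [
            report.section_counts[k]["probes"]
            for k in (
                "1_promoter_island",
                "1_unmethylated_in_normal",
                "2_proximity_and_stage_combined",
                "3_methylated_and_downregulated",
                "4_cross_tissue_specific",
            )
        ]
        assert all(a >= b for a, b in zip(seq, seq[1:]))

    def test_zero_fdr_threshold_empties_candidates(self, sim_small):
        params = DiscoveryParams(fdr_threshold=1e-300)
        report = run_discovery(
            sim_small["colon"], sim_small["tissues"], sim_small["expr"],
            sim_small["annotation"], params,
        )
        assert report.top_genes == []


class TestDifferentialMethylationGates:
    def test_effect_size_gate_blocks_small_gaps(self):
        # strongly significant shift but median gap only ~0.10: dropped
        rng = np.random.default_rng(0)
        n = 30
        normals = rng.uniform(0.02, 0.06, n)
        tumors = rng.uniform(0.12, 0.16, 2 * n)
        groups = ["normal"] * n + ["tumor"] * 2 * n
        cohort = _beta_cohort({"a": np.concatenate([normals, tumors])}, groups)
        # stage assignment: half II, half III so both comparisons run
        cohort.samples.loc[cohort.samples["group"] == "tumor", "stage"] = (
            ["II"] * n + ["III"] * n
        )
        sets = differential_methylation(cohort, {"a"}, DiscoveryParams())
        assert sets["I/II"] == set() and sets["III/IV"] == set()

    def test_constant_gene_excluded_from_expression(self, sim_small):
        expr = sim_small["expr"]
        const = expr.expr.copy()
        const.loc[:] = 5.0
        from methmark import ExpressionCohort

        cohort = ExpressionCohort(const, expr.samples.reset_index(drop=True))
        assert differential_expression(cohort, DiscoveryParams()) == set()
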