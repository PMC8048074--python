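# Methods

## The discovery model

The cascade treats a candidate CRC methylation marker as a promoter
CpG-island locus that is (i) essentially unmethylated in normal colon,
(ii) strongly hypermethylated in tumors of *every* stage, (iii) supported
by at least two nearby array probes, (iv) transcriptionally silenced in
tumors, and (v) unmethylated in the normal tissue of other organs (so a
stool or plasma signal is colon-tumor specific). Each requirement maps to
one filter:

| section | rule | default |
|---|---|---|
| promoter/island | strand-aware TSS offset in [−1000, +500] bp (inclusive) and CpG-island membership | — |
| unmethylated in normal | median β over colon normals strictly < threshold | 0.20 |
| differential methylation | one-sided shifted rank-sum, tumors exceed normals by more than \|μ\|; BH-FDR < q AND median(normal) − median(tumor) < δ | μ = −0.25, q = 0.05, δ = −0.25 |
| proximity | another significant probe within w bp (inclusive) on the same chromosome | w = 750 |
| expression | one-sided shifted rank-sum, normals exceed tumors by more than μₑ on the normalized scale; BH-FDR < q | μₑ = 1 |
| cross-tissue | max over tissues of the fraction of normal samples with β > 0.20 strictly < f | f = 0.25 |
| ranking | per gene, max over surviving probes of sensitivity at 100 % specificity; top k, ties by gene name | k = 20 |

Differential methylation is evaluated separately against stage I/II and
stage III/IV tumors; because an early-detection marker must flag all
stages, the two proximity-filtered significant sets are **intersected**
by default (`stage_combination="union"` is available). The intersection
with downregulated genes happens at gene level: probes of
non-downregulated genes are removed.

### The shifted rank-sum test

`shifted_rank_sum_test(reference, alternative, shift, direction)` tests
H₀: the alternative group's location exceeds the reference's by exactly
`shift` by subtracting the shift from the alternative sample and ranking
(the standard μ-parameterized Mann–Whitney construction). Exact
enumeration is used when the combined sample is ≤ 12 tie-free values,
otherwise the normal approximation with tie and continuity correction.
With shift 0 this is the classical one-sided Mann–Whitney test; the test
suite verifies agreement with a full enumeration oracle over every
two-group split of up to 10 values.

The expression shift μₑ = 1 is applied on the raw normalized scale (no
log transform). This is only a meaningful margin when candidate genes are
lowly expressed — which holds for the nervous-system genes this analysis
targets in colorectal tissue — and the simulator's expression scale is
chosen accordingly (below).

## Diagnostic statistics

* **AUC** is the concordance probability with ties counted ½, identical
  to U/(n₁n₂); the 95 % CI uses the DeLong placement-variance normal
  approximation (a seeded bootstrap percentile interval is available).
* **Cutoffs** maximize LR⁺ over the unique observed values; a sample is
  positive strictly above the cutoff. Zero-false-positive cutoffs give
  LR⁺ = +∞ and win only when sensitivity > 0; ties break by higher
  sensitivity, then lower cutoff.
* **Binomial CIs**: exact Clopper–Pearson (beta quantiles) by default;
  Wald (p̂ ± z·√(p̂(1−p̂)/n), truncated) is provided because published
  panel/FIT intervals follow it. The method used is always recorded.
* **Panels** follow the any-positive rule; subjects missing a member
  value are excluded from that panel only. All (2^m − 1) subsets are
  evaluated with and without FIT, plus FIT alone, ranked by specificity
  tier, then sensitivity, then fewer markers, then name. FIT is positive
  at ≥ 50 ng Hb/ml (configurable).
* **Cutoff-free panels** use a maximum-likelihood logistic combination;
  exactly duplicated marker columns are collapsed first, and
  non-convergence (e.g. perfect separation) raises `ConvergenceError`
  rather than returning a silent fit.

## Association tests

The exact McNemar test is the default for paired tumor/normal calls
because discordant counts in small tissue series are far below the χ²
regime (the χ² approximation is available behind a flag). When only
marginal frequencies are published, `worst_case_mcnemar_from_marginals`
maximizes the exact p over every consistent pairing (the least favourable
pairing puts no pair in the both-positive cell, inflating balanced
discordance); a small bound is therefore pairing-proof. Contingency
tables use Pearson χ² without continuity correction (this reproduces
published stage-association p-values); `auto` mode switches to Fisher for
sparse 2×2 tables. Rows/columns labelled `unknown` are dropped before
testing. Two-group continuous comparisons use the equal-variance t test,
more groups one-way ANOVA.

## Enrichment

Per-term over-representation is the upper-tail hypergeometric probability
of the observed target/term overlap given the background universe,
BH-FDR corrected; term sizes are computed within the background. No
ontology-graph propagation is applied — the catalogue is taken as a flat
term→gene map (parent propagation can be done upstream when `is_a` edges
are available). Keyword classification matches 13 nervous-system
substrings case-insensitively against term *names* only. The Fisher
frequency comparison of neuronal terms in the enriched set versus the
complete catalogue is reported descriptively, without multiplicity
correction: ontology terms share genes hierarchically and are not
independent, so its p-value is an effect summary, not a calibrated test.

## The synthetic generator

`SimulationConfig` defaults encode the study conditions: 37 colon
normals; 73/73/58/58 tumors per stage (146 stage I/II, 116 stage III/IV);
expression on 41 normals / 285 tumors; a 14-tissue specificity panel;
stool cohorts of 50 controls / 43 cases. Choices the source data leave
open were fixed once on realism grounds:

* **β values** draw from Beta(1, 9) (unmethylated, mean 0.1) and
  Beta(9, 1) (methylated, mean 0.9) — the bimodal β convention.
* **Per-tissue normal counts** are 80. Beta(1, 9) puts 13.4 % of its mass
  above β = 0.20, so the strict `< 25 % methylated` pan-tissue rule needs
  enough samples per tissue for the empirical fraction to concentrate;
  at 80 samples the spurious gene-level loss of a true marker is ~10⁻⁴.
* **Expression** is log-normal with log-mean 1.5 and log-sd 0.5 (median
  ≈ 4.5 on the normalized scale, tumors divided by a fold change of 4 for
  silenced classes). The low scale reflects lowly expressed neuronal
  genes in colorectal tissue and makes the μₑ = 1 shift an actual margin,
  so equal-distribution decoys are rejected essentially surely rather
  than at the nominal FDR rate.
* **Stool signals**: controls draw gamma background noise (mean
  10 copies/µl); cases add, with probability 0.6, a log-normal signal at
  200 copies/µl — a right-shifted mixture whose positive fraction tunes
  sensitivity at high specificity. FIT behaves analogously
  (control mean 5, case median 400 ng Hb/ml).
* **Geometry**: one synthetic chromosome per gene, TSS fixed, strand
  always '+', promoter probes 100 bp apart; isolated-probe decoys have
  exactly one promoter-island probe with the rest far downstream.

One seed drives every generator (sub-streams are derived with fixed
offsets), and identical configurations produce byte-identical output.

What the generator does **not** emulate: probe–probe correlation
(neighboring CpGs in real arrays are strongly correlated), batch and
purity effects, missing values, non-β measurement error, realistic
ontology topology. Passing recovery tests therefore demonstrates that the
cascade's filters reject exactly what they claim to reject under clean
planted signals — not that the thresholds are optimal for real 450k data.

## Numerical choices and edge cases

* Window and proximity bounds are inclusive; the β thresholds
  (median < 0.20, fraction < 25 %) are strict, matching the published
  wording.
* Median-β differences use the convention median(normal) −
  median(tumor) < −0.25 (tumor hypermethylated).
* Probes/genes are tested only when ≥ 3 non-missing values remain per
  group; missing values are dropped pairwise.
* BH-FDR is computed within each tested probe/gene set.
* Constant genes yield p = 1 under the tie policy and are never called.
* `worst_case_mcnemar_from_marginals` enumerates every feasible
  both-positive count; mcnemar p is capped at 1.

## Validation instruments

`methmark.validation` reruns the cascade on seeded replicates and
reports: the exact-recovery rate (candidate list equals the planted true
markers), per-decoy-class elimination-at-designated-filter rates, and the
no-signal false-alarm rate of the differential-methylation stage. The
acceptance script runs these at 100 replicates (~40 s on one CPU) along
with the deterministic confidence-interval and McNemar-bound
recomputations; the test suite runs the same checks plus
enumeration-oracle equivalences for every statistical primitive.

## Known limitations

* The DeLong CI is asymptotic; at very small n or AUC near 1 the
  truncated interval is conservative.
* The logistic panel score is a stand-in for whichever multivariate
  combination a given study used without predetermined cutoffs; its AUC
  is not expected to reproduce published cutoff-free panel AUCs.
* The OBO ecosystem is deliberately out of scope: catalogues enter as
  TSV (terms + annotations), and graph-aware enrichment should be done
  with dedicated tooling.
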