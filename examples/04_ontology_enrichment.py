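"""Term enrichment of a candidate gene set and the neuronal-keyword
frequency comparison.

A synthetic ontology plants a target gene set preferentially annotated to
nervous system-related terms. Hypergeometric over-representation (BH-FDR)
finds the enriched terms; keyword matching classifies term names as
neuronal; Fisher's exact test compares the neuronal frequency among
enriched terms with the whole catalogue.
"""

from methmark import (
    classify_neuronal,
    hypergeometric_enrichment,
    neuronal_frequency_test,
    simulate_ontology,
)

universe = [f"gene{i:03d}" for i in range(300)]
catalogue, target = simulate_ontology(
    n_terms=200, n_neuronal=12, gene_universe=universe,
    enrichment_strength=30.0, seed=1, n_target=40,
)

table = hypergeometric_enrichment(target, set(universe), catalogue, alpha=0.05)
enriched = table[table["enriched"]].copy()
enriched["neuronal"] = classify_neuronal(enriched["name"])
print(f"{len(enriched)} of {len(table)} terms enriched at q < 0.05; top 5:")
print(enriched[["term_id", "name", "overlap", "expected", "p", "q"]]
      .head(5).to_string(index=False))

all_names = [name for name, _ns in catalogue.terms.values()]
n_neuronal_all = int(classify_neuronal(all_names).sum())
res = neuronal_frequency_test(
    int(enriched["neuronal"].sum()), len(enriched),
    n_neuronal_all, len(catalogue.terms),
)
print(f"\nneuronal terms: {res['enriched_fraction']:.1%} of the enriched set "
      f"vs {res['complete_fraction']:.1%} of the catalogue "
      f"(odds ratio {res['odds_ratio']:.1f}, Fisher p = {res['p']:.2e})")
# 'overlap' vs 'expected' shows how many target genes hit each term against
# chance; the frequency test quantifies how strongly neuronal terms
# dominate the enriched list.
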