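"""Ontology-term enrichment and neuronal keyword analysis.

Over-representation of ontology terms in a candidate gene set is tested
against a background universe with the upper-tail hypergeometric
distribution, BH-FDR corrected. Term names are classified as nervous
system related by case-insensitive keyword matching, and the frequency of
neuronal terms among the enriched set is compared with their frequency in
the complete catalogue by Fisher's exact test. Because ontology terms
share genes through the term hierarchy they are not independent, so the
frequency comparison is descriptive and no multiplicity correction is
applied to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .discovery import bh_fdr

__all__ = [
    "NEURONAL_KEYWORDS",
    "OntologyCatalogue",
    "hypergeometric_enrichment",
    "classify_neuronal",
    "neuronal_frequency_test",
]

#: keywords marking a term name as nervous system related
NEURONAL_KEYWORDS: tuple[str, ...] = (
    "neuro",
    "neuron",
    "neuronal",
    "neural",
    "nervous",
    "axon",
    "dendritic",
    "synaptic",
    "synapse",
    "learning",
    "memory",
    "brain",
    "hippocampus",
)

NAMESPACES = ("biological_process", "cellular_component", "molecular_function")


@dataclass
class OntologyCatalogue:
    """Term catalogue plus gene -> term annotations.

    ``terms`` maps term_id -> (name, namespace); ``annotations`` maps
    gene -> set of term_ids.
    """

    terms: dict[str, tuple[str, str]]
    annotations: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = {
            t for ts in self.annotations.values() for t in ts if t not in self.terms
        }
        if unknown:
            raise ValueError(f"annotations reference uncatalogued terms: {sorted(unknown)[:5]}")

    def term_genes(self) -> dict[str, set[str]]:
        by_term: dict[str, set[str]] = {t: set() for t in self.terms}
        for gene, ts in self.annotations.items():
            for t in ts:
                by_term[t].add(gene)
        return by_term

    def names(self) -> pd.Series:
        return pd.Series({t: name for t, (name, _ns) in self.terms.items()})


def hypergeometric_enrichment(
    target: set[str],
    background: set[str],
    catalogue: OntologyCatalogue,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-term over-representation of ``target`` within ``background``.

    p is the upper-tail hypergeometric probability of observing at least
    the seen overlap given the term's annotated-gene count (restricted to
    the background), the target size and the background size; q is the
    BH-FDR adjusted value. Returns a table sorted by p with an ``enriched``
    flag (q < alpha).
    """
    target = set(target)
    background = set(background)
    strays = target - background
    if strays:
        raise ValueError(f"target genes outside the background: {sorted(strays)[:10]}")
    N = len(background)
    n = len(target)
    rows = []
    for term, genes in catalogue.term_genes().items():
        in_bg = genes & background
        K = len(in_bg)
        if K == 0:
            continue
        k = len(in_bg & target)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        name, ns = catalogue.terms[term]
        rows.append(
            {
                "term_id": term,
                "name": name,
                "namespace": ns,
                "term_size": K,
                "overlap": k,
                "expected": K * n / N,
                "p": min(1.0, p),
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        table["q"] = []
        table["enriched"] = []
        return table
    table["q"] = bh_fdr(table["p"].to_numpy())
    table["enriched"] = table["q"] < alpha
    return table.sort_values(["p", "term_id"]).reset_index(drop=True)


def classify_neuronal(term_names, keywords=NEURONAL_KEYWORDS) -> np.ndarray:
    """True where any keyword occurs as a case-insensitive substring of the
    term name."""
    kws = [k.lower() for k in keywords]
    if not kws:
        raise ValueError("keyword set must be non-empty")
    return np.array([any(k in str(name).lower() for k in kws) for name in term_names])


def neuronal_frequency_test(
    enriched_neuronal: int,
    enriched_total: int,
    complete_neuronal: int,
    complete_total: int,
) -> dict:
    """Two-sided Fisher's exact comparison of the neuronal-term frequency in
    the enriched set versus the complete catalogue.

    Returns the two frequencies, the sample odds ratio and the p-value.
    """
    if enriched_total <= 0 or complete_total <= 0:
        raise ValueError("set totals must be positive")
    if not (0 <= enriched_neuronal <= enriched_total):
        raise ValueError("enriched counts inconsistent")
    if not (0 <= complete_neuronal <= complete_total):
        raise ValueError("complete-set counts inconsistent")
    table = np.array(
        [
            [enriched_neuronal, enriched_total - enriched_neuronal],
            [complete_neuronal, complete_total - complete_neuronal],
        ]
    )
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return {
        "enriched_fraction": enriched_neuronal / enriched_total,
        "complete_fraction": complete_neuronal / complete_total,
        "odds_ratio": float(odds),
        "p": float(p),
    }
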