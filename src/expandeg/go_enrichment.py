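"""Family-level GO over-representation on flat annotations.

A family's annotation is the union of the GO terms of its member genes
across all species. Each term present in the subset is tested with a
one-sided over-representation test (Fisher / hypergeometric upper tail)
against the background of conserved families. Following the source
analysis' reporting filters, a term is flagged `reported` when p < 0.05
(strict) AND it annotates at least two subset families. No GO-DAG
propagation or decorrelation is applied: terms are opaque ids.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .core_model import ConservedSet
from .enrichment_stats import hypergeom_over

__all__ = ["union_annotate", "go_over_representation"]


def union_annotate(
    conserved: ConservedSet,
    gene_to_terms: Mapping[tuple[str, str], frozenset[str]],
) -> dict[str, frozenset[str]]:
    """Per-family union of member-gene GO terms ((species, gene) keyed map);
    unannotated genes contribute nothing, so a family may map to the empty
    set."""
    out: dict[str, set[str]] = {h: set() for h in conserved.hog_ids}
    for hog, sp, gene in conserved.table.genes.itertuples(index=False):
        terms = gene_to_terms.get((sp, gene))
        if terms:
            out[hog].update(terms)
    return {h: frozenset(t) for h, t in out.items()}


def go_over_representation(
    subset_hogs: Iterable[str],
    background_hogs: Iterable[str],
    annotation: Mapping[str, frozenset[str]],
    p_threshold: float = 0.05,
    min_subset_count: int = 2,
) -> pd.DataFrame:
    """Term-by-term over-representation of subset families vs background.

    Background families without annotation still count toward N (they are
    genuine draws that lack the term). Returns one row per term present in
    the subset: (term, k, n, K, N, p_value, reported), sorted by p then
    term id.
    """
    background = list(dict.fromkeys(background_hogs))
    subset = list(dict.fromkeys(subset_hogs))
    bg = set(background)
    stray = set(subset) - bg
    if stray:
        raise ValueError(f"subset families outside the background (e.g. {sorted(stray)[:3]})")

    N, n = len(background), len(subset)
    term_bg: dict[str, int] = {}
    for h in background:
        for t in annotation.get(h, ()):  # term incidence over the background
            term_bg[t] = term_bg.get(t, 0) + 1
    term_sub: dict[str, int] = {}
    for h in subset:
        for t in annotation.get(h, ()):
            term_sub[t] = term_sub.get(t, 0) + 1

    rows = []
    for term, k in term_sub.items():
        K = term_bg[term]
        p = hypergeom_over(k, n, K, N)
        rows.append(
            {
                "term": term,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p_value": p,
                "reported": bool(p < p_threshold and k >= min_subset_count),
            }
        )
    out = pd.DataFrame(rows, columns=["term", "k", "n", "K", "N", "p_value", "reported"])
    return out.sort_values(["p_value", "term"], kind="mergesort").reset_index(drop=True)
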