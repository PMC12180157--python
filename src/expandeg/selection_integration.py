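"""Diversifying-selection flags and the gene- and family-level enrichment
designs built on them.

Genes enter the analysis only if they passed the branch-site workflow's
quality filters ("tested"); a tested gene is flagged *selected* when its
corrected p-value is at most alpha_sel (inclusive). Denominators use tested
genes only: untested genes are outside both foreground and background.

Three gene-level designs are supported, mirroring the published tables:
(a) DEGs vs all tested genes of the species, under-representation;
(b) genes in species-specific expanded families vs all tested genes,
over-representation; (c) DEGs in expanded families vs all DEGs,
over-representation. A family-level variant counts a family as a success
when at least one DEG from the species group is selected and as tested
when at least one such DEG was tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .enrichment_stats import EnrichmentResult, enrich
from .io_formats import SelectionTable

__all__ = [
    "SelectionFlags",
    "flag_selection",
    "selection_enrichment_genes",
    "selection_enrichment_families",
    "selection_table_rows",
]


@dataclass
class SelectionFlags:
    """Per-gene tested/selected flags plus per-species tallies (species
    resolved through family membership, since selection tables are keyed by
    bare gene id)."""

    df: pd.DataFrame  # gene_id, tested, selected, p_corrected
    per_species: pd.DataFrame | None = None  # index species: n_tested, n_selected

    def tested_genes(self) -> set[str]:
        return set(self.df.loc[self.df["tested"], "gene_id"])

    def selected_genes(self) -> set[str]:
        return set(self.df.loc[self.df["selected"], "gene_id"])


def flag_selection(
    table: SelectionTable,
    alpha_sel: float,
    gene_species: Mapping[str, str] | None = None,
) -> SelectionFlags:
    """Inclusive thresholding of corrected p-values at alpha_sel.

    `gene_species` (gene_id -> species, typically derived from family
    membership) enables the per-species tested/selected tallies.
    """
    df = table.df.copy()
    bad = df["p_corrected"].notna() & ((df["p_corrected"] < 0) | (df["p_corrected"] > 1))
    if bad.any():
        raise ValueError("p_corrected outside [0, 1]")
    df["selected"] = df["tested"] & df["p_corrected"].notna() & (df["p_corrected"] <= alpha_sel)
    per_species = None
    if gene_species is not None:
        df["species"] = df["gene_id"].map(gene_species)
        per_species = (
            df.dropna(subset=["species"])
            .groupby("species")
            .agg(n_tested=("tested", "sum"), n_selected=("selected", "sum"))
            .astype(int)
        )
    return SelectionFlags(df=df[[c for c in ("gene_id", "tested", "selected", "p_corrected", "species") if c in df.columns]], per_species=per_species)


def selection_enrichment_genes(
    gene_set: Iterable[str],
    flags: SelectionFlags,
    universe_genes: Iterable[str],
    direction: str,
    universe_name: str = "",
    label: str = "",
) -> EnrichmentResult:
    """Gene-level selection enrichment: restrict subset and universe to
    tested genes, mark selected genes, apply the requested tail."""
    tested = flags.tested_genes()
    uni = set(universe_genes) & tested
    if not uni:
        raise ValueError("empty tested universe")
    sub = set(gene_set) & tested
    return enrich(sub, flags.selected_genes(), uni, direction, universe_name, label)


def selection_enrichment_families(
    hog_set: Iterable[str],
    group_species: Sequence[str],
    flags: SelectionFlags,
    de_gene_flags: pd.DataFrame,
    universe_genes: Iterable[str],
) -> tuple[EnrichmentResult, pd.DataFrame]:
    """Family-level enrichment with a gene-level background.

    A family in `hog_set` counts as *tested* when it holds >= 1 tested DEG
    from the species group and as a *success* when >= 1 such DEG is
    selected. The background (K, N) is gene-level: selected / tested DEGs
    of the group in `universe_genes`. The two counting conventions are
    deliberately mixed to mirror the published table; the returned frame
    records both so the ambiguity stays visible.

    de_gene_flags: long frame (hog_id, species, gene_id, de, up).
    """
    tested = flags.tested_genes()
    selected = flags.selected_genes()
    degs = de_gene_flags[de_gene_flags["de"] & de_gene_flags["species"].isin(group_species)]

    in_set = degs[degs["hog_id"].isin(set(hog_set))]
    if len(in_set) == 0:
        n_families_tested = k_families = 0
    else:
        by_hog = in_set.assign(
            t=in_set["gene_id"].isin(tested), s=in_set["gene_id"].isin(selected)
        ).groupby("hog_id")[["t", "s"]].any()
        n_families_tested = int(by_hog["t"].sum())
        k_families = int((by_hog["t"] & by_hog["s"]).sum())

    uni = set(universe_genes) & tested & set(degs["gene_id"])
    K = len(uni & selected)
    N = len(uni)
    from .enrichment_stats import Contingency, hypergeom_over

    if n_families_tested > N:
        raise ValueError("family count exceeds gene-level background; universe too small")
    c = Contingency(N=N, K=K, n=n_families_tested, k=k_families)
    p = hypergeom_over(k_families, n_families_tested, K, N)
    detail = pd.DataFrame(
        [
            {
                "convention": "family_numerator_gene_background",
                "k": k_families,
                "n": n_families_tested,
                "K": K,
                "N": N,
                "p_over": p,
                "note": "mixed convention as published; see gene_level row",
            }
        ]
    )
    # pure gene-level companion row
    sub_genes = set(in_set["gene_id"]) & tested
    k_genes = len(sub_genes & selected)
    p_genes = hypergeom_over(k_genes, len(sub_genes), K, N) if sub_genes else 1.0
    detail.loc[len(detail)] = {
        "convention": "gene_level",
        "k": k_genes,
        "n": len(sub_genes),
        "K": K,
        "N": N,
        "p_over": p_genes,
        "note": "same test with gene-count numerator",
    }
    return EnrichmentResult(c, "over", p, universe="tested group DEGs (gene level)"), detail


def selection_table_rows(
    design: str,
    per_species_sets: Mapping[str, Mapping[str, set[str]]],
    flags: SelectionFlags,
    direction: str,
) -> pd.DataFrame:
    """Assemble a published-table analogue.

    per_species_sets: species -> {'subset': genes, 'universe': genes}.
    Returns one row per species with the contingency, percentages, and the
    one-sided p in the requested direction.
    """
    rows = []
    for sp, sets in per_species_sets.items():
        res = selection_enrichment_genes(
            sets["subset"], flags, sets["universe"], direction,
            universe_name=f"tested genes of {sp} in the conserved set", label=f"{design}:{sp}",
        )
        c = res.contingency
        rows.append(
            {
                "species": sp,
                "design": design,
                "k": c.k,
                "n": c.n,
                "K": c.K,
                "N": c.N,
                "percent_set": 100.0 * c.k / c.n if c.n else float("nan"),
                "percent_background": 100.0 * c.K / c.N if c.N else float("nan"),
                "direction": direction,
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(rows)
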