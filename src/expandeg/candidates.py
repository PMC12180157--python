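"""Tiered candidate families and the enrichment tests over them.

Candidate tiers are nested subsets of the Conserved Set:

* ``candidate`` — expanded in both tolerant species (and in no sensitive
  species, per the expansion hypothesis) AND differentially expressed in
  at least one tolerant species;
* ``conserved_de`` — additionally DE in *both* tolerant species;
* ``unique_up`` — additionally with no DEG in any sensitive species and no
  down-regulated tolerant DEG.

``unique_up`` is reported in two readings: the permissive one admits
families whose tolerant DEGs are all up-regulated regardless of their
number, the strict one additionally requires the >= 2-DEG precondition of
the regulation-category classifier. Contrast tiers are the exact
phenotype-swapped image of the candidate construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core_model import ConservedSet, ExpansionResult, StudyConfig
from .de_integration import DEFlagSet, categorize_regulation
from .enrichment_stats import EnrichmentResult, enrich

__all__ = [
    "TierTable",
    "build_tiers",
    "conserved_de_enrichment",
    "unique_de_enrichment",
    "regulation_enrichment",
]


@dataclass
class TierTable:
    """Per-family tier flags; one row per conserved family."""

    df: pd.DataFrame
    tolerant: tuple[str, ...]
    sensitive: tuple[str, ...]

    def tier(self, name: str) -> list[str]:
        col = self.df[name]
        return list(self.df.index[col])

    def counts(self) -> dict[str, int]:
        cols = [
            "candidate", "conserved_de", "unique_up", "unique_up_min2",
            "contrast_candidate", "contrast_conserved_de", "contrast_unique_up",
        ]
        return {c: int(self.df[c].sum()) for c in cols if c in self.df.columns}


def _tier_flags(
    expanded_both: pd.Series,
    any_deg: pd.DataFrame,
    n_up: pd.DataFrame,
    n_down: pd.DataFrame,
    focal: tuple[str, ...],
    other: tuple[str, ...],
) -> pd.DataFrame:
    focal_cols = list(focal)
    other_cols = list(other)
    de_any = any_deg[focal_cols].any(axis=1)
    de_all = any_deg[focal_cols].all(axis=1)
    no_other = ~any_deg[other_cols].any(axis=1)
    focal_up = n_up[focal_cols].sum(axis=1)
    focal_down = n_down[focal_cols].sum(axis=1)

    candidate = expanded_both & de_any
    conserved_de = candidate & de_all
    only_up = (focal_down == 0) & (focal_up >= 1)
    unique_up = conserved_de & no_other & only_up
    unique_up_min2 = unique_up & ((focal_up + focal_down) >= 2)
    return pd.DataFrame(
        {
            "candidate": candidate,
            "conserved_de": conserved_de,
            "unique_up": unique_up,
            "unique_up_min2": unique_up_min2,
        }
    )


def build_tiers(
    conserved: ConservedSet,
    expansion: ExpansionResult,
    de_flags: DEFlagSet,
    config: StudyConfig,
    tolerant_hypothesis: str = "exp_tolerant_both",
    sensitive_hypothesis: str = "exp_sensitive_both",
) -> TierTable:
    """Compose tier flags from the expansion matrix and family DE flags.

    The contrast tiers swap the phenotype roles symmetrically, using the
    both-sensitive expansion hypothesis.
    """
    tol, sen = config.tolerant, config.sensitive
    for h in (tolerant_hypothesis, sensitive_hypothesis):
        if h not in expansion.matrix.columns:
            raise KeyError(f"hypothesis {h!r} missing from the expansion matrix")
    main = _tier_flags(
        expansion.matrix[tolerant_hypothesis], de_flags.any_deg,
        de_flags.n_up, de_flags.n_down, tol, sen,
    )
    contrast = _tier_flags(
        expansion.matrix[sensitive_hypothesis], de_flags.any_deg,
        de_flags.n_up, de_flags.n_down, sen, tol,
    ).rename(columns=lambda c: f"contrast_{c}")

    df = pd.concat([expansion.matrix, de_flags.any_deg.add_prefix("de_"), main, contrast], axis=1)
    df["regulation_tolerant"] = categorize_regulation(
        de_flags.n_up[list(tol)].sum(axis=1), de_flags.n_down[list(tol)].sum(axis=1)
    )
    df["regulation_all"] = categorize_regulation(
        de_flags.n_up.sum(axis=1), de_flags.n_down.sum(axis=1)
    )
    return TierTable(df=df, tolerant=tol, sensitive=sen)


def conserved_de_enrichment(
    tiers: TierTable, de_flags: DEFlagSet, contrast: bool = False
) -> EnrichmentResult:
    """Is DE-in-both-focal-species over-represented in the candidate tier,
    relative to all families DE in at least one focal species?"""
    focal = tiers.sensitive if contrast else tiers.tolerant
    any_deg = de_flags.any_deg
    universe = any_deg.index[any_deg[list(focal)].any(axis=1)]
    prop = any_deg.index[any_deg[list(focal)].all(axis=1)]
    subset = tiers.tier("contrast_candidate" if contrast else "candidate")
    return enrich(
        subset, prop, universe, "over",
        universe_name=f"families DE in >= 1 of {focal}",
        label="conserved_de_in_candidates",
    )


def unique_de_enrichment(
    tiers: TierTable, de_flags: DEFlagSet, contrast: bool = False
) -> EnrichmentResult:
    """Is absence of DE in the opposite phenotype over-represented among the
    conserved-DE tier, relative to all families DE in both focal species?"""
    focal = tiers.sensitive if contrast else tiers.tolerant
    other = tiers.tolerant if contrast else tiers.sensitive
    any_deg = de_flags.any_deg
    universe = any_deg.index[any_deg[list(focal)].all(axis=1)]
    prop = any_deg.index[~any_deg[list(other)].any(axis=1)]
    subset = tiers.tier("contrast_conserved_de" if contrast else "conserved_de")
    return enrich(
        subset, prop, universe, "over",
        universe_name=f"families DE in both of {focal}",
        label="unique_de_in_conserved_de_tier",
    )


def regulation_enrichment(
    subset_hogs: list[str],
    universe_hogs: list[str],
    categories: pd.Series,
) -> dict[str, EnrichmentResult]:
    """One over-representation test per regulation category.

    Both subset and universe are first restricted to families where the
    category applies (>= 2 DEGs in the scope the caller classified).
    """
    applicable = set(categories.index[categories != "not_applicable"])
    uni = [h for h in universe_hogs if h in applicable]
    sub = [h for h in subset_hogs if h in applicable]
    out = {}
    for cat in ("up", "down", "down_and_up"):
        prop = set(categories.index[categories == cat])
        out[cat] = enrich(
            sub, prop, uni, "over",
            universe_name="families with >= 2 DEGs in scope",
            label=f"regulation:{cat}",
        )
    return out
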