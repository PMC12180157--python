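"""Map differential expression onto gene families, classify regulation
patterns, and compute the cross-species DE-conservation statistic.

A gene is a DEG when its adjusted p-value is present and at most alpha_de
(inclusive boundary). Family-level flags count DEGs per species, which is
why the number of DEGs can exceed the number of families holding one. The
conservation statistic compares the observed counts of families DE in all
species / in no species against the independence null: the product across
species of the per-species probabilities that a family holds a DEG
(p_s4 = prod p_s, p_f4 = prod (1 - p_s)), assessed with a two-cell
chi-square goodness-of-fit (df = 1, no continuity correction, mirroring
R's ``chisq.test(x, p)``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import ConservedSet
from .io_formats import DETable

__all__ = [
    "flag_degs",
    "DEFlagSet",
    "hog_de_flags",
    "regulation_category",
    "categorize_regulation",
    "ConservationStats",
    "conservation_stats",
    "conservation_stats_from_counts",
    "REGULATION_CATEGORIES",
]

REGULATION_CATEGORIES = ("up", "down", "down_and_up", "not_applicable")


def flag_degs(de_table: DETable, alpha_de: float) -> pd.DataFrame:
    """Per-gene DE calls with sign.

    Returns a frame (gene_id, de, up, log2fc, padj). Missing padj is never
    DE. A gene called DE with log2fc exactly 0 is degenerate and rejected.
    """
    df = de_table.df
    de = df["padj"].notna() & (df["padj"] <= alpha_de)
    zero = de & (df["log2fc"] == 0)
    if zero.any():
        gene = df.loc[zero, "gene_id"].iloc[0]
        raise ValueError(
            f"gene {gene!r} ({de_table.species}): significant with log2fc == 0; "
            "cannot assign a regulation sign"
        )
    return pd.DataFrame(
        {
            "gene_id": df["gene_id"],
            "de": de,
            "up": de & (df["log2fc"] > 0),
            "log2fc": df["log2fc"],
            "padj": df["padj"],
        }
    )


@dataclass
class DEFlagSet:
    """Family x species DE counts.

    n_up / n_down: DEG counts by sign; any_deg: >= 1 DEG. `summary` holds
    per-species totals (n_degs assigned to conserved families, n_hogs with
    a DEG, n_degs_unassigned outside the conserved universe).
    """

    n_up: pd.DataFrame
    n_down: pd.DataFrame
    any_deg: pd.DataFrame
    summary: pd.DataFrame
    gene_flags: pd.DataFrame  # long: hog_id, species, gene_id, de, up

    @property
    def species(self) -> list[str]:
        return list(self.any_deg.columns)


def hog_de_flags(conserved: ConservedSet, flagged: Mapping[str, pd.DataFrame]) -> DEFlagSet:
    """Aggregate per-gene DE flags to the family level over the Conserved Set.

    `flagged` maps species -> output of :func:`flag_degs`. DE genes that do
    not map to any conserved family are tallied as unassigned and excluded
    from every statistic (the analysis universe is the Conserved Set).
    """
    table = conserved.table
    species = [sp for sp in table.species if sp in flagged]
    missing = set(table.species) - set(species)
    if missing:
        raise ValueError(f"no DE flags for species {sorted(missing)}")

    genes = table.genes
    parts = []
    summary_rows = []
    for sp in species:
        fl = flagged[sp]
        sub = genes[genes["species"] == sp].merge(fl, on="gene_id", how="left")
        sub["de"] = sub["de"].eq(True)
        sub["up"] = sub["up"].eq(True)
        parts.append(sub[["hog_id", "species", "gene_id", "de", "up"]])
        n_de_total = int(fl["de"].sum())
        assigned_genes = set(sub.loc[sub["de"], "gene_id"])
        n_assigned = len(assigned_genes & set(fl.loc[fl["de"], "gene_id"]))
        summary_rows.append(
            {
                "species": sp,
                "n_degs": n_assigned,
                "n_degs_unassigned": n_de_total - n_assigned,
            }
        )
    long = pd.concat(parts, ignore_index=True)

    de_rows = long[long["de"]]
    n_up = (
        de_rows[de_rows["up"]].groupby(["hog_id", "species"]).size().unstack(fill_value=0)
    )
    n_down = (
        de_rows[~de_rows["up"]].groupby(["hog_id", "species"]).size().unstack(fill_value=0)
    )
    idx = table.hog_ids
    n_up = n_up.reindex(index=idx, columns=species, fill_value=0).astype(int)
    n_down = n_down.reindex(index=idx, columns=species, fill_value=0).astype(int)
    any_deg = (n_up + n_down) >= 1

    summary = pd.DataFrame(summary_rows).set_index("species")
    summary["n_hogs_with_deg"] = [int(any_deg[sp].sum()) for sp in species]
    return DEFlagSet(n_up=n_up, n_down=n_down, any_deg=any_deg, summary=summary, gene_flags=long)


def categorize_regulation(n_up: pd.Series, n_down: pd.Series) -> pd.Series:
    """Vectorised regulation category from signed DEG counts.

    Families with fewer than 2 DEGs (in the chosen scope) are
    'not_applicable'; otherwise 'up' when every DEG is up-regulated, 'down'
    when every DEG is down-regulated, and 'down_and_up' when both signs
    occur.
    """
    total = n_up + n_down
    out = pd.Series("not_applicable", index=n_up.index, dtype=object)
    applicable = total >= 2
    out[applicable & (n_down == 0)] = "up"
    out[applicable & (n_up == 0)] = "down"
    out[applicable & (n_up >= 1) & (n_down >= 1)] = "down_and_up"
    return pd.Series(pd.Categorical(out, categories=REGULATION_CATEGORIES), index=n_up.index)


def regulation_category(
    flags: DEFlagSet, scope: str | Sequence[str] = "across_species"
) -> pd.Series:
    """Per-family regulation category.

    scope='across_species' pools DEGs from every species; a species name or
    list of names restricts the classification to those species' DEGs
    (within-species divergent regulation uses a single-species scope).
    """
    if scope == "across_species":
        cols = flags.species
    elif isinstance(scope, str):
        cols = [scope]
    else:
        cols = list(scope)
    for c in cols:
        if c not in flags.species:
            raise KeyError(f"unknown species {c!r} in scope")
    return categorize_regulation(flags.n_up[cols].sum(axis=1), flags.n_down[cols].sum(axis=1))


@dataclass
class ConservationStats:
    """Independence-null summary for cross-species DE conservation."""

    N: int
    p_s: dict[str, float]
    p_f: dict[str, float]
    p_s4: float
    p_f4: float
    observed_all: int
    observed_none: int
    expected_all: float
    expected_none: float
    chi2_all: float
    p_all: float
    chi2_none: float
    p_none: float


def _gof(observed: int, expected: float, N: int) -> tuple[float, float]:
    # 2-cell goodness-of-fit against (p, 1-p); df = 1, no continuity correction
    if expected <= 0 or expected >= N:
        # degenerate null (all or none certain): statistic undefined unless exact
        if observed == round(expected):
            return 0.0, 1.0
        return float("inf"), 0.0
    stat = (observed - expected) ** 2 / expected + (
        (N - observed) - (N - expected)
    ) ** 2 / (N - expected)
    return float(stat), float(stats.chi2.sf(stat, df=1))


def conservation_stats(conserved: ConservedSet | int, flags: DEFlagSet | pd.DataFrame) -> ConservationStats:
    """Compute p_s, p_f per species, their products, and the two chi-square
    tests (families DE in all species; families DE in none).

    Accepts either a ConservedSet + DEFlagSet or a bare N + any_deg frame.
    """
    any_deg = flags.any_deg if isinstance(flags, DEFlagSet) else flags
    N = conserved.N if isinstance(conserved, ConservedSet) else int(conserved)
    if N <= 0:
        raise ValueError("conserved-set size must be >= 1")
    if len(any_deg) != N:
        raise ValueError(f"flag frame has {len(any_deg)} rows but N = {N}")

    p_s = {sp: float(any_deg[sp].sum()) / N for sp in any_deg.columns}
    p_f = {sp: 1.0 - v for sp, v in p_s.items()}
    p_s4 = float(np.prod(list(p_s.values())))
    p_f4 = float(np.prod(list(p_f.values())))
    observed_all = int(any_deg.all(axis=1).sum())
    observed_none = int((~any_deg).all(axis=1).sum())
    expected_all = p_s4 * N
    expected_none = p_f4 * N
    chi2_all, p_all = _gof(observed_all, expected_all, N)
    chi2_none, p_none = _gof(observed_none, expected_none, N)
    return ConservationStats(
        N=N,
        p_s=p_s,
        p_f=p_f,
        p_s4=p_s4,
        p_f4=p_f4,
        observed_all=observed_all,
        observed_none=observed_none,
        expected_all=expected_all,
        expected_none=expected_none,
        chi2_all=chi2_all,
        p_all=p_all,
        chi2_none=chi2_none,
        p_none=p_none,
    )


def conservation_stats_from_counts(
    hogs_with_deg: Mapping[str, int],
    N: int,
    observed_all: int | None = None,
    observed_none: int | None = None,
) -> ConservationStats:
    """Conservation null directly from per-species family-with-DEG counts.

    Useful when only the published summary counts are available. When the
    observed all-/no-species counts are not supplied, the rounded expected
    counts stand in and the chi-square statistics are 0 by construction.
    """
    if N <= 0:
        raise ValueError("N must be >= 1")
    p_s = {sp: c / N for sp, c in hogs_with_deg.items()}
    for sp, p in p_s.items():
        if not 0 <= p <= 1:
            raise ValueError(f"count for {sp!r} outside [0, N]")
    p_f = {sp: 1.0 - v for sp, v in p_s.items()}
    p_s4 = float(np.prod(list(p_s.values())))
    p_f4 = float(np.prod(list(p_f.values())))
    expected_all = p_s4 * N
    expected_none = p_f4 * N
    obs_all = int(round(expected_all)) if observed_all is None else int(observed_all)
    obs_none = int(round(expected_none)) if observed_none is None else int(observed_none)
    chi2_all, p_all = _gof(obs_all, expected_all, N)
    chi2_none, p_none = _gof(obs_none, expected_none, N)
    return ConservationStats(
        N=N,
        p_s=p_s,
        p_f=p_f,
        p_s4=p_s4,
        p_f4=p_f4,
        observed_all=obs_all,
        observed_none=obs_none,
        expected_all=expected_all,
        expected_none=expected_none,
        chi2_all=chi2_all,
        p_all=p_all,
        chi2_none=chi2_none,
        p_none=p_none,
    )
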