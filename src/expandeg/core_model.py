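"""Family/species data model, the Conserved Set filter, and ploidy-corrected
expansion calling.

The central container is :class:`OrthogroupTable`, a long-format table of
(hog_id, species, gene_id) memberships with a derived copy-number matrix.
Gene ids are namespaced per species: the same string may appear in two
species without conflict, but within a species a gene belongs to at most
one family.

Expansion semantics
-------------------
A family is *expanded* in a focal species relative to a set of background
species when the focal species' ploidy-corrected copy number is at least
``factor`` times the ploidy-corrected copy number of *every* background
species, and the focal species carries at least ``min_focal_copies`` raw
copies. Ploidy correction scales a species' raw count by ``2 / ploidy``
(halving for a tetraploid) and is applied symmetrically, whether the
polyploid is focal or background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpeciesProfile",
    "Hypothesis",
    "StudyConfig",
    "OrthogroupTable",
    "ConservedSet",
    "ExpansionResult",
    "effective_count",
    "filter_conserved",
    "is_expanded",
    "expansion_matrix",
]

PHENOTYPES = ("tolerant", "sensitive")


@dataclass(frozen=True)
class SpeciesProfile:
    """A study species with its ploidy and tolerance phenotype.

    ploidy is the somatic chromosome multiplicity (2 = diploid baseline);
    it must be even and at least 2 so that the 2/ploidy correction maps a
    diploid to the identity.
    """

    name: str
    ploidy: int = 2
    phenotype: str = "sensitive"

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("species name must be non-empty")
        if self.ploidy < 2 or self.ploidy % 2 != 0:
            raise ValueError(
                f"species {self.name!r}: ploidy must be an even integer >= 2, "
                f"got {self.ploidy}"
            )
        if self.phenotype not in PHENOTYPES:
            raise ValueError(
                f"species {self.name!r}: phenotype must be one of {PHENOTYPES}, "
                f"got {self.phenotype!r}"
            )


@dataclass(frozen=True)
class Hypothesis:
    """One expansion contrast: every focal species must be expanded relative
    to each background species."""

    id: str
    focal: tuple[str, ...]
    background: tuple[str, ...]
    factor: float = 2.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "focal", tuple(self.focal))
        object.__setattr__(self, "background", tuple(self.background))
        if not self.focal or not self.background:
            raise ValueError(f"hypothesis {self.id!r}: focal and background must be non-empty")
        if set(self.focal) & set(self.background):
            raise ValueError(f"hypothesis {self.id!r}: focal and background overlap")
        if self.factor <= 0:
            raise ValueError(f"hypothesis {self.id!r}: factor must be positive")


@dataclass(frozen=True)
class StudyConfig:
    """Study-wide parameters: species roster, thresholds, and the expansion
    hypotheses to evaluate.

    alpha_de : adjusted-p cutoff calling a gene differentially expressed
        (inclusive; default 0.1).
    alpha_sel : corrected-p cutoff calling a gene under diversifying
        selection (inclusive; default 0.05).
    expansion_factor : copy-number ratio defining expansion (default 2,
        "at least twice the number of genes").
    min_focal_copies : minimum raw copy number in the focal species for an
        expansion call (default 2; set to 1 for the literal ratio rule).
    """

    species: tuple[SpeciesProfile, ...]
    alpha_de: float = 0.1
    alpha_sel: float = 0.05
    expansion_factor: float = 2.0
    min_focal_copies: int = 2
    hypotheses: tuple[Hypothesis, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "hypotheses", tuple(self.hypotheses))
        names = [s.name for s in self.species]
        if len(names) != len(set(names)):
            raise ValueError("duplicate species names in config")
        if len(names) < 2:
            raise ValueError("need at least 2 species")
        if not (0 < self.alpha_de < 1) or not (0 < self.alpha_sel < 1):
            raise ValueError("alpha_de and alpha_sel must lie in (0, 1)")
        if not self.tolerant or not self.sensitive:
            raise ValueError("both phenotype classes must be non-empty")
        if self.min_focal_copies < 1:
            raise ValueError("min_focal_copies must be >= 1")
        known = set(names)
        for h in self.hypotheses:
            unknown = (set(h.focal) | set(h.background)) - known
            if unknown:
                raise ValueError(f"hypothesis {h.id!r} references unknown species {sorted(unknown)}")

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    @property
    def tolerant(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species if s.phenotype == "tolerant")

    @property
    def sensitive(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species if s.phenotype == "sensitive")

    def profile(self, name: str) -> SpeciesProfile:
        for s in self.species:
            if s.name == name:
                return s
        raise KeyError(f"unknown species {name!r}")

    def ploidy_map(self) -> dict[str, int]:
        return {s.name: s.ploidy for s in self.species}

    def with_default_hypotheses(self) -> "StudyConfig":
        """Return a copy carrying the standard six contrasts: each species
        alone versus the opposite phenotype class, plus each full phenotype
        class versus the other."""
        tol, sen = self.tolerant, self.sensitive
        f = self.expansion_factor
        hyps = []
        for sp in tol:
            hyps.append(Hypothesis(f"exp_{sp}", (sp,), sen, f))
        for sp in sen:
            hyps.append(Hypothesis(f"exp_{sp}", (sp,), tol, f))
        hyps.append(Hypothesis("exp_tolerant_both", tol, sen, f))
        hyps.append(Hypothesis("exp_sensitive_both", sen, tol, f))
        return StudyConfig(
            species=self.species,
            alpha_de=self.alpha_de,
            alpha_sel=self.alpha_sel,
            expansion_factor=self.expansion_factor,
            min_focal_copies=self.min_focal_copies,
            hypotheses=tuple(hyps),
        )


class OrthogroupTable:
    """Gene-family membership across species.

    Parameters
    ----------
    genes : DataFrame with columns (hog_id, species, gene_id), one row per
        gene. A gene id may recur across species but not across families
        within a species.
    species : the full species roster, in study order (a family may have
        zero members in some species).
    hog_ids : optional explicit family roster; defaults to the families
        present in `genes`.
    og_ids : optional mapping hog_id -> coarse orthogroup id.
    """

    def __init__(
        self,
        genes: pd.DataFrame,
        species: Sequence[str],
        hog_ids: Sequence[str] | None = None,
        og_ids: Mapping[str, str] | None = None,
    ) -> None:
        required = {"hog_id", "species", "gene_id"}
        if not required.issubset(genes.columns):
            raise ValueError(f"genes frame must have columns {sorted(required)}")
        genes = genes.loc[:, ["hog_id", "species", "gene_id"]].reset_index(drop=True)
        self.species = list(species)
        unknown = set(genes["species"]) - set(self.species)
        if unknown:
            raise ValueError(f"genes reference unknown species {sorted(unknown)}")

        dup = genes.duplicated(subset=["species", "gene_id"], keep=False)
        if dup.any():
            bad = genes.loc[dup]
            multi = bad.groupby(["species", "gene_id"])["hog_id"].nunique()
            multi = multi[multi > 1]
            if len(multi) > 0:
                sp, gid = multi.index[0]
                raise ValueError(
                    f"gene {gid!r} of species {sp!r} is assigned to more than one family"
                )
            # same gene listed twice in the same family: collapse silently is
            # unsafe for the token-count invariant, so reject
            sp, gid = bad.iloc[0][["species", "gene_id"]]
            raise ValueError(f"gene {gid!r} of species {sp!r} listed more than once")

        if hog_ids is None:
            hog_ids = list(dict.fromkeys(genes["hog_id"]))
        else:
            hog_ids = list(hog_ids)
            if len(hog_ids) != len(set(hog_ids)):
                raise ValueError("duplicate hog_id in roster")
            stray = set(genes["hog_id"]) - set(hog_ids)
            if stray:
                raise ValueError(f"genes reference families outside the roster: {sorted(stray)[:3]}")
        self.hog_ids = hog_ids
        self.genes = genes
        self.og_ids = dict(og_ids) if og_ids else {}

        counts = (
            genes.groupby(["hog_id", "species"], sort=False).size().unstack(fill_value=0)
        )
        counts = counts.reindex(index=hog_ids, columns=self.species, fill_value=0)
        self.counts = counts.astype(int)

    def __len__(self) -> int:
        return len(self.hog_ids)

    def members(self, hog_id: str) -> dict[str, set[str]]:
        sub = self.genes[self.genes["hog_id"] == hog_id]
        out: dict[str, set[str]] = {sp: set() for sp in self.species}
        for sp, grp in sub.groupby("species"):
            out[str(sp)] = set(grp["gene_id"])
        return out

    def subset(self, hog_ids: Sequence[str]) -> "OrthogroupTable":
        keep = set(hog_ids)
        genes = self.genes[self.genes["hog_id"].isin(keep)]
        ogs = {h: v for h, v in self.og_ids.items() if h in keep}
        return OrthogroupTable(genes, self.species, list(hog_ids), ogs)


@dataclass
class ConservedSet:
    """The families with at least one gene from every study species — the
    universe for every downstream statistic."""

    table: OrthogroupTable
    absence_patterns: dict[tuple[str, ...], int] = field(default_factory=dict)

    @property
    def N(self) -> int:
        return len(self.table)

    @property
    def hog_ids(self) -> list[str]:
        return self.table.hog_ids


def effective_count(raw_count: int | float, ploidy: int) -> float:
    """Ploidy-corrected copy number: raw count scaled by 2/ploidy, so a
    tetraploid's count is halved and a diploid's is unchanged."""
    if raw_count < 0:
        raise ValueError("raw_count must be non-negative")
    if ploidy < 2:
        raise ValueError("ploidy must be >= 2")
    return raw_count * 2.0 / ploidy


def filter_conserved(table: OrthogroupTable, species_list: Sequence[str]) -> ConservedSet:
    """Keep the families with >= 1 member in every listed species.

    Excluded families are tallied by their absence pattern (the sorted tuple
    of species they lack) so the caller can report what was dropped.
    """
    counts = table.counts[list(species_list)]
    present = counts >= 1
    keep_mask = present.all(axis=1)
    kept = [h for h, k in zip(table.counts.index, keep_mask) if k]

    patterns: dict[tuple[str, ...], int] = {}
    missing = ~present[~keep_mask.values]
    for _, row in missing.iterrows():
        pat = tuple(sorted(c for c in missing.columns if row[c]))
        patterns[pat] = patterns.get(pat, 0) + 1
    return ConservedSet(table.subset(kept), patterns)


def is_expanded(
    family_counts: Mapping[str, int],
    focal: str,
    background: Iterable[str],
    config: StudyConfig,
    factor: float | None = None,
) -> bool:
    """Expansion call for one family and one focal species.

    True iff the focal species' effective count is at least ``factor`` times
    the effective count of every background species and the focal raw count
    meets ``min_focal_copies``. Ties count as expanded ("at least twice").
    """
    background = list(background)
    if focal in background:
        raise ValueError(f"focal species {focal!r} also appears in the background set")
    if factor is None:
        factor = config.expansion_factor
    ploidy = config.ploidy_map()
    focal_eff = effective_count(family_counts[focal], ploidy[focal])
    if family_counts[focal] < config.min_focal_copies:
        return False
    return all(
        focal_eff >= factor * effective_count(family_counts[b], ploidy[b]) for b in background
    )


@dataclass
class ExpansionResult:
    """Per-family expansion flags for every hypothesis, plus the per-species
    single-focal flags used for intersection bookkeeping."""

    matrix: pd.DataFrame  # bool, index hog_id, one column per hypothesis id
    per_species: pd.DataFrame  # bool, index hog_id, one column per focal species

    def expanded_hogs(self, hypothesis_id: str) -> list[str]:
        col = self.matrix[hypothesis_id]
        return list(col.index[col])

    def intersection(self, species_a: str, species_b: str) -> list[str]:
        both = self.per_species[species_a] & self.per_species[species_b]
        return list(both.index[both])


def expansion_matrix(
    conserved: ConservedSet,
    hypotheses: Sequence[Hypothesis],
    config: StudyConfig,
) -> ExpansionResult:
    """Vectorised expansion calls over the Conserved Set.

    For a multi-focal hypothesis the flag is the AND over focal species of
    the single-focal rule against the hypothesis' background set. The
    per-species frame carries each species' flag against its own
    opposite-phenotype background (factor from config), which is what
    "expansions common to both tolerant species" intersects.
    """
    counts = conserved.table.counts
    ploidy = config.ploidy_map()
    eff = counts.astype(float).copy()
    for sp in counts.columns:
        eff[sp] = counts[sp] * 2.0 / ploidy[sp]

    def focal_flag(focal: str, background: Sequence[str], factor: float) -> pd.Series:
        ok = counts[focal] >= config.min_focal_copies
        for b in background:
            ok &= eff[focal] >= factor * eff[b]
        return ok

    cols = {}
    for h in hypotheses:
        flag = pd.Series(True, index=counts.index)
        for f in h.focal:
            if f in h.background:
                raise ValueError(f"hypothesis {h.id!r}: focal {f!r} in background")
            flag &= focal_flag(f, h.background, h.factor)
        cols[h.id] = flag
    matrix = pd.DataFrame(cols, index=counts.index) if cols else pd.DataFrame(index=counts.index)

    tol, sen = set(config.tolerant), set(config.sensitive)
    per_sp = {}
    for sp in counts.columns:
        contrast = sorted(sen - {sp}) if sp in tol else sorted(tol - {sp})
        if contrast:
            per_sp[sp] = focal_flag(sp, contrast, config.expansion_factor)
    per_species = pd.DataFrame(per_sp, index=counts.index)
    return ExpansionResult(matrix=matrix, per_species=per_species)
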