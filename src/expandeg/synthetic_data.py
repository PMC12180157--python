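"""Synthetic study generator: complete, statistically structured inputs
(orthogroup membership, per-species DE tables, selection table, GO map)
with planted effects recorded in a truth ledger for recovery scoring.

What it emulates
----------------
* Heavy-tailed family sizes: per-species copy numbers follow a
  zero-truncated geometric law; the tetraploid draws two subgenome copies.
* Trait-specific expansions: a disjoint subset of families is planted per
  expansion hypothesis by raising focal copy numbers just enough to
  satisfy the ploidy-corrected expansion rule (disjoint assignment keeps
  planted contrasts from interfering with one another).
* Cross-species DE conservation: each family x species is DE-active with a
  base probability whose odds are multiplied by a coupling factor once any
  previously generated species is DE in that family, and by an
  expansion-DE factor in families planted-expanded for that species.
  `de_base_rate` is the per-family any-DEG probability; it is converted to
  a per-gene Bernoulli rate 1-(1-r)^(1/n) so that family-level DE
  frequency does not scale with copy number while DEG counts still exceed
  family counts.
* Signed regulation, selection flags enriched on DEGs in
  tolerant-expanded families, and GO terms with one planted term enriched
  in the candidate tier.

Identical config (including seed) yields byte-identical files. Gene ids
encode species and family of origin for debuggability only; the pipeline
must not exploit this (see :func:`scramble_gene_ids`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .core_model import (
    ExpansionResult,
    OrthogroupTable,
    SpeciesProfile,
    StudyConfig,
)
from .io_formats import (
    DETable,
    SelectionTable,
    write_config,
    write_de_table,
    write_go_map,
    write_orthogroups,
    write_selection_table,
    _write_tsv,
)

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate", "write_dataset", "recover", "scramble_gene_ids"]

_DEFAULT_SPECIES = (
    SpeciesProfile("tolA", 2, "tolerant"),
    SpeciesProfile("tolB", 2, "tolerant"),
    SpeciesProfile("senA", 2, "sensitive"),
    SpeciesProfile("senB", 4, "sensitive"),
)

# Default planting rates and DE rates follow the observed study proportions:
# per-species expansions near 2-10% of conserved families, group expansions
# well below 1%, and per-species family-with-DEG frequencies of 16-51%.
_DEFAULT_EXPANSION_RATES = {
    "exp_tolA": 0.035,
    "exp_tolB": 0.055,
    "exp_tolerant_both": 0.008,
    "exp_senA": 0.020,
    "exp_senB": 0.090,
    "exp_sensitive_both": 0.003,
}
_DEFAULT_DE_RATES = {"tolA": 0.42, "tolB": 0.51, "senA": 0.16, "senB": 0.40}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; defaults encode the study conditions."""

    seed: int = 0
    n_hogs: int = 2000
    species: tuple[SpeciesProfile, ...] = _DEFAULT_SPECIES
    family_q: float = 0.85  # zero-truncated geometric success prob (mean copies 1/q)
    missing_rate: float = 0.05  # per-species family dropout (non-planted families)
    expansion_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_EXPANSION_RATES)
    )
    de_base_rate: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_DE_RATES))
    conservation_coupling: float = 2.5  # odds multiplier once another species is DE
    expansion_de_multiplier: float = 1.4  # odds multiplier in planted-expanded families
    up_fraction: float = 0.5
    up_fraction_expanded: float = 0.7  # DEG up-probability where the species is planted focal
    padj_na_rate: float = 0.1  # independent-filtering NA among non-DE genes
    alpha_de: float = 0.1
    alpha_sel: float = 0.05
    tested_rate: float = 0.72
    base_selected_rate: float = 0.095
    selection_de_multiplier: float = 2.0  # on DEGs in tolerant-planted-expanded families
    n_go_terms: int = 40
    go_terms_per_gene: float = 2.0
    go_planted_prob: float = 0.4  # planted term on DEGs of candidate-tier families
    expansion_factor: float = 2.0
    min_focal_copies: int = 2
    max_planted_copies: int = 60

    def __post_init__(self) -> None:
        for name in ("missing_rate", "up_fraction", "up_fraction_expanded", "padj_na_rate",
                     "tested_rate", "base_selected_rate", "go_planted_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0 < self.family_q <= 1:
            raise ValueError("family_q must lie in (0, 1]")
        for name in ("conservation_coupling", "expansion_de_multiplier", "selection_de_multiplier"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for sp, r in self.de_base_rate.items():
            if not 0 <= r < 1:
                raise ValueError(f"de_base_rate[{sp!r}] must lie in [0, 1)")
        if self.n_hogs < 1:
            raise ValueError("n_hogs must be >= 1")

    def study_config(self) -> StudyConfig:
        return StudyConfig(
            species=self.species,
            alpha_de=self.alpha_de,
            alpha_sel=self.alpha_sel,
            expansion_factor=self.expansion_factor,
            min_focal_copies=self.min_focal_copies,
        ).with_default_hypotheses()


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    study_config: StudyConfig
    orthogroups: OrthogroupTable
    de_tables: dict[str, DETable]
    selection: SelectionTable
    go_map: dict[tuple[str, str], frozenset[str]]
    truth_hogs: pd.DataFrame  # hog_id, conserved, planted_<hyp>..., any_deg_<sp>...
    truth_genes: pd.DataFrame  # gene_id, species, hog_id, de, up, tested, selected


def _odds_to_prob(odds: np.ndarray) -> np.ndarray:
    return odds / (1.0 + odds)


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a full synthetic study. Deterministic in `config` (the seed
    is part of the config)."""
    rng = np.random.default_rng(config.seed)
    study = config.study_config()
    species = list(study.species_names)
    ploidy = study.ploidy_map()
    n = config.n_hogs
    hog_ids = [f"F{i:06d}" for i in range(n)]

    # --- copy numbers -----------------------------------------------------
    counts: dict[str, np.ndarray] = {}
    for sp in species:
        draws = rng.geometric(config.family_q, size=n)
        if ploidy[sp] == 4:
            draws = draws + rng.geometric(config.family_q, size=n)
        elif ploidy[sp] > 4:
            for _ in range(ploidy[sp] // 2 - 1):
                draws = draws + rng.geometric(config.family_q, size=n)
        counts[sp] = draws.astype(np.int64)
    for sp in species:
        drop = rng.random(n) < config.missing_rate
        counts[sp][drop] = 0

    # --- planted expansions (disjoint assignment across hypotheses) ------
    hyp_list = list(study.hypotheses)
    rates = [float(config.expansion_rates.get(h.id, 0.0)) for h in hyp_list]
    if sum(rates) > 1:
        raise ValueError("expansion planting rates sum above 1; cannot assign disjointly")
    u = rng.random(n)
    planted: dict[str, np.ndarray] = {}
    lo = 0.0
    for h, r in zip(hyp_list, rates):
        planted[h.id] = (u >= lo) & (u < lo + r)
        lo += r
    for h in hyp_list:
        mask = planted[h.id]
        if not mask.any():
            continue
        for sp in species:  # planted families stay conserved
            counts[sp][mask & (counts[sp] == 0)] = 1
        bg_eff = np.zeros(n)
        for b in h.background:
            bg_eff = np.maximum(bg_eff, counts[b] * 2.0 / ploidy[b])
        for f in h.focal:
            need = np.ceil(h.factor * bg_eff * ploidy[f] / 2.0).astype(np.int64)
            need = np.maximum(need, config.min_focal_copies)
            if (need[mask] > config.max_planted_copies).any():
                raise ValueError(
                    f"hypothesis {h.id!r}: planting requires more than "
                    f"{config.max_planted_copies} copies; family-size law cannot deliver"
                )
            counts[f][mask] = np.maximum(counts[f][mask], need[mask])

    planted_focal: dict[str, np.ndarray] = {
        sp: np.zeros(n, dtype=bool) for sp in species
    }
    for h in hyp_list:
        for f in h.focal:
            planted_focal[f] |= planted[h.id]
    tol_set = set(study.tolerant)
    planted_tolerant = np.zeros(n, dtype=bool)
    for h in hyp_list:
        if set(h.focal) <= tol_set:
            planted_tolerant |= planted[h.id]

    # --- gene rosters -----------------------------------------------------
    gene_frames = []
    gene_ids: dict[str, np.ndarray] = {}
    hog_idx: dict[str, np.ndarray] = {}
    for sp in species:
        cnt = counts[sp]
        idx = np.repeat(np.arange(n), cnt)
        starts = np.concatenate(([0], np.cumsum(cnt)))[:-1]
        within = np.arange(cnt.sum()) - np.repeat(starts, cnt)
        ids = np.array([f"{sp}_{hog_ids[h]}_{w}" for h, w in zip(idx, within)], dtype=object)
        gene_ids[sp] = ids
        hog_idx[sp] = idx
        gene_frames.append(
            pd.DataFrame({"hog_id": np.array(hog_ids, dtype=object)[idx], "species": sp, "gene_id": ids})
        )
    genes_long = pd.concat(gene_frames, ignore_index=True)
    orthogroups = OrthogroupTable(genes_long, species, hog_ids, {h: h.replace("F", "G") for h in hog_ids})

    # --- differential expression ------------------------------------------
    prev_any = np.zeros(n, dtype=bool)
    de_flags: dict[str, np.ndarray] = {}
    up_flags: dict[str, np.ndarray] = {}
    any_deg: dict[str, np.ndarray] = {}
    de_tables: dict[str, DETable] = {}
    c = config.conservation_coupling
    m = config.expansion_de_multiplier
    for sp in species:
        cnt = counts[sp]
        r = float(config.de_base_rate.get(sp, 0.3))
        odds = np.full(n, r / (1.0 - r)) if r > 0 else np.zeros(n)
        odds[prev_any] *= c
        odds[planted_focal[sp]] *= m
        r_hog = np.minimum(_odds_to_prob(odds), 0.995)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_gene_hog = np.where(cnt > 0, 1.0 - (1.0 - r_hog) ** (1.0 / np.maximum(cnt, 1)), 0.0)
        p_gene = np.repeat(p_gene_hog, cnt)
        de = rng.random(cnt.sum()) < p_gene
        idx = hog_idx[sp]
        hit = np.zeros(n, dtype=bool)
        hit[idx[de]] = True
        any_deg[sp] = hit
        prev_any = prev_any | hit

        p_up = np.where(np.repeat(planted_focal[sp], cnt), config.up_fraction_expanded, config.up_fraction)
        up = de & (rng.random(cnt.sum()) < p_up)

        n_genes = cnt.sum()
        # keep a margin around alpha_de so 8-decimal rounding cannot flip a call
        padj = np.empty(n_genes)
        padj[de] = rng.uniform(0.0, config.alpha_de - 1e-6, size=int(de.sum()))
        padj[~de] = rng.uniform(config.alpha_de + 1e-6, 1.0, size=int((~de).sum()))
        # independent-filtering NAs among non-DE rows
        na = (~de) & (rng.random(n_genes) < config.padj_na_rate)
        padj[na] = np.nan
        mag = rng.lognormal(mean=0.0, sigma=0.6, size=n_genes) + 1e-9
        sign_up = np.where(de, up, rng.random(n_genes) < 0.5)
        log2fc = np.where(sign_up, mag, -mag)
        base_mean = np.round(rng.lognormal(mean=4.0, sigma=1.5, size=n_genes), 3)
        de_tables[sp] = DETable(
            species=sp,
            df=pd.DataFrame(
                {
                    "gene_id": gene_ids[sp],
                    "log2fc": np.round(log2fc, 6),
                    "padj": np.round(padj, 8),
                    "base_mean": base_mean,
                }
            ),
        )
        de_flags[sp] = de
        up_flags[sp] = up

    # --- selection ---------------------------------------------------------
    sel_frames = []
    gene_truth_frames = []
    for sp in species:
        cnt = counts[sp]
        n_genes = cnt.sum()
        tested = rng.random(n_genes) < config.tested_rate
        boost = np.repeat(planted_tolerant, cnt) & de_flags[sp]
        rate = np.where(
            boost,
            np.minimum(config.base_selected_rate * config.selection_de_multiplier, 0.99),
            config.base_selected_rate,
        )
        selected = tested & (rng.random(n_genes) < rate)
        p_corr = np.full(n_genes, np.nan)
        p_corr[selected] = rng.uniform(0.0, config.alpha_sel - 1e-6, size=int(selected.sum()))
        untested_sel = tested & ~selected
        p_corr[untested_sel] = rng.uniform(config.alpha_sel + 1e-6, 1.0, size=int(untested_sel.sum()))
        sel_frames.append(
            pd.DataFrame(
                {"gene_id": gene_ids[sp], "p_corrected": np.round(p_corr, 8), "tested": tested}
            )
        )
        gene_truth_frames.append(
            pd.DataFrame(
                {
                    "gene_id": gene_ids[sp],
                    "species": sp,
                    "hog_id": np.array(hog_ids, dtype=object)[hog_idx[sp]],
                    "de": de_flags[sp],
                    "up": up_flags[sp],
                    "tested": tested,
                    "selected": selected,
                }
            )
        )
    selection = SelectionTable(df=pd.concat(sel_frames, ignore_index=True))

    # --- GO annotations -----------------------------------------------------
    terms = np.array([f"GO:{i:07d}" for i in range(config.n_go_terms)], dtype=object)
    planted_term = terms[0]
    go_map: dict[tuple[str, str], frozenset[str]] = {}
    candidate_truth = planted["exp_tolerant_both"] & np.logical_or.reduce(
        [any_deg[sp] for sp in study.tolerant]
    )
    for sp in species:
        cnt = counts[sp]
        n_genes = cnt.sum()
        k_terms = rng.poisson(config.go_terms_per_gene, size=n_genes)
        in_candidate = np.repeat(candidate_truth, cnt) & de_flags[sp]
        add_planted = in_candidate & (rng.random(n_genes) < config.go_planted_prob)
        # one bulk draw (with replacement, deduplicated per gene) instead of a
        # per-gene RNG call; keeps 100-seed studies cheap
        offsets = np.concatenate(([0], np.cumsum(k_terms)))
        draws = rng.integers(0, config.n_go_terms, size=int(k_terms.sum()))
        for g in range(n_genes):
            tset = {terms[t] for t in draws[offsets[g]:offsets[g + 1]]}
            if add_planted[g]:
                tset.add(planted_term)
            if tset:
                go_map[(sp, gene_ids[sp][g])] = frozenset(tset)

    # --- truth --------------------------------------------------------------
    conserved = np.logical_and.reduce([counts[sp] >= 1 for sp in species])
    truth = {"hog_id": hog_ids, "conserved": conserved}
    for h in hyp_list:
        truth[f"planted_{h.id}"] = planted[h.id]
    for sp in species:
        truth[f"any_deg_{sp}"] = any_deg[sp]
    truth_hogs = pd.DataFrame(truth)
    truth_genes = pd.concat(gene_truth_frames, ignore_index=True)

    return SyntheticDataset(
        config=config,
        study_config=study,
        orthogroups=orthogroups,
        de_tables=de_tables,
        selection=selection,
        go_map=go_map,
        truth_hogs=truth_hogs,
        truth_genes=truth_genes,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> None:
    """Write the dataset in the exact dialects the readers consume, plus the
    truth ledger. Deterministic: same dataset, same bytes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_orthogroups(ds.orthogroups, outdir / "orthogroups.tsv")
    for sp, table in ds.de_tables.items():
        write_de_table(table, outdir / f"de_{sp}.tsv")
    write_selection_table(ds.selection, outdir / "selection.tsv")
    write_go_map(ds.go_map, outdir / "go_map.tsv")
    write_config(ds.study_config, outdir / "config.yaml")
    _write_tsv(ds.truth_hogs.astype({c: int for c in ds.truth_hogs.columns if ds.truth_hogs[c].dtype == bool}), outdir / "truth_hogs.tsv")
    _write_tsv(ds.truth_genes.astype({c: int for c in ds.truth_genes.columns if ds.truth_genes[c].dtype == bool}), outdir / "truth_genes.tsv")


def recover(ds: SyntheticDataset, expansion: ExpansionResult, tier_counts: Mapping[str, int] | None = None) -> dict:
    """Score a completed run against the truth ledger.

    Returns precision/recall of expansion calls per hypothesis (over
    conserved families; planting guarantees rule satisfaction, so recall
    should be 1), observed-vs-configured family-level DE rates per species,
    and, when supplied, observed tier counts next to the truth-derived
    candidate count.
    """
    truth = ds.truth_hogs.set_index("hog_id")
    called_idx = expansion.matrix.index
    stray = set(called_idx) - set(truth.index)
    if stray:
        raise ValueError("expansion matrix families unknown to the truth record; mismatched run")
    truth_c = truth.loc[called_idx]
    report: dict = {"expansion": {}, "de_rates": {}}
    for hyp in expansion.matrix.columns:
        col = f"planted_{hyp}"
        if col not in truth_c.columns:
            continue
        called = expansion.matrix[hyp].to_numpy()
        true = truth_c[col].to_numpy()
        tp = int((called & true).sum())
        report["expansion"][hyp] = {
            "planted": int(true.sum()),
            "called": int(called.sum()),
            "recall": tp / true.sum() if true.sum() else float("nan"),
            "precision": tp / called.sum() if called.sum() else float("nan"),
        }
    conserved_truth = truth_c
    for sp in ds.study_config.species_names:
        observed = float(conserved_truth[f"any_deg_{sp}"].mean())
        report["de_rates"][sp] = {
            "configured": float(ds.config.de_base_rate.get(sp, float("nan"))),
            "observed_family_rate": observed,
        }
    truth_candidates = int(
        (
            conserved_truth["planted_exp_tolerant_both"]
            & np.logical_or.reduce(
                [conserved_truth[f"any_deg_{sp}"].to_numpy() for sp in ds.study_config.tolerant]
            )
        ).sum()
    )
    report["truth_candidate_count"] = truth_candidates
    if tier_counts is not None:
        report["tier_counts"] = dict(tier_counts)
    return report


def scramble_gene_ids(ds: SyntheticDataset, seed: int = 0) -> SyntheticDataset:
    """Replace every gene id with an opaque token (consistently across all
    tables) — used to verify the pipeline does not exploit the id encoding."""
    rng = np.random.default_rng(seed)
    all_ids = list(ds.truth_genes["gene_id"])
    perm = rng.permutation(len(all_ids))
    mapping = {g: f"x{p:07d}" for g, p in zip(all_ids, perm)}

    genes = ds.orthogroups.genes.copy()
    genes["gene_id"] = genes["gene_id"].map(mapping)
    orth = OrthogroupTable(genes, ds.orthogroups.species, ds.orthogroups.hog_ids, ds.orthogroups.og_ids)
    de_tables = {}
    for sp, t in ds.de_tables.items():
        df = t.df.copy()
        df["gene_id"] = df["gene_id"].map(mapping)
        de_tables[sp] = DETable(sp, df)
    sel = ds.selection.df.copy()
    sel["gene_id"] = sel["gene_id"].map(mapping)
    go = {(sp, mapping[g]): t for (sp, g), t in ds.go_map.items()}
    tg = ds.truth_genes.copy()
    tg["gene_id"] = tg["gene_id"].map(mapping)
    return SyntheticDataset(
        config=ds.config,
        study_config=ds.study_config,
        orthogroups=orth,
        de_tables=de_tables,
        selection=SelectionTable(sel),
        go_map=go,
        truth_hogs=ds.truth_hogs,
        truth_genes=tg,
    )
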