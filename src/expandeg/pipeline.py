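"""End-to-end orchestration: ingest -> Conserved Set -> expansion -> DE
integration -> enrichment battery -> selection -> candidate tiers -> GO,
with a machine-readable run manifest.

The manifest is a JSON document (schema: `manifest["schema"]`) holding the
config snapshot, input file hashes, per-stage row counts, every enrichment
result with its universe definition, tier counts, and the tool version.
Re-running on identical inputs reproduces an identical manifest; no
timestamps are recorded. The reporter renders the manifest only — it never
recomputes a number.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .candidates import (
    TierTable,
    build_tiers,
    conserved_de_enrichment,
    regulation_enrichment,
    unique_de_enrichment,
)
from .core_model import ConservedSet, ExpansionResult, StudyConfig, expansion_matrix, filter_conserved
from .de_integration import (
    DEFlagSet,
    conservation_stats,
    flag_degs,
    hog_de_flags,
    regulation_category,
)
from .enrichment_stats import EnrichmentResult
from .go_enrichment import go_over_representation, union_annotate
from .io_formats import (
    DETable,
    SelectionTable,
    read_config,
    read_de_table,
    read_go_map,
    read_orthogroups,
    read_selection_table,
    write_candidate_table,
    _write_tsv,
)
from .selection_integration import (
    SelectionFlags,
    flag_selection,
    selection_enrichment_families,
    selection_table_rows,
)

__all__ = ["RunResult", "run_analysis", "run", "report"]

MANIFEST_SCHEMA = "expandeg-manifest/1"


@dataclass
class RunResult:
    config: StudyConfig
    conserved: ConservedSet
    expansion: ExpansionResult
    de_flags: DEFlagSet
    tiers: TierTable
    battery: pd.DataFrame
    selection_tables: dict[str, pd.DataFrame]
    go_results: dict[str, pd.DataFrame]
    manifest: dict


def _enr_row(test_id: str, res: EnrichmentResult) -> dict:
    c = res.contingency
    return {
        "test_id": test_id,
        "universe": res.universe,
        "direction": res.direction,
        "k": c.k,
        "n": c.n,
        "K": c.K,
        "N": c.N,
        "fold": None if pd.isna(c.fold) else round(c.fold, 6),
        "p_value": res.p_value,
    }


def run_analysis(
    config: StudyConfig,
    orthogroups,
    de_tables: dict[str, DETable],
    selection: SelectionTable | None = None,
    go_map: dict | None = None,
    input_hashes: dict[str, str] | None = None,
) -> RunResult:
    """Run the full analysis on in-memory inputs."""
    missing = set(config.species_names) - set(de_tables)
    if missing:
        raise ValueError(f"missing DE tables for species {sorted(missing)}")

    conserved = filter_conserved(orthogroups, config.species_names)
    if conserved.N == 0:
        raise ValueError("empty conserved set: no family holds every species")

    expansion = expansion_matrix(conserved, config.hypotheses, config)
    flagged = {sp: flag_degs(de_tables[sp], config.alpha_de) for sp in config.species_names}
    de_flags = hog_de_flags(conserved, flagged)
    cons = conservation_stats(conserved, de_flags)
    tiers = build_tiers(conserved, expansion, de_flags, config)

    # --- enrichment battery: expansion x DE over the Conserved Set ---------
    battery_rows = []
    universe = list(conserved.hog_ids)
    any_deg = de_flags.any_deg
    from .enrichment_stats import enrich

    for h in config.hypotheses:
        subset = expansion.expanded_hogs(h.id)
        prop = any_deg.index[any_deg[list(h.focal)].all(axis=1)]
        res = enrich(
            subset, prop, universe, "over",
            universe_name="conserved set", label=f"de_in_expanded:{h.id}",
        )
        battery_rows.append(_enr_row(f"de_in_expanded:{h.id}", res))
    battery_rows.append(_enr_row("conserved_de_in_candidates", conserved_de_enrichment(tiers, de_flags)))
    battery_rows.append(
        _enr_row("conserved_de_in_contrast", conserved_de_enrichment(tiers, de_flags, contrast=True))
    )
    battery_rows.append(_enr_row("unique_de_in_conserved_de", unique_de_enrichment(tiers, de_flags)))

    # regulation enrichment within families DE in the tolerant group
    reg_tol = regulation_category(de_flags, scope=list(config.tolerant))
    reg_universe = list(any_deg.index[any_deg[list(config.tolerant)].any(axis=1)])
    reg_results = regulation_enrichment(tiers.tier("candidate"), reg_universe, reg_tol)
    for cat, res in reg_results.items():
        battery_rows.append(_enr_row(f"regulation_{cat}_in_candidates", res))
    battery = pd.DataFrame(battery_rows)

    # --- selection ----------------------------------------------------------
    selection_tables: dict[str, pd.DataFrame] = {}
    if selection is not None:
        gene_species = dict(zip(conserved.table.genes["gene_id"], conserved.table.genes["species"]))
        sel_flags = flag_selection(selection, config.alpha_sel, gene_species)
        gf = de_flags.gene_flags
        genes_by_sp = {sp: set(gf.loc[gf["species"] == sp, "gene_id"]) for sp in config.species_names}
        degs_by_sp = {
            sp: set(gf.loc[(gf["species"] == sp) & gf["de"], "gene_id"])
            for sp in config.species_names
        }
        # (a) DEGs vs all genes: under-representation
        selection_tables["table1_degs_vs_background"] = selection_table_rows(
            "degs_vs_all",
            {sp: {"subset": degs_by_sp[sp], "universe": genes_by_sp[sp]} for sp in config.species_names},
            sel_flags,
            "under",
        )
        # (b) genes in species-specific expanded families vs all genes: over
        sets_b = {}
        for sp in config.species_names:
            hyp = f"exp_{sp}"
            if hyp not in expansion.matrix.columns:
                continue
            hogs = set(expansion.expanded_hogs(hyp))
            sub = set(gf.loc[(gf["species"] == sp) & gf["hog_id"].isin(hogs), "gene_id"])
            sets_b[sp] = {"subset": sub, "universe": genes_by_sp[sp]}
        selection_tables["table2_expanded_vs_background"] = selection_table_rows(
            "expanded_genes_vs_all", sets_b, sel_flags, "over"
        )
        # (c) DEGs in expanded families vs all DEGs: over, plus the
        # family-level candidate/contrast rows in both counting conventions
        sets_c = {}
        for sp in config.species_names:
            hyp = f"exp_{sp}"
            if hyp not in expansion.matrix.columns:
                continue
            hogs = set(expansion.expanded_hogs(hyp))
            sub = degs_by_sp[sp] & set(gf.loc[gf["hog_id"].isin(hogs), "gene_id"])
            sets_c[sp] = {"subset": sub, "universe": degs_by_sp[sp]}
        table3 = selection_table_rows("degs_in_expanded_vs_degs", sets_c, sel_flags, "over")
        group_rows = []
        for label, hog_tier, group in (
            ("tolerant_candidates", "candidate", config.tolerant),
            ("sensitive_contrast", "contrast_candidate", config.sensitive),
        ):
            group_degs = set().union(*(degs_by_sp[sp] for sp in group))
            try:
                _, detail = selection_enrichment_families(
                    tiers.tier(hog_tier), group, sel_flags, gf, group_degs
                )
                detail.insert(0, "group", label)
                group_rows.append(detail)
            except ValueError:
                pass
        selection_tables["table3_degs_in_expanded"] = table3
        if group_rows:
            selection_tables["table3_group_families"] = pd.concat(group_rows, ignore_index=True)

    # --- GO ------------------------------------------------------------------
    go_results: dict[str, pd.DataFrame] = {}
    if go_map is not None:
        annotation = union_annotate(conserved, go_map)
        for tier_name in ("candidate", "conserved_de"):
            go_results[tier_name] = go_over_representation(
                tiers.tier(tier_name), conserved.hog_ids, annotation
            )

    # --- manifest ------------------------------------------------------------
    manifest = {
        "schema": MANIFEST_SCHEMA,
        "version": __version__,
        "config": {
            "species": [
                {"name": s.name, "ploidy": s.ploidy, "phenotype": s.phenotype}
                for s in config.species
            ],
            "alpha_de": config.alpha_de,
            "alpha_sel": config.alpha_sel,
            "expansion_factor": config.expansion_factor,
            "min_focal_copies": config.min_focal_copies,
            "hypotheses": [
                {"id": h.id, "focal": list(h.focal), "background": list(h.background), "factor": h.factor}
                for h in config.hypotheses
            ],
        },
        "input_hashes": input_hashes or {},
        "stages": {
            "n_families_input": len(orthogroups),
            "n_conserved": conserved.N,
            "absence_patterns": {"|".join(k): v for k, v in conserved.absence_patterns.items()},
            "n_degs_per_species": {
                sp: int(de_flags.summary.loc[sp, "n_degs"]) for sp in config.species_names
            },
            "n_hogs_with_deg_per_species": {
                sp: int(de_flags.summary.loc[sp, "n_hogs_with_deg"]) for sp in config.species_names
            },
            "n_degs_unassigned": {
                sp: int(de_flags.summary.loc[sp, "n_degs_unassigned"]) for sp in config.species_names
            },
            "expansion_counts": {
                h.id: int(expansion.matrix[h.id].sum()) for h in config.hypotheses
            },
        },
        "conservation": {
            "N": cons.N,
            "p_s": cons.p_s,
            "p_s4": cons.p_s4,
            "p_f4": cons.p_f4,
            "observed_all": cons.observed_all,
            "observed_none": cons.observed_none,
            "expected_all": cons.expected_all,
            "expected_none": cons.expected_none,
            "chi2_all": cons.chi2_all,
            "p_all": cons.p_all,
            "chi2_none": cons.chi2_none,
            "p_none": cons.p_none,
        },
        "tier_counts": tiers.counts(),
        "enrichment": battery.to_dict(orient="records"),
        "selection_tables": {k: v.to_dict(orient="records") for k, v in selection_tables.items()},
        "go_reported_terms": {
            k: v.loc[v["reported"], "term"].tolist() for k, v in go_results.items()
        },
    }

    return RunResult(
        config=config,
        conserved=conserved,
        expansion=expansion,
        de_flags=de_flags,
        tiers=tiers,
        battery=battery,
        selection_tables=selection_tables,
        go_results=go_results,
        manifest=manifest,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(config_path: str | Path, input_dir: str | Path, output_dir: str | Path) -> RunResult:
    """File-level entry point: read every input from `input_dir`, run the
    analysis, and write all outputs plus `manifest.json` to `output_dir`.

    Expected files: orthogroups.tsv, de_<species>.tsv per species,
    optional selection.tsv and go_map.tsv.
    """
    input_dir, output_dir = Path(input_dir), Path(output_dir)
    config = read_config(config_path)
    hashes = {}
    og_path = input_dir / "orthogroups.tsv"
    orthogroups = read_orthogroups(og_path, config)
    hashes["orthogroups.tsv"] = _sha256(og_path)
    de_tables = {}
    for sp in config.species_names:
        p = input_dir / f"de_{sp}.tsv"
        if not p.exists():
            raise FileNotFoundError(f"missing DE table for species {sp!r}: {p}")
        de_tables[sp] = read_de_table(p, sp)
        hashes[p.name] = _sha256(p)
    selection = None
    if (input_dir / "selection.tsv").exists():
        selection = read_selection_table(input_dir / "selection.tsv")
        hashes["selection.tsv"] = _sha256(input_dir / "selection.tsv")
    go_map = None
    if (input_dir / "go_map.tsv").exists():
        go_map = read_go_map(input_dir / "go_map.tsv")
        hashes["go_map.tsv"] = _sha256(input_dir / "go_map.tsv")

    result = run_analysis(config, orthogroups, de_tables, selection, go_map, hashes)

    output_dir.mkdir(parents=True, exist_ok=True)
    cand = build_candidate_frame(result)
    write_candidate_table(cand, output_dir / "candidate_table.tsv")
    _write_tsv(result.battery, output_dir / "enrichment_battery.tsv")
    _write_tsv(
        result.expansion.matrix.astype(int).reset_index(names="hog_id"),
        output_dir / "expansion_matrix.tsv",
    )
    for name, table in result.selection_tables.items():
        _write_tsv(table, output_dir / f"{name}.tsv")
    for name, table in result.go_results.items():
        out = table.copy()
        out["reported"] = out["reported"].astype(int)
        _write_tsv(out, output_dir / f"go_{name}.tsv")
    with open(output_dir / "conservation_report.txt", "w", encoding="utf-8", newline="\n") as fh:
        c = result.manifest["conservation"]
        fh.write("cross-species DE conservation (independence null)\n")
        for key in ("N", "p_s4", "p_f4", "observed_all", "expected_all", "p_all",
                    "observed_none", "expected_none", "p_none"):
            fh.write(f"{key}\t{c[key]}\n")
    with open(output_dir / "manifest.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(result.manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return result


def build_candidate_frame(result: RunResult) -> pd.DataFrame:
    """Per-family output table: copy counts, DE flags, regulation, tier and
    selection flags."""
    counts = result.conserved.table.counts.add_prefix("n_genes_")
    df = pd.concat([counts, result.tiers.df], axis=1)
    df = df.reset_index(names="hog_id")
    return df


def report(manifest: dict) -> str:
    """Human-readable markdown summary rendered from the manifest alone."""
    if manifest.get("schema") != MANIFEST_SCHEMA:
        raise ValueError(f"unknown manifest schema {manifest.get('schema')!r}")
    lines = []
    st = manifest["stages"]
    lines.append(f"# Analysis summary (expandeg {manifest['version']})")
    lines.append("")
    lines.append(f"Conserved families: {st['n_conserved']} of {st['n_families_input']} input families.")
    lines.append("")
    lines.append("## Differential expression per species")
    for sp, n in st["n_degs_per_species"].items():
        hogs = st["n_hogs_with_deg_per_species"][sp]
        lines.append(f"- {sp}: {n} DEGs in {hogs} families")
    c = manifest["conservation"]
    lines.append("")
    lines.append("## DE conservation null")
    lines.append(
        f"- DE in all species: observed {c['observed_all']}, expected {c['expected_all']:.1f} "
        f"(p_s4 = {100 * c['p_s4']:.1f}%), chi-square p = {c['p_all']:.3g}"
    )
    lines.append(
        f"- DE in no species: observed {c['observed_none']}, expected {c['expected_none']:.1f} "
        f"(p_f4 = {100 * c['p_f4']:.1f}%), chi-square p = {c['p_none']:.3g}"
    )
    lines.append("")
    lines.append("## Expansion counts per hypothesis")
    for hyp, cnt in st["expansion_counts"].items():
        lines.append(f"- {hyp}: {cnt} families")
    lines.append("")
    lines.append("## Candidate tiers")
    tier_defs = {
        "candidate": "expanded in both tolerant species, DE in >= 1 tolerant species",
        "conserved_de": "additionally DE in both tolerant species",
        "unique_up": "additionally no sensitive-species DEG and only up-regulated tolerant DEGs",
    }
    for tier, cnt in manifest["tier_counts"].items():
        suffix = f" ({tier_defs[tier]})" if tier in tier_defs else ""
        lines.append(f"- {tier}: {cnt} families{suffix}")
    lines.append("")
    lines.append("## Enrichment battery")
    for row in manifest["enrichment"]:
        lines.append(
            f"- {row['test_id']}: k/n = {row['k']}/{row['n']} vs K/N = {row['K']}/{row['N']} "
            f"({row['direction']}), p = {row['p_value']:.3g} [universe: {row['universe']}]"
        )
    if manifest.get("go_reported_terms"):
        lines.append("")
        lines.append("## GO terms passing the reporting filters")
        for tier, terms in manifest["go_reported_terms"].items():
            lines.append(f"- {tier}: {', '.join(terms) if terms else '(none)'}")
    return "\n".join(lines) + "\n"
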