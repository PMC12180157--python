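"""Readers and writers for every file the pipeline touches.

All files are UTF-8, LF-terminated, tab-separated text. Orthogroup
membership follows the hierarchical-orthogroup TSV dialect emitted by
OrthoFinder's phylogenetic orthology inference (``N0.tsv``): a header of
``HOG``, ``OG``, ``Gene Tree Parent Clade`` followed by one column per
species, each cell a comma+space separated gene list, empty cell meaning
no members. DE tables use the conventional count-based DE output columns
(gene, log2FoldChange, padj, baseMean), selection tables carry one
corrected p-value per tested gene, and the study configuration is a small
YAML document (flat keys plus a per-species table; see ``read_config``).

Writers are bit-stable: identical inputs produce byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .core_model import Hypothesis, OrthogroupTable, SpeciesProfile, StudyConfig

__all__ = [
    "DETable",
    "SelectionTable",
    "read_orthogroups",
    "write_orthogroups",
    "read_de_table",
    "write_de_table",
    "read_selection_table",
    "write_selection_table",
    "read_go_map",
    "write_go_map",
    "read_config",
    "write_config",
    "write_candidate_table",
]

_RESERVED_OG_COLUMNS = ("HOG", "OG", "Gene Tree Parent Clade")


@dataclass
class DETable:
    """One species' drought-vs-control differential-expression results.

    Rows with missing padj (the independent-filtering NA convention) are
    retained but can never be flagged differentially expressed.
    """

    species: str
    df: pd.DataFrame  # columns: gene_id, log2fc, padj, base_mean


@dataclass
class SelectionTable:
    """Per-gene diversifying-selection test results: corrected p-value for
    tested genes, tested=False (and no p) otherwise."""

    df: pd.DataFrame  # columns: gene_id, p_corrected, tested


# ---------------------------------------------------------------------------
# orthogroups


def read_orthogroups(path: str | Path, config: StudyConfig) -> OrthogroupTable:
    """Parse a hierarchical-orthogroup membership TSV.

    Species columns are re-ordered to config order. Unknown species columns,
    duplicate family ids, and genes assigned to two families are hard errors.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] not in ("HOG", "hog_id"):
            raise ValueError(f"{path}: first column must be 'HOG', got {header[:1]}")
        species_cols = [c for c in header if c not in _RESERVED_OG_COLUMNS and c != "hog_id"]
        unknown = set(species_cols) - set(config.species_names)
        if unknown:
            raise ValueError(f"{path}: unknown species column(s) {sorted(unknown)}")
        missing = set(config.species_names) - set(species_cols)
        if missing:
            raise ValueError(f"{path}: missing species column(s) {sorted(missing)}")
        idx = {c: i for i, c in enumerate(header)}

        hog_ids: list[str] = []
        og_ids: dict[str, str] = {}
        rows: list[tuple[str, str, str]] = []
        seen = set()
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ValueError(f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}")
            hog = fields[idx["HOG"]] if "HOG" in idx else fields[idx["hog_id"]]
            if not hog:
                raise ValueError(f"{path}:{lineno}: empty HOG id")
            if hog in seen:
                raise ValueError(f"{path}:{lineno}: duplicate hog_id {hog!r}")
            seen.add(hog)
            hog_ids.append(hog)
            if "OG" in idx and fields[idx["OG"]]:
                og_ids[hog] = fields[idx["OG"]]
            for sp in species_cols:
                cell = fields[idx[sp]].strip()
                if not cell:
                    continue
                for tok in cell.split(","):
                    gene = tok.strip()
                    if not gene:
                        raise ValueError(f"{path}:{lineno}: empty gene token in column {sp!r}")
                    rows.append((hog, sp, gene))

    genes = pd.DataFrame(rows, columns=["hog_id", "species", "gene_id"])
    return OrthogroupTable(genes, list(config.species_names), hog_ids, og_ids)


def write_orthogroups(table: OrthogroupTable, path: str | Path) -> None:
    path = Path(path)
    header = ["HOG", "OG", "Gene Tree Parent Clade", *table.species]
    by_hog: dict[str, dict[str, list[str]]] = {h: {} for h in table.hog_ids}
    for hog, sp, gene in table.genes.itertuples(index=False):
        by_hog[hog].setdefault(sp, []).append(gene)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(header) + "\n")
        for hog in sorted(table.hog_ids):
            cells = [hog, table.og_ids.get(hog, ""), ""]
            for sp in table.species:
                cells.append(", ".join(sorted(by_hog[hog].get(sp, []))))
            fh.write("\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# differential expression

_DE_ALIASES = {
    "gene_id": ("gene", "gene_id", "geneid", "id"),
    "log2fc": ("log2foldchange", "log2fc", "lfc", "logfc"),
    "padj": ("padj", "p_adj", "adj_pvalue", "adj_p", "fdr", "qvalue"),
    "base_mean": ("basemean", "base_mean"),
}


def _resolve_columns(columns: Sequence[str], aliases: Mapping[str, tuple[str, ...]],
                     required: Sequence[str], path: Path) -> dict[str, str]:
    lower = {c.lower(): c for c in columns}
    out = {}
    for canon, names in aliases.items():
        for name in names:
            if name in lower:
                out[canon] = lower[name]
                break
    for canon in required:
        if canon not in out:
            raise ValueError(f"{path}: no column found for {canon!r} (aliases {aliases[canon]})")
    return out


def _numeric(series: pd.Series, name: str, path: Path) -> pd.Series:
    converted = pd.to_numeric(series, errors="coerce")
    # distinguish genuine NA (allowed for padj) from unparsable text
    bad = converted.isna() & series.notna() & (series.astype(str).str.strip().str.upper() != "NA")
    bad &= series.astype(str).str.strip() != ""
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"{path}: non-numeric {name} {series.iloc[row]!r} at data row {row + 1}")
    return converted


def read_de_table(path: str | Path, species: str) -> DETable:
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    cols = _resolve_columns(raw.columns, _DE_ALIASES, ("gene_id", "log2fc", "padj"), path)
    df = pd.DataFrame({"gene_id": raw[cols["gene_id"]].astype(str)})
    df["log2fc"] = _numeric(raw[cols["log2fc"]], "log2FoldChange", path)
    if df["log2fc"].isna().any():
        row = int(np.flatnonzero(df["log2fc"].isna().to_numpy())[0])
        raise ValueError(f"{path}: missing log2FoldChange at data row {row + 1}")
    df["padj"] = _numeric(raw[cols["padj"]], "padj", path)
    out_of_range = df["padj"].notna() & ((df["padj"] < 0) | (df["padj"] > 1))
    if out_of_range.any():
        row = int(np.flatnonzero(out_of_range.to_numpy())[0])
        raise ValueError(
            f"{path}: padj {df['padj'].iloc[row]} outside [0, 1] at data row {row + 1}"
        )
    if "base_mean" in cols:
        df["base_mean"] = _numeric(raw[cols["base_mean"]], "baseMean", path)
        if (df["base_mean"].dropna() < 0).any():
            raise ValueError(f"{path}: negative baseMean")
    else:
        df["base_mean"] = np.nan
    if df["gene_id"].duplicated().any():
        dupe = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"{path}: duplicate gene id {dupe!r}")
    return DETable(species=species, df=df)


def write_de_table(table: DETable, path: str | Path) -> None:
    _write_tsv(
        table.df.sort_values("gene_id", kind="mergesort"),
        path,
        rename={"gene_id": "gene", "log2fc": "log2FoldChange", "base_mean": "baseMean"},
    )


# ---------------------------------------------------------------------------
# selection

_SEL_ALIASES = {
    "gene_id": ("gene", "gene_id", "geneid", "id"),
    "p_corrected": ("p_corrected", "pcorrected", "corrected_p", "padj", "p.adjusted"),
    "tested": ("tested",),
}


def read_selection_table(path: str | Path) -> SelectionTable:
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    cols = _resolve_columns(raw.columns, _SEL_ALIASES, ("gene_id", "p_corrected"), path)
    df = pd.DataFrame({"gene_id": raw[cols["gene_id"]].astype(str)})
    df["p_corrected"] = _numeric(raw[cols["p_corrected"]], "p_corrected", path)
    if "tested" in cols:
        df["tested"] = raw[cols["tested"]].astype(str).str.strip().isin(("1", "true", "True", "TRUE"))
    else:
        df["tested"] = df["p_corrected"].notna()
    if (df["tested"] & df["p_corrected"].isna()).any():
        raise ValueError(f"{path}: tested gene without a corrected p-value")
    if (~df["tested"] & df["p_corrected"].notna()).any():
        raise ValueError(f"{path}: untested gene carries a p-value")
    bad = df["p_corrected"].notna() & ((df["p_corrected"] < 0) | (df["p_corrected"] > 1))
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"{path}: p_corrected outside [0, 1] at data row {row + 1}")
    if df["gene_id"].duplicated().any():
        dupe = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"{path}: duplicate gene id {dupe!r}")
    return SelectionTable(df=df)


def write_selection_table(table: SelectionTable, path: str | Path) -> None:
    df = table.df.sort_values("gene_id", kind="mergesort").copy()
    df["tested"] = df["tested"].astype(int)
    _write_tsv(df, path, rename={"gene_id": "gene"})


# ---------------------------------------------------------------------------
# GO annotation map


def read_go_map(path: str | Path) -> dict[tuple[str, str], frozenset[str]]:
    """Gene -> GO-term map, keyed by (species, gene_id); terms are opaque
    comma-separated ids."""
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    need = {"gene", "species", "go_terms"}
    if not need.issubset({c.lower() for c in raw.columns}):
        raise ValueError(f"{path}: expected columns {sorted(need)}")
    raw.columns = [c.lower() for c in raw.columns]
    out: dict[tuple[str, str], frozenset[str]] = {}
    for rec in raw.itertuples(index=False):
        terms = frozenset(t.strip() for t in rec.go_terms.split(",") if t.strip())
        out[(rec.species, rec.gene)] = terms
    return out


def write_go_map(go_map: Mapping[tuple[str, str], frozenset[str]], path: str | Path) -> None:
    rows = [
        {"gene": gene, "species": sp, "go_terms": ",".join(sorted(terms))}
        for (sp, gene), terms in sorted(go_map.items())
    ]
    _write_tsv(pd.DataFrame(rows, columns=["gene", "species", "go_terms"]), path)


# ---------------------------------------------------------------------------
# study config


def read_config(path: str | Path) -> StudyConfig:
    """Read the YAML study configuration.

    Schema: flat scalar keys (alpha_de, alpha_sel, expansion_factor,
    min_focal_copies) plus a `species` list of {name, ploidy, phenotype}
    and an optional `hypotheses` list of {id, focal, background, factor}.
    When `hypotheses` is absent the standard phenotype contrasts are
    generated.
    """
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "species" not in doc:
        raise ValueError(f"{path}: config must be a mapping with a 'species' list")
    species = tuple(
        SpeciesProfile(
            name=str(s["name"]),
            ploidy=int(s.get("ploidy", 2)),
            phenotype=str(s.get("phenotype", "sensitive")),
        )
        for s in doc["species"]
    )
    hyps = tuple(
        Hypothesis(
            id=str(h["id"]),
            focal=tuple(h["focal"]),
            background=tuple(h["background"]),
            factor=float(h.get("factor", doc.get("expansion_factor", 2.0))),
        )
        for h in doc.get("hypotheses", [])
    )
    cfg = StudyConfig(
        species=species,
        alpha_de=float(doc.get("alpha_de", 0.1)),
        alpha_sel=float(doc.get("alpha_sel", 0.05)),
        expansion_factor=float(doc.get("expansion_factor", 2.0)),
        min_focal_copies=int(doc.get("min_focal_copies", 2)),
        hypotheses=hyps,
    )
    if not cfg.hypotheses:
        cfg = cfg.with_default_hypotheses()
    return cfg


def write_config(config: StudyConfig, path: str | Path) -> None:
    doc = {
        "alpha_de": config.alpha_de,
        "alpha_sel": config.alpha_sel,
        "expansion_factor": config.expansion_factor,
        "min_focal_copies": config.min_focal_copies,
        "species": [
            {"name": s.name, "ploidy": s.ploidy, "phenotype": s.phenotype}
            for s in config.species
        ],
        "hypotheses": [
            {"id": h.id, "focal": list(h.focal), "background": list(h.background), "factor": h.factor}
            for h in config.hypotheses
        ],
    }
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# candidate table


def write_candidate_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write the per-family candidate table, sorted by family id, booleans
    as 1/0. Deterministic: identical input gives byte-identical output."""
    df = records.copy()
    if "hog_id" in df.columns:
        df = df.sort_values("hog_id", kind="mergesort")
    for col in df.columns:
        if df[col].dtype == bool:
            df[col] = df[col].astype(int)
    _write_tsv(df, path)


def _write_tsv(df: pd.DataFrame, path: str | Path, rename: Mapping[str, str] | None = None) -> None:
    if rename:
        df = df.rename(columns=rename)
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(lambda v: "" if (v is None or (isinstance(v, float) and math.isnan(v))) else format(v, ".10g"))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        out.to_csv(fh, sep="\t", index=False, lineterminator="\n")
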