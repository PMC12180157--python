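"""Candidate tier composition, nesting, swap-symmetry, and the tier-level
enrichment tests."""

import numpy as np
import pandas as pd
import pytest

from expandeg.candidates import (
    build_tiers,
    conserved_de_enrichment,
    regulation_enrichment,
    unique_de_enrichment,
)
from expandeg.core_model import (
    ConservedSet,
    ExpansionResult,
    SpeciesProfile,
    StudyConfig,
    filter_conserved,
)
from expandeg.de_integration import DEFlagSet, categorize_regulation
from expandeg.enrichment_stats import enrich, hypergeom_over
from conftest import make_orthogroups


def build_inputs(config, spec_rows):
    """spec_rows: hog -> (expanded_tol_both, expanded_sen_both,
    {species: (n_up, n_down)})."""
    hogs = list(spec_rows)
    species = list(config.species_names)
    n_up = pd.DataFrame(0, index=hogs, columns=species)
    n_down = pd.DataFrame(0, index=hogs, columns=species)
    exp_tol = pd.Series(False, index=hogs)
    exp_sen = pd.Series(False, index=hogs)
    for hog, (tol, sen, per_sp) in spec_rows.items():
        exp_tol[hog], exp_sen[hog] = tol, sen
        for sp, (u, d) in per_sp.items():
            n_up.loc[hog, sp] = u
            n_down.loc[hog, sp] = d
    any_deg = (n_up + n_down) >= 1
    matrix = pd.DataFrame({"exp_tolerant_both": exp_tol, "exp_sensitive_both": exp_sen})
    members = {h: {sp: [f"{sp}_{h}"] for sp in species} for h in hogs}
    conserved = filter_conserved(make_orthogroups(members, species), species)
    expansion = ExpansionResult(matrix=matrix, per_species=pd.DataFrame(index=hogs))
    flags = DEFlagSet(n_up=n_up, n_down=n_down, any_deg=any_deg,
                      summary=pd.DataFrame(), gene_flags=pd.DataFrame())
    return conserved, expansion, flags


class TestTierLogic:
    def test_candidate_but_not_conserved_de(self, config4):
        conserved, expansion, flags = build_inputs(
            config4, {"H1": (True, False, {"tolA": (1, 0)})}
        )
        tiers = build_tiers(conserved, expansion, flags, config4)
        row = tiers.df.loc["H1"]
        assert row["candidate"] and not row["conserved_de"] and not row["unique_up"]

    def test_conserved_de_but_not_unique_up_when_sensitive_de(self, config4):
        conserved, expansion, flags = build_inputs(
            config4, {"H1": (True, False, {"tolA": (1, 0), "tolB": (1, 0), "senB": (1, 0)})}
        )
        row = build_tiers(conserved, expansion, flags, config4).df.loc["H1"]
        assert row["conserved_de"] and not row["unique_up"]

    def test_unique_up_requires_no_down_regulated_tolerant_deg(self, config4):
        conserved, expansion, flags = build_inputs(
            config4,
            {
                "H1": (True, False, {"tolA": (1, 0), "tolB": (1, 0)}),
                "H2": (True, False, {"tolA": (1, 1), "tolB": (1, 0)}),
            },
        )
        df = build_tiers(conserved, expansion, flags, config4).df
        assert df.loc["H1", "unique_up"] and not df.loc["H2", "unique_up"]
        # both readings agree here: H1 has two tolerant DEGs
        assert df.loc["H1", "unique_up_min2"]

    def test_planted_tier_counts_and_nesting(self, config4):
        """9 candidates, of which 4 conserved-DE, of which 2 unique-up."""
        rows = {}
        for i in range(9):
            if i < 2:
                per = {"tolA": (1, 0), "tolB": (1, 0)}  # unique up
            elif i < 4:
                per = {"tolA": (1, 0), "tolB": (1, 0), "senA": (1, 0)}  # conserved DE only
            else:
                per = {"tolA": (1, 0)}  # candidate only
            rows[f"H{i}"] = (True, False, per)
        rows["H9"] = (False, False, {"tolA": (3, 0)})  # DE but not expanded
        conserved, expansion, flags = build_inputs(config4, rows)
        tiers = build_tiers(conserved, expansion, flags, config4)
        counts = tiers.counts()
        assert (counts["candidate"], counts["conserved_de"], counts["unique_up"]) == (9, 4, 2)
        df = tiers.df
        assert (df["unique_up"] <= df["conserved_de"]).all()
        assert (df["conserved_de"] <= df["candidate"]).all()
        # independent set-algebra route to the candidate count
        brute = (
            expansion.matrix["exp_tolerant_both"]
            & flags.any_deg[["tolA", "tolB"]].any(axis=1)
        ).sum()
        assert counts["candidate"] == int(brute)

    def test_contrast_is_phenotype_swapped_image(self, config4):
        rows = {
            "H1": (True, False, {"tolA": (1, 0), "tolB": (1, 0)}),
            "H2": (False, True, {"senA": (1, 0), "senB": (1, 0)}),
            "H3": (False, True, {"senA": (1, 0), "tolA": (1, 0)}),
        }
        conserved, expansion, flags = build_inputs(config4, rows)
        tiers = build_tiers(conserved, expansion, flags, config4)

        swapped = StudyConfig(
            species=tuple(
                SpeciesProfile(s.name, s.ploidy,
                               "tolerant" if s.phenotype == "sensitive" else "sensitive")
                for s in config4.species
            )
        ).with_default_hypotheses()
        sw_matrix = expansion.matrix.rename(
            columns={"exp_tolerant_both": "exp_sensitive_both",
                     "exp_sensitive_both": "exp_tolerant_both"}
        )
        sw_exp = ExpansionResult(matrix=sw_matrix, per_species=expansion.per_species)
        sw_tiers = build_tiers(conserved, sw_exp, flags, swapped)
        for a, b in (
            ("contrast_candidate", "candidate"),
            ("contrast_conserved_de", "conserved_de"),
            ("contrast_unique_up", "unique_up"),
        ):
            assert tiers.df[a].equals(sw_tiers.df[b])


class TestTierEnrichments:
    def test_conserved_de_enrichment_counts(self, config4):
        rows = {}
        for i in range(40):
            per = {"tolA": (1, 0)}
            if i % 2 == 0:
                per["tolB"] = (1, 0)
            rows[f"H{i:02d}"] = (i < 10, False, per)
        conserved, expansion, flags = build_inputs(config4, rows)
        tiers = build_tiers(conserved, expansion, flags, config4)
        res = conserved_de_enrichment(tiers, flags)
        c = res.contingency
        assert (c.N, c.K, c.n, c.k) == (40, 20, 10, 5)
        assert res.p_value == pytest.approx(hypergeom_over(5, 10, 20, 40), abs=1e-14)

    def test_unique_de_partition(self, config4):
        rows = {}
        for i in range(30):
            per = {"tolA": (1, 0), "tolB": (1, 0)}
            if i % 3 == 0:
                per["senA"] = (1, 0)
            rows[f"H{i:02d}"] = (i < 12, False, per)
        conserved, expansion, flags = build_inputs(config4, rows)
        tiers = build_tiers(conserved, expansion, flags, config4)
        res = unique_de_enrichment(tiers, flags)
        c = res.contingency
        # property complement: families with / without sensitive DE partition n
        with_sensitive = c.n - c.k
        assert with_sensitive + c.k == c.n
        assert c.N == 30 and c.n == 12

    def test_unique_de_null_calibration(self, config4):
        """Independent sensitive-species DE: p >= 0.05 in >= 90/100 seeds."""
        ok = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            rows = {}
            for i in range(200):
                per = {"tolA": (1, 0), "tolB": (1, 0)}
                if rng.random() < 0.4:
                    per["senA"] = (1, 0)
                rows[f"H{i:03d}"] = (bool(rng.random() < 0.15), False, per)
            conserved, expansion, flags = build_inputs(config4, rows)
            tiers = build_tiers(conserved, expansion, flags, config4)
            ok += unique_de_enrichment(tiers, flags).p_value >= 0.05
        assert ok >= 90

    def test_regulation_enrichment_oracle_and_degenerate(self):
        """Universe of 300 families with category counts (100, 100, 100);
        subset of 30 with (20, 5, 5): the 'up' p-value equals the
        (20, 30, 100, 300) upper tail; subset == universe gives p = 1."""
        hogs = [f"H{i:03d}" for i in range(300)]
        n_up = pd.Series(0, index=hogs)
        n_down = pd.Series(0, index=hogs)
        # first 100: up; next 100: down; last 100: mixed
        n_up[:100] = 2
        n_down[100:200] = 2
        n_up[200:] = 1
        n_down[200:] = 1
        cats = categorize_regulation(n_up, n_down)
        subset = hogs[:20] + hogs[100:105] + hogs[200:205]
        out = regulation_enrichment(subset, hogs, cats)
        assert out["up"].p_value == pytest.approx(hypergeom_over(20, 30, 100, 300), abs=1e-14)
        degenerate = regulation_enrichment(hogs, hogs, cats)
        for res in degenerate.values():
            assert res.p_value == pytest.approx(1.0)
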