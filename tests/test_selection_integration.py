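"""Selection flagging and the gene-/family-level enrichment designs."""

import numpy as np
import pandas as pd
import pytest

from expandeg.enrichment_stats import hypergeom_over, hypergeom_under
from expandeg.io_formats import SelectionTable
from expandeg.selection_integration import (
    SelectionFlags,
    flag_selection,
    selection_enrichment_families,
    selection_enrichment_genes,
)


def sel_table(rows):
    return SelectionTable(pd.DataFrame(rows, columns=["gene_id", "p_corrected", "tested"]))


def make_flags(tested: set, selected: set, universe: list) -> SelectionFlags:
    df = pd.DataFrame(
        {
            "gene_id": universe,
            "tested": [g in tested for g in universe],
            "selected": [g in selected for g in universe],
            "p_corrected": [0.01 if g in selected else (0.5 if g in tested else np.nan) for g in universe],
        }
    )
    return SelectionFlags(df=df)


class TestFlagSelection:
    def test_boundary_p_is_inclusive(self):
        flags = flag_selection(sel_table([("g1", 0.05, True)]), 0.05)
        assert bool(flags.df.loc[0, "selected"])

    def test_untested_gene_is_never_selected(self):
        flags = flag_selection(sel_table([("g1", np.nan, False)]), 0.05)
        assert not flags.df["selected"].any()
        assert flags.df.loc[0, "gene_id"] not in flags.tested_genes()

    def test_per_species_tallies(self):
        """20 genes, 15 tested, 3 at p <= 0.05 -> tallies (15, 3)."""
        rows = []
        for i in range(20):
            tested = i < 15
            p = 0.01 if i < 3 else (0.5 if tested else np.nan)
            rows.append((f"g{i}", p, tested))
        flags = flag_selection(sel_table(rows), 0.05, {f"g{i}": "A" for i in range(20)})
        assert flags.per_species.loc["A", "n_tested"] == 15
        assert flags.per_species.loc["A", "n_selected"] == 3

    def test_raising_alpha_never_loses_selections(self):
        rng = np.random.default_rng(5)
        rows = [(f"g{i}", round(float(rng.random()), 4), True) for i in range(200)]
        t = sel_table(rows)
        previous = -1
        for alpha in (0.01, 0.05, 0.2, 0.5, 0.9):
            n = int(flag_selection(t, alpha).df["selected"].sum())
            assert n >= previous
            previous = n


class TestGeneLevelEnrichment:
    def test_toy_degs_in_expanded_vs_all_degs(self):
        """Universe of 40 tested DEGs with 8 selected; subset of 10 with 5
        selected: p equals the (5, 10, 8, 40) upper tail."""
        universe = [f"g{i}" for i in range(40)]
        selected = set(universe[:5]) | set(universe[20:23])  # 8 selected
        subset = universe[:10]  # holds 5 of the selected
        flags = make_flags(set(universe), selected, universe)
        res = selection_enrichment_genes(subset, flags, universe, "over")
        assert res.p_value == pytest.approx(hypergeom_over(5, 10, 8, 40), abs=1e-14)

    def test_subset_equal_universe_gives_fold_one_and_p_one(self):
        universe = [f"g{i}" for i in range(30)]
        flags = make_flags(set(universe), set(universe[:6]), universe)
        res = selection_enrichment_genes(universe, flags, universe, "over")
        assert res.fold == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_untested_genes_leave_both_sides(self):
        universe = [f"g{i}" for i in range(10)]
        flags = make_flags(set(universe[:4]), {"g0"}, universe)
        res = selection_enrichment_genes(universe[:6], flags, universe, "over")
        assert res.contingency.N == 4 and res.contingency.n == 4

    def test_empty_tested_universe_is_an_error(self):
        universe = ["g0", "g1"]
        flags = make_flags(set(), set(), universe)
        with pytest.raises(ValueError, match="empty tested universe"):
            selection_enrichment_genes(universe, flags, universe, "over")

    def test_null_designs_are_calibrated(self):
        """With DE assignment independent of selection, both the
        under-representation and over-representation designs stay above
        p = 0.05 in at least 90% of 100 seeds."""
        universe = [f"g{i}" for i in range(400)]
        ok_under = ok_over = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            selected = set(np.array(universe)[rng.random(400) < 0.1])
            subset = set(np.array(universe)[rng.random(400) < 0.3])
            flags = make_flags(set(universe), selected, universe)
            p_u = selection_enrichment_genes(subset, flags, universe, "under").p_value
            p_o = selection_enrichment_genes(subset, flags, universe, "over").p_value
            ok_under += p_u >= 0.05
            ok_over += p_o >= 0.05
        assert ok_under >= 90 and ok_over >= 90


def gene_flags_frame(rows):
    return pd.DataFrame(rows, columns=["hog_id", "species", "gene_id", "de", "up"])


class TestFamilyLevelEnrichment:
    def test_one_selected_deg_makes_the_family_a_success(self):
        gf = gene_flags_frame(
            [("H1", "tolA", "g1", True, True), ("H1", "tolB", "g2", True, True)]
        )
        flags = make_flags({"g1", "g2"}, {"g1"}, ["g1", "g2"])
        res, detail = selection_enrichment_families(
            ["H1"], ["tolA", "tolB"], flags, gf, ["g1", "g2"]
        )
        fam = detail[detail["convention"] == "family_numerator_gene_background"].iloc[0]
        assert fam["k"] == 1 and fam["n"] == 1

    def test_family_with_only_untested_degs_leaves_the_sample(self):
        gf = gene_flags_frame(
            [("H1", "tolA", "g1", True, True), ("H2", "tolA", "g2", True, True)]
        )
        flags = make_flags({"g1"}, set(), ["g1", "g2"])  # g2 untested
        res, detail = selection_enrichment_families(
            ["H1", "H2"], ["tolA"], flags, gf, ["g1", "g2"]
        )
        fam = detail[detail["convention"] == "family_numerator_gene_background"].iloc[0]
        assert fam["n"] == 1  # H2 excluded

    def test_planted_successes_are_counted(self):
        rows, tested, selected, genes = [], set(), set(), []
        for i in range(10):
            g = f"g{i}"
            rows.append((f"H{i}", "tolA", g, True, True))
            tested.add(g)
            genes.append(g)
            if i < 3:
                selected.add(g)
        flags = make_flags(tested, selected, genes)
        res, detail = selection_enrichment_families(
            [f"H{i}" for i in range(10)], ["tolA"], flags, gene_flags_frame(rows), genes
        )
        fam = detail[detail["convention"] == "family_numerator_gene_background"].iloc[0]
        assert fam["k"] == 3 and fam["n"] == 10

    def test_gene_and_family_counts_agree_with_one_deg_per_family(self):
        rows = [(f"H{i}", "tolA", f"g{i}", True, True) for i in range(12)]
        genes = [f"g{i}" for i in range(12)]
        flags = make_flags(set(genes), {"g0", "g5"}, genes)
        _, detail = selection_enrichment_families(
            [f"H{i}" for i in range(12)], ["tolA"], flags, gene_flags_frame(rows), genes
        )
        fam = detail[detail["convention"] == "family_numerator_gene_background"].iloc[0]
        gene = detail[detail["convention"] == "gene_level"].iloc[0]
        assert fam["k"] == gene["k"] and fam["n"] == gene["n"]
        assert fam["p_over"] == pytest.approx(gene["p_over"], abs=1e-14)
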