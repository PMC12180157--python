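"""Conserved-set filtering and ploidy-corrected expansion calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from expandeg.core_model import (
    Hypothesis,
    SpeciesProfile,
    StudyConfig,
    effective_count,
    expansion_matrix,
    filter_conserved,
    is_expanded,
)
from conftest import make_orthogroups


@pytest.mark.parametrize(
    "raw,ploidy,expected",
    [(4, 4, 2.0), (3, 2, 3.0), (3, 4, 1.5), (0, 2, 0.0)],
)
def test_effective_count_halves_tetraploid(raw, ploidy, expected):
    assert effective_count(raw, ploidy) == expected


def test_effective_count_rejects_bad_inputs():
    with pytest.raises(ValueError):
        effective_count(3, 1)
    with pytest.raises(ValueError):
        effective_count(-1, 2)


def test_species_profile_validation():
    with pytest.raises(ValueError):
        SpeciesProfile("x", 3, "tolerant")  # odd ploidy
    with pytest.raises(ValueError):
        SpeciesProfile("x", 2, "resistant")  # unknown phenotype


def test_config_requires_both_phenotype_classes():
    with pytest.raises(ValueError):
        StudyConfig(species=(SpeciesProfile("a", 2, "tolerant"), SpeciesProfile("b", 2, "tolerant")))


def test_filter_conserved_basic(config4):
    og = make_orthogroups(
        {
            "H1": {"tolA": ["a1"], "tolB": ["b1"], "senA": ["c1"], "senB": ["d1"]},
            "H2": {"tolA": ["a2", "a3"], "tolB": ["b2"], "senA": [], "senB": ["d2"]},
            "H3": {"tolA": [], "tolB": ["b3"], "senA": ["c2"], "senB": ["d3"]},
        },
        list(config4.species_names),
    )
    cs = filter_conserved(og, config4.species_names)
    assert cs.N == 1 and cs.hog_ids == ["H1"]
    assert cs.absence_patterns == {("senA",): 1, ("tolA",): 1}


def test_filter_conserved_identity_when_all_present(tiny_orthogroups, config4):
    cs = filter_conserved(tiny_orthogroups, config4.species_names)
    assert cs.hog_ids == ["H1", "H2"]
    assert cs.absence_patterns == {("senB",): 1}


def test_filter_conserved_reports_knockout_pattern(config4):
    """Five families, one species knocked out in two of them: the conserved
    set has three members and the report tallies the two absences."""
    members = {
        f"H{i}": {sp: [f"{sp}{i}"] for sp in config4.species_names} for i in range(5)
    }
    members["H1"]["senA"] = []
    members["H3"]["senA"] = []
    cs = filter_conserved(make_orthogroups(members, list(config4.species_names)), config4.species_names)
    assert cs.N == 3
    assert cs.absence_patterns == {("senA",): 2}


class TestIsExpanded:
    def test_tolerant_vs_both_sensitive_with_tetraploid_halving(self, config4):
        counts = {"tolA": 4, "tolB": 1, "senA": 2, "senB": 4}
        assert is_expanded(counts, "tolA", ["senA", "senB"], config4)  # 4 >= 2*2, 4 >= 2*2

    def test_not_expanded_when_one_background_too_close(self, config4):
        counts = {"tolA": 1, "tolB": 3, "senA": 2, "senB": 4}
        assert not is_expanded(counts, "tolB", ["senA", "senB"], config4)  # 3 < 2*2

    def test_min_focal_copies_guard_blocks_single_copy_calls(self, config4):
        # 1 vs (1 tetraploid-halved = 0.5) satisfies the ratio but not the guard
        counts = {"tolA": 1, "tolB": 1, "senA": 1, "senB": 1}
        assert not is_expanded(counts, "tolA", ["senB"], config4)
        relaxed = StudyConfig(
            species=config4.species, min_focal_copies=1, hypotheses=config4.hypotheses
        )
        assert is_expanded(counts, "tolA", ["senB"], relaxed)

    def test_tie_counts_as_expanded(self, config4):
        counts = {"tolA": 2, "tolB": 1, "senA": 1, "senB": 2}
        assert is_expanded(counts, "tolA", ["senA", "senB"], config4)  # 2 == 2*1 exactly

    def test_focal_in_background_is_an_error(self, config4):
        with pytest.raises(ValueError):
            is_expanded({"tolA": 2, "senA": 1}, "tolA", ["tolA", "senA"], config4)


@given(
    counts=st.tuples(st.integers(1, 30), st.integers(1, 30)),
    scale=st.integers(1, 5),
)
@settings(max_examples=200, derandomize=True)
def test_expansion_antisymmetry_and_scaling(counts, scale):
    """For factor 2, A-over-B and B-over-A cannot both hold; multiplying all
    counts by a positive integer leaves the call unchanged once the focal
    copy guard is met."""
    config4 = StudyConfig(
        species=(
            SpeciesProfile("tolA", 2, "tolerant"),
            SpeciesProfile("tolB", 2, "tolerant"),
            SpeciesProfile("senA", 2, "sensitive"),
            SpeciesProfile("senB", 4, "sensitive"),
        )
    )
    a, b = counts
    fam = {"tolA": a, "tolB": 1, "senA": b, "senB": 1}
    ab = is_expanded(fam, "tolA", ["senA"], config4)
    ba = is_expanded(fam, "senA", ["tolA"], config4)
    assert not (ab and ba)
    if a >= 2 and b >= 2:  # guard already satisfied before scaling
        scaled = {k: v * scale for k, v in fam.items()}
        assert is_expanded(scaled, "tolA", ["senA"], config4) == ab
        assert is_expanded(scaled, "senA", ["tolA"], config4) == ba


def test_expansion_matrix_and_semantics_and_intersections(config4):
    """20 families: 6 planted expansions in tolA, 5 in tolB, 2 overlapping;
    the matrix flags AND over focal species and the per-species intersection
    recovers the overlap exactly."""
    rng = np.random.default_rng(0)
    members = {}
    tolA_exp = set(range(6))            # families 0-5 expanded in tolA
    tolB_exp = set(range(4, 9))         # families 4-8 expanded in tolB; overlap {4, 5}
    for i in range(20):
        counts = {"tolA": 1, "tolB": 1, "senA": 1, "senB": 2}
        if i in tolA_exp:
            counts["tolA"] = 4
        if i in tolB_exp:
            counts["tolB"] = 4
        members[f"H{i:02d}"] = {
            sp: [f"{sp}_{i}_{j}" for j in range(counts[sp])] for sp in config4.species_names
        }
    og = make_orthogroups(members, list(config4.species_names))
    cs = filter_conserved(og, config4.species_names)
    res = expansion_matrix(cs, config4.hypotheses, config4)

    assert set(res.expanded_hogs("exp_tolA")) == {f"H{i:02d}" for i in tolA_exp}
    assert set(res.expanded_hogs("exp_tolB")) == {f"H{i:02d}" for i in tolB_exp}
    both = set(res.expanded_hogs("exp_tolerant_both"))
    assert both == {"H04", "H05"}
    assert set(res.intersection("tolA", "tolB")) == both
    # brute-force cross-check of the intersection count
    assert len(both) == len(tolA_exp & tolB_exp)


def test_expansion_matrix_single_focal_does_not_imply_group_flag(config4):
    members = {
        "H1": {"tolA": ["a"] * 4, "tolB": ["b"], "senA": ["c"], "senB": ["d", "e"]},
    }
    members = {
        h: {sp: [f"{sp}{i}" for i in range(len(g))] for sp, g in per.items()}
        for h, per in members.items()
    }
    og = make_orthogroups(members, list(config4.species_names))
    cs = filter_conserved(og, config4.species_names)
    res = expansion_matrix(cs, config4.hypotheses, config4)
    assert res.matrix.loc["H1", "exp_tolA"]
    assert not res.matrix.loc["H1", "exp_tolerant_both"]


def test_gene_in_two_families_is_rejected(config4):
    genes = pd.DataFrame(
        [("H1", "tolA", "g1"), ("H2", "tolA", "g1")],
        columns=["hog_id", "species", "gene_id"],
    )
    with pytest.raises(ValueError, match="g1"):
        from expandeg.core_model import OrthogroupTable

        OrthogroupTable(genes, list(config4.species_names))


def test_cross_species_id_collision_is_legal(config4):
    genes = pd.DataFrame(
        [("H1", "tolA", "g1"), ("H2", "tolB", "g1")],
        columns=["hog_id", "species", "gene_id"],
    )
    from expandeg.core_model import OrthogroupTable

    t = OrthogroupTable(genes, list(config4.species_names))
    assert t.counts.loc["H1", "tolA"] == 1 and t.counts.loc["H2", "tolB"] == 1
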