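import pandas as pd
import pytest

from expandeg.core_model import OrthogroupTable, SpeciesProfile, StudyConfig


@pytest.fixture
def config4() -> StudyConfig:
    """Four-species study: two tolerant diploids, one sensitive diploid, one
    sensitive tetraploid, with the standard phenotype-contrast hypotheses."""
    return StudyConfig(
        species=(
            SpeciesProfile("tolA", 2, "tolerant"),
            SpeciesProfile("tolB", 2, "tolerant"),
            SpeciesProfile("senA", 2, "sensitive"),
            SpeciesProfile("senB", 4, "sensitive"),
        )
    ).with_default_hypotheses()


def make_orthogroups(members: dict[str, dict[str, list[str]]], species: list[str]) -> OrthogroupTable:
    """Build an OrthogroupTable from {hog: {species: [genes]}}."""
    rows = [
        (hog, sp, gene)
        for hog, per_sp in members.items()
        for sp, genes in per_sp.items()
        for gene in genes
    ]
    genes = pd.DataFrame(rows, columns=["hog_id", "species", "gene_id"])
    return OrthogroupTable(genes, species, list(members))


@pytest.fixture
def tiny_orthogroups(config4) -> OrthogroupTable:
    """Three families over four species; H3 lacks senB (not conserved)."""
    return make_orthogroups(
        {
            "H1": {"tolA": ["a1", "a2"], "tolB": ["b1"], "senA": ["c1"], "senB": ["d1", "d2"]},
            "H2": {"tolA": ["a3"], "tolB": ["b2", "b3"], "senA": ["c2"], "senB": ["d3"]},
            "H3": {"tolA": ["a4"], "tolB": ["b4"], "senA": ["c3"], "senB": []},
        },
        list(config4.species_names),
    )
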