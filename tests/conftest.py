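import pytest

from chitomics.peptide_index import build_index
from chitomics.simulate import SimulationConfig, simulate_reference
from chitomics.taxonomy import TaxNode, TaxonomyTree


@pytest.fixture(scope="session")
def toy_tree() -> TaxonomyTree:
    """A hand-built eight-rank tree with two genera under one phylum."""
    return TaxonomyTree(
        [
            TaxNode(1, 1, "root", "root"),
            TaxNode(2, 1, "superkingdom", "Bacteria"),
            TaxNode(3, 2, "phylum", "Proteobacteria"),
            TaxNode(40, 3, "class", "Gammaproteobacteria"),
            TaxNode(50, 40, "order", "Cellvibrionales"),
            TaxNode(60, 50, "family", "Cellvibrionaceae"),
            TaxNode(61, 50, "family", "Nitrosomonadaceae"),
            TaxNode(70, 60, "genus", "Cellvibrio"),
            TaxNode(71, 61, "genus", "Nitrosospira"),
            TaxNode(80, 70, "species", "Cellvibrio mixtus"),
            TaxNode(81, 70, "species", "Cellvibrio japonicus"),
            TaxNode(90, 71, "species", "Nitrosospira briensis"),
        ]
    )


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A small but fully-featured synthetic study (fast to classify)."""
    return SimulationConfig(
        seed=11,
        n_genera=6,
        proteins_per_taxon=5,
        protein_len_range=(60, 120),
        depth_reads=300,
        read_len_nt=150,
    )


@pytest.fixture(scope="session")
def small_reference(small_config):
    return simulate_reference(small_config)


@pytest.fixture(scope="session")
def small_index(small_reference):
    return build_index(
        [(pep, taxid) for _, pep, taxid in small_reference.proteins],
        small_reference.tree,
    )
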