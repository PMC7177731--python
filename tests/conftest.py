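import numpy as np
import pytest

from genefamkit import phylo, simulate as sg


@pytest.fixture
def four_taxon_spec() -> sg.SpeciesTreeSpec:
    return sg.SpeciesTreeSpec("((A:1,B:1):0.5,(C:1,D:0.8):0.7);")


@pytest.fixture
def six_taxon_tree():
    """Rooted binary 6-taxon tree with labelled internal nodes; branch
    lengths in substitutions per codon."""
    tree = phylo.read_newick(
        "(((A:0.2,B:0.2):0.15,(C:0.2,D:0.2):0.15):0.1,(E:0.3,F:0.3):0.1);",
        rooted=True)
    sg.ensure_node_labels(tree)
    return tree


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
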