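import numpy as np
import pytest

from benthos.taxbin import TaxonomyTree


@pytest.fixture
def small_tree() -> TaxonomyTree:
    """Hand-built taxonomy: one phylum chain down to two genera/species.

        root(1) > phylum(2) > class(3) > order(4) > family(5=FamF)
        FamF > GenA(6), GenB(7); GenA > SpA1(8), SpA2(9); GenB > SpB1(10)
    """
    parents = {1: 1, 2: 1, 3: 2, 4: 3, 5: 4, 6: 5, 7: 5, 8: 6, 9: 6, 10: 7}
    ranks = {1: "root", 2: "phylum", 3: "class", 4: "order", 5: "family",
             6: "genus", 7: "genus", 8: "species", 9: "species", 10: "species"}
    names = {1: "root", 2: "PhyP", 3: "ClaC", 4: "OrdO", 5: "FamF",
             6: "GenA", 7: "GenB", 8: "SpA1", 9: "SpA2", 10: "SpB1"}
    return TaxonomyTree(parents, ranks, names)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
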