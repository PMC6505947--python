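import numpy as np
import pytest

from penguinproc.io_formats import (
    OtuTable,
    SampleMetadata,
    TaxonomyMap,
    tree_from_newick,
)


@pytest.fixture
def toy_table():
    return OtuTable(["s1", "s2"], ["Otu1", "Otu2", "Otu3"],
                    np.array([[1, 2, 3], [4, 5, 6]]))


@pytest.fixture
def toy_tree():
    return tree_from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def toy_metadata():
    return SampleMetadata({
        "s1": ("chinstrap", "feeding"),
        "s2": ("chinstrap", "moulting"),
    })


@pytest.fixture
def toy_taxonomy():
    return TaxonomyMap({
        "Otu1": ("Bacteria", "Fusobacteria", "Fusobacteriia",
                 "Fusobacteriales", "Fusobacteriaceae", "Fusobacterium"),
        "Otu2": ("Bacteria", "Fusobacteria", "Fusobacteriia",
                 "Fusobacteriales", "Fusobacteriaceae", "Cetobacterium"),
        "Otu3": ("Bacteria", "Firmicutes", "Clostridia",
                 "Clostridiales", "Lachnospiraceae", "Blautia"),
    })


def random_table(rng, n_samples=5, n_taxa=8, max_count=50, prefix=""):
    counts = rng.integers(0, max_count, size=(n_samples, n_taxa))
    # keep every row non-empty
    counts[:, 0] += 1
    return OtuTable(
        [f"{prefix}s{i}" for i in range(n_samples)],
        [f"{prefix}Otu{j:03d}" for j in range(n_taxa)],
        counts,
    )
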