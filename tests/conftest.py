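import numpy as np
import pytest
import scipy.sparse as sp

from clseq.model import CountMatrix, make_annotations, make_gene_table


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_matrix():
    counts = np.array(
        [
            [3, 0, 1],
            [0, 5, 2],
            [1, 1, 0],
            [4, 0, 0],
        ]
    )
    return CountMatrix(sp.csc_matrix(counts), ["gA", "gB", "gC", "gD"], ["L1", "L2", "L3"])


@pytest.fixture
def tiny_annotations(tiny_matrix):
    return make_annotations(tiny_matrix, kind="single", condition="control")


@pytest.fixture
def random_matrix(rng):
    dense = rng.poisson(1.0, size=(20, 10))
    genes = [f"g{i:02d}" for i in range(20)]
    libs = [f"b{i:02d}" for i in range(10)]
    return CountMatrix(sp.csc_matrix(dense), genes, libs)


@pytest.fixture
def gene_table(tiny_matrix):
    return make_gene_table(
        list(tiny_matrix.gene_ids),
        flags={"gA": {"mitochondrial"}, "gD": {"sex_linked"}},
    )
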