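import numpy as np
import pandas as pd
import pytest

from hfsig.iolib import BulkCohort, ExpressionMatrix, GeneSet, GeneSetCollection
from hfsig.synthdata import SyntheticSpec


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_matrix():
    """3 genes x 4 columns counts matrix."""
    return ExpressionMatrix(
        ["gA", "gB", "gC"],
        ["c1", "c2", "c3", "c4"],
        np.array([[1.0, 0.0, 3.0, 2.0],
                  [0.0, 2.0, 1.0, 0.0],
                  [4.0, 1.0, 0.0, 5.0]]),
        layer="counts",
    )


@pytest.fixture
def tiny_spec():
    return SyntheticSpec(
        n_genes=200,
        n_cells_per_cluster=40,
        clusters=(("B", "C1"), ("B", "C2"), ("NK", "C1")),
        n_markers_per_cluster=8,
        marker_log2_shift=2.0,
        n_bulk_samples_per_class=20,
        panel_size=10,
        panel_effect=2.0,
        n_true_sets=2,
        n_null_sets=6,
        set_size=12,
        seed=7,
    )


def make_bulk(values: np.ndarray, n_pos: int, gene_prefix: str = "g") -> BulkCohort:
    """BulkCohort from a genes x samples array; first n_pos columns positive."""
    n_genes, n_samples = values.shape
    genes = [f"{gene_prefix}{i:03d}" for i in range(n_genes)]
    samples = [f"s{j:03d}" for j in range(n_samples)]
    labels = pd.Series(
        ["positive"] * n_pos + ["negative"] * (n_samples - n_pos), index=samples
    )
    return BulkCohort(ExpressionMatrix(genes, samples, values, layer="lognorm"), labels)


def make_collection(sets: dict[str, tuple[str, ...]], category: str = "GOBP"
                    ) -> GeneSetCollection:
    coll = GeneSetCollection()
    for name, members in sets.items():
        coll.add(GeneSet(name, category, tuple(members)))
    return coll
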