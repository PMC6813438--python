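import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from phyloturn import CommunityTable, PhyloTree

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_table():
    # 3 samples x 5 OTUs with singletons, single-sample OTUs and shared OTUs
    counts = np.array(
        [
            [5, 1, 0, 3, 0],
            [4, 0, 1, 2, 0],
            [6, 0, 0, 1, 1],
        ]
    )
    return CommunityTable(["A", "B", "C"], [f"o{i}" for i in range(1, 6)], counts)


@pytest.fixture
def three_tip_tree():
    return PhyloTree.from_newick("((A:0.5,B:0.5):0.5,C:1);")


@pytest.fixture
def metadata6():
    df = pd.DataFrame(
        {"depth_m": [2801.0, 2939.0, 1250.0, 880.0, 79.0, 1469.0]},
        index=["ST11", "ST32", "ST61", "ST65", "ST76", "ST81"],
    )
    df.index.name = "sample_id"
    return df


def random_instance(rng, max_samples=10, max_taxa=30, min_samples=3, min_taxa=4):
    """A random tree + community table over its tips, for oracle checks."""
    from phyloturn.simulate import simulate_yule_tree

    n_taxa = int(rng.integers(min_taxa, max_taxa + 1))
    n_samples = int(rng.integers(min_samples, max_samples + 1))
    tree = simulate_yule_tree(n_taxa, seed=int(rng.integers(2**31)))
    # abundance with zeros but no empty samples
    counts = rng.integers(0, 20, size=(n_samples, n_taxa))
    for i in range(n_samples):
        if counts[i].sum() == 0:
            counts[i, int(rng.integers(n_taxa))] = 1
    table = CommunityTable(
        [f"s{i}" for i in range(n_samples)], list(tree.tip_labels), counts
    )
    return tree, table
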