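import numpy as np
import pandas as pd
import pytest

from assemblage.io import CountTable, SampleMetadata, read_newick
from assemblage.phylo import cophenetic_distances


@pytest.fixture
def five_tip_tree():
    return read_newick("((A:1,B:2):0.5,(C:1.5,(D:0.5,E:0.5):1):0.5);")


@pytest.fixture
def five_tip_dist(five_tip_tree):
    return cophenetic_distances(five_tip_tree)


@pytest.fixture
def toy_counts():
    frame = pd.DataFrame(
        [[5.0, 0.0, 3.0, 0.0, 2.0],
         [0.0, 1.0, 4.0, 2.0, 0.0],
         [1.0, 1.0, 1.0, 1.0, 1.0]],
        index=["s1", "s2", "s3"],
        columns=["A", "B", "C", "D", "E"],
    )
    return CountTable(frame)


@pytest.fixture
def toy_metadata():
    frame = pd.DataFrame(
        {
            "well_id": ["w1", "w1", "w2"],
            "collection_day": [0, 90, 0],
            "pH": [8.0, 8.4, 11.2],
            "temperature": [17.0, 18.5, np.nan],
        },
        index=["s1", "s2", "s3"],
    )
    return SampleMetadata(frame)


@pytest.fixture
def star_dist():
    """Star phylogeny: every tip at distance 2 from the hub, 4 apart."""
    from assemblage.phylo import TipDistanceMatrix

    ids = ("a", "b", "c", "d")
    d = np.full((4, 4), 4.0)
    np.fill_diagonal(d, 0.0)
    return TipDistanceMatrix(ids, d)
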