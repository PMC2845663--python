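import numpy as np
import pandas as pd
import pytest

from standscape.core import GenotypeTable, Marker, MarkerMap


def make_map(n_markers=10, n_chrom=2, spacing=100_000):
    markers = []
    per = n_markers // n_chrom + (n_markers % n_chrom > 0)
    k = 0
    for c in range(1, n_chrom + 1):
        for i in range(per):
            if k >= n_markers:
                break
            markers.append(Marker(f"m{k}", c, (i + 1) * spacing, "A", "C"))
            k += 1
    return MarkerMap(markers)


def make_table(calls, stand_ids=None, marker_map=None, years=None, transect=None):
    calls = np.asarray(calls, dtype=np.int8)
    n = calls.shape[0]
    if marker_map is None:
        marker_map = make_map(calls.shape[1])
    if stand_ids is None:
        stand_ids = ["S1"] * n
    meta = pd.DataFrame(
        {
            "sample_id": [f"p{i}" for i in range(n)],
            "stand_id": stand_ids,
            "year": years if years is not None else [2007] * n,
            "transect_index": pd.array(
                transect if transect is not None else [pd.NA] * n, dtype="Int64"
            ),
        }
    )
    return GenotypeTable(meta, calls, marker_map)


@pytest.fixture
def tiny_map():
    return make_map(6, n_chrom=2)


@pytest.fixture
def three_stand_table():
    calls = np.array(
        [
            [0, 0, 0, 0, 0, 0],
            [0, 0, 0, 0, 0, 0],
            [2, 2, 2, 2, 2, 2],
            [2, 2, 2, 0, 0, 0],
            [1, 1, 1, 1, 1, 1],
            [0, 2, 0, 2, 0, 2],
        ],
        dtype=np.int8,
    )
    return make_table(calls, stand_ids=["A", "A", "B", "B", "C", "C"])
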