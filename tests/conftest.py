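import numpy as np
import pytest

from ecoassembly.data_model import OtuTable, SampleMetadata
import pandas as pd


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table():
    counts = np.array(
        [
            [5, 0, 3, 2],
            [1, 4, 0, 7],
            [0, 2, 6, 1],
        ]
    )
    return OtuTable(counts, ["S1", "S2", "S3"], ["O1", "O2", "O3", "O4"])


@pytest.fixture
def random_table(rng):
    counts = rng.integers(0, 50, size=(10, 20))
    counts[:, 0] += 1  # avoid all-zero samples
    return OtuTable(
        counts,
        [f"S{i}" for i in range(10)],
        [f"O{j}" for j in range(20)],
    )


@pytest.fixture
def small_metadata():
    df = pd.DataFrame(
        {
            "latitude": [44.0, 45.0, 46.0, 47.0],
            "longitude": [81.0, 82.5, 84.0, 85.5],
            "altitude": [1200.0, 1800.0, 2400.0, 2900.0],
            "MAT": [2.0, 1.0, 0.0, -1.0],
            "MAP": [200.0, 300.0, 400.0, 500.0],
            "PET": [1000.0, 1000.0, 1250.0, 1250.0],
            "AI": [0.2, 0.3, 0.32, 0.4],
            "SM": [10.0, 20.0, 25.0, 30.0],
            "pH": [4.5, 5.5, 6.5, 7.4],
            "TSN": [1.0, 2.0, 3.0, 4.0],
            "TSP": [0.4, 0.6, 0.8, 1.0],
            "TOC": [10.0, 30.0, 50.0, 70.0],
            "AN": [50.0, 120.0, 190.0, 260.0],
            "CN": [8.0, 11.0, 14.0, 17.0],
            "NP": [2.0, 6.0, 10.0, 14.0],
        },
        index=pd.Index(["S1", "S2", "S3", "S4"], name="sample_id"),
    )
    return SampleMetadata(df)
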