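import numpy as np
import pandas as pd
import pytest

from ifxpanel.io import (
    CountTable,
    CtMatrix,
    Metadata,
    SampleMeta,
    TaxonomyMap,
)


@pytest.fixture
def toy_counts() -> CountTable:
    """3 taxa x 4 samples with easy totals."""
    return CountTable(
        pd.DataFrame(
            {
                "S1": [2, 3, 5],
                "S2": [1, 0, 9],
                "S3": [4, 4, 2],
                "S4": [0, 0, 10],
            },
            index=["T1", "T2", "T3"],
            dtype=np.int64,
        )
    )


@pytest.fixture
def toy_taxonomy() -> TaxonomyMap:
    return TaxonomyMap(
        {
            "T1": ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales",
                   "Lachnospiraceae", "Blautia"),
            "T2": ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales",
                   "Lachnospiraceae", "Blautia"),
            "T3": ("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales",
                   "Rikenellaceae", "unassigned"),
        }
    )


@pytest.fixture
def toy_meta() -> Metadata:
    rows = []
    for i in range(2):
        rows.append(SampleMeta(f"S{i+1}", f"P{i+1}", "CD", "pre", "R"))
    for i in range(2, 4):
        rows.append(SampleMeta(f"S{i+1}", f"P{i+1}", "CD", "pre", "NONR"))
    return Metadata(rows)


@pytest.fixture
def toy_ct() -> CtMatrix:
    genes = ["TNF", "IL18", "ACTB", "B2M"]
    data = pd.DataFrame(
        {
            "S1": [25.0, 24.0, 20.0, 20.0],
            "S2": [26.0, 22.0, 19.5, 20.5],
            "S3": [22.0, 28.0, 20.2, 19.8],
            "S4": [23.0, 27.0, 20.1, 19.9],
        },
        index=genes,
    )
    return CtMatrix(data, ("ACTB", "B2M"))
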