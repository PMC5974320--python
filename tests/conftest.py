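import numpy as np
import pandas as pd
import pytest

from tomoloc.io_formats import CqTable, SegmentTable


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def small_rna_table():
    """Two genes, five segments, two replicates."""
    data = pd.DataFrame(
        {
            "A_r1": [60.0, 10.0], "B_r1": [20.0, 10.0], "C_r1": [10.0, 15.0],
            "D_r1": [5.0, 35.0], "E_r1": [5.0, 30.0],
            "A_r2": [58.0, 12.0], "B_r2": [22.0, 9.0], "C_r2": [10.0, 14.0],
            "D_r2": [6.0, 36.0], "E_r2": [4.0, 29.0],
        },
        index=["gene_an", "gene_vg"],
    )
    return SegmentTable(data, ["A", "B", "C", "D", "E"], [1, 2], "rna")


@pytest.fixture
def flat_cq_table():
    """One anchor with equal Cq everywhere (uniform distribution)."""
    cols = {f"{s}_r{r}": [10.0] for s in "ABCDE" for r in (1, 2)}
    data = pd.DataFrame(cols, index=["anc1"])
    return CqTable(data, ["A", "B", "C", "D", "E"], [1, 2])
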