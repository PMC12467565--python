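import numpy as np
import pandas as pd
import pytest

from altifun.io import RANKS, FunctionMatrix, OtuTable


def make_otu_table(counts: dict[str, list[int]], groups: dict[str, str],
                   taxonomy: dict[str, str] | None = None) -> OtuTable:
    """Small helper: counts maps sample -> column of counts over taxa t1..tn."""
    df = pd.DataFrame(counts)
    df.index = [f"t{i+1}" for i in range(df.shape[0])]
    tax = pd.DataFrame(index=df.index, columns=RANKS, dtype=object)
    tax["kingdom"] = "Bacteria"
    tax["phylum"] = [
        (taxonomy or {}).get(t, f"P{(i % 3) + 1}") for i, t in enumerate(df.index)
    ]
    tax["genus"] = ["g_" + t for t in df.index]
    meta = pd.DataFrame({"group": pd.Series(groups)})
    meta["replicate"] = range(1, len(meta) + 1)
    return OtuTable(df, tax, meta)


@pytest.fixture
def toy_table() -> OtuTable:
    return make_otu_table(
        {"s1": [5, 3, 1, 1], "s2": [2, 2, 0, 6], "s3": [1, 0, 9, 0], "s4": [4, 4, 4, 4]},
        {"s1": "A", "s2": "A", "s3": "B", "s4": "B"},
    )


@pytest.fixture
def toy_function_matrix() -> FunctionMatrix:
    rng = np.random.default_rng(42)
    plots = [f"p{i}" for i in range(8)]
    cols = {
        "c1": "EF-C", "c2": "EF-C", "n1": "EF-N", "n2": "EF-N",
        "p1": "EF-P", "prod1": "EF-Prod",
    }
    values = pd.DataFrame(
        rng.normal(10, 2, size=(8, len(cols))), index=plots, columns=list(cols)
    )
    groups = pd.Series(["G1"] * 4 + ["G2"] * 4, index=plots)
    return FunctionMatrix(values, cols, groups)
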