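import numpy as np
import pandas as pd
import pytest

from cafet import ExpressionMatrix, SampleGrouping


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 probes (2 genes, one multi-probe) x 4 samples, linear scale."""
    values = pd.DataFrame(
        [[100.0, 120.0, 110.0, 300.0],
         [90.0, 100.0, 95.0, 260.0],
         [50.0, 55.0, 45.0, 40.0]],
        index=["TP53_p1", "TP53_p2", "MYC_p1"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(
        values=values,
        probe_to_gene={"TP53_p1": "TP53", "TP53_p2": "TP53", "MYC_p1": "MYC"},
    )


@pytest.fixture
def two_block_matrix() -> tuple[ExpressionMatrix, SampleGrouping]:
    """10 probes x 8 samples with a clean two-block structure.

    Samples a1..a4 share one expression profile, b1..b4 another, far apart
    in probe space relative to the within-block noise.
    """
    rng = np.random.default_rng(42)
    a_profile = rng.uniform(100, 200, size=10)
    b_profile = a_profile * 8
    cols = {}
    for i in range(4):
        cols[f"a{i+1}"] = a_profile * rng.normal(1, 0.01, size=10)
        cols[f"b{i+1}"] = b_profile * rng.normal(1, 0.01, size=10)
    values = pd.DataFrame(cols, index=[f"p{i}" for i in range(10)])
    matrix = ExpressionMatrix(values=values,
                              probe_to_gene={f"p{i}": f"g{i}" for i in range(10)})
    grouping = SampleGrouping(
        group1=frozenset({"a1", "a2", "a3", "a4"}),
        group2=frozenset({"b1", "b2", "b3", "b4"}),
    )
    return matrix, grouping
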