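import numpy as np
import pandas as pd
import pytest

from middascan import (
    ExpressionMatrix,
    GeneOrder,
    GeneRecord,
    SimulationConfig,
    simulate,
)


def make_order(n, contig="c1", prefix="g"):
    return GeneOrder(
        GeneRecord(f"{prefix}{i:04d}", contig, i * 1500 + 1, i * 1500 + 1000, "+")
        for i in range(n)
    )


@pytest.fixture
def order10():
    return make_order(10)


@pytest.fixture
def toy_matrix():
    """Four genes, two conditions x two replicates, hand-pickable values."""
    values = pd.DataFrame(
        {
            "p1": [8.0, 4.0, 0.0, 3.0],
            "p2": [8.0, 4.0, 0.0, 5.0],
            "n1": [2.0, 4.0, 4.0, 1.0],
            "n2": [2.0, 4.0, 4.0, 3.0],
        },
        index=pd.Index(["gA", "gB", "gC", "gD"], name="gene_id"),
    )
    sheet = pd.DataFrame(
        {
            "sample_id": ["p1", "p2", "n1", "n2"],
            "condition": ["prod", "prod", "non", "non"],
            "replicate": ["1", "2", "1", "2"],
        }
    )
    return ExpressionMatrix(values, sheet)


@pytest.fixture(scope="session")
def default_sim():
    """The default benchmark scenario at seed 1."""
    return simulate(SimulationConfig(), seed=1)
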