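import numpy as np
import pandas as pd
import pytest

from mimgo.enrichment_core import EnrichmentParams, run_all_pairs
from mimgo.expression import ExpressionMatrix
from mimgo.synthetic_data import (PlantedSet, SyntheticSpec,
                                  default_conditions, simulate)


@pytest.fixture
def tiny_expr():
    """5 genes x 3 conditions with hand-pickable ratios."""
    data = pd.DataFrame(
        {
            "c1": [4.0, 1.0, 2.0, 1.0, 0.5],
            "c2": [1.0, 1.0, 1.0, 2.0, 1.0],
            "c3": [2.0, 4.0, 0.5, 1.0, 1.0],
        },
        index=["g1", "g2", "g3", "g4", "g5"],
    )
    return ExpressionMatrix(data)


@pytest.fixture(scope="session")
def small_sim():
    """Seeded 6-condition simulation with two planted and two decoy sets."""
    spec = SyntheticSpec(
        n_genes=300,
        conditions=default_conditions(6),
        planted_sets=[
            PlantedSet(size=8, peaks=(1,), fold=4.0),
            PlantedSet(size=8, peaks=(2, 4), fold=4.0),
        ],
        n_decoy_sets=2,
        decoy_size=8,
        noise_sigma=0.3,
        seed=7,
    )
    return simulate(spec)


@pytest.fixture(scope="session")
def small_tensor(small_sim):
    expr, coll, _ = small_sim
    params = EnrichmentParams(n_perm=100, seed=7)
    return run_all_pairs(expr, coll, params)
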