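import numpy as np
import pandas as pd
import pytest

import mbgraph as mg


@pytest.fixture
def tiny_table() -> mg.AbundanceTable:
    """2 samples x 3 taxa, with one zero cell."""
    return mg.AbundanceTable(
        pd.DataFrame(
            [[10, 5, 0], [2, 0, 8]],
            index=["s1", "s2"],
            columns=["t1", "t2", "t3"],
        )
    )


@pytest.fixture
def synthetic_trio():
    """Default synthetic cohort: 10 samples, 2 groups, planted structure."""
    return mg.generate(mg.SyntheticSpec(seed=42))


@pytest.fixture
def synthetic_graph(synthetic_trio):
    table, taxonomy, metadata = synthetic_trio
    return mg.build_graph(table, taxonomy=taxonomy, metadata=metadata)


def random_table(rng: np.random.Generator, max_samples=12, max_taxa=30,
                 density=0.4) -> mg.AbundanceTable:
    """Random sparse count table with no all-zero row/column."""
    while True:
        n = rng.integers(2, max_samples + 1)
        m = rng.integers(2, max_taxa + 1)
        counts = rng.integers(0, 50, size=(n, m))
        counts[rng.random(size=(n, m)) > density] = 0
        if (counts.sum(axis=1) > 0).all() and (counts.sum(axis=0) > 0).all():
            return mg.AbundanceTable(
                pd.DataFrame(
                    counts,
                    index=[f"s{i}" for i in range(n)],
                    columns=[f"t{j}" for j in range(m)],
                )
            )
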