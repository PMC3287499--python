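import numpy as np
import pandas as pd
import pytest

import condegree as cd


@pytest.fixture(scope="session")
def small_two_class():
    """30+30 samples, 150 genes (20 informative, 3-SD shift), seed 1."""
    expr, clin = cd.simulate_two_class(cd.SimConfig(seed=1))
    aligned, y = cd.align(expr, clin, "class")
    return aligned, y


@pytest.fixture()
def tiny_expr():
    rng = np.random.default_rng(0)
    genes = [f"g{i}" for i in range(6)]
    samples = [f"s{j}" for j in range(8)]
    return cd.ExpressionMatrix(genes, samples, rng.normal(size=(6, 8)))


@pytest.fixture()
def surv_clin():
    """Ten samples, times 100..1000, all events."""
    idx = [f"s{j}" for j in range(10)]
    df = pd.DataFrame(
        {"days": np.arange(100, 1100, 100, dtype=float), "event": 1},
        index=idx,
    )
    return cd.ClinicalTable(df, time_col="days", event_col="event")
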