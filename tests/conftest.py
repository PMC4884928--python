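import numpy as np
import pandas as pd
import pytest

from exitpaths.synthetic import SimConfig, gen_expression_dataset


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Small but fully structured scenario shared across tests."""
    return SimConfig(n_genes=400, n_drugs=8, n_controls=14, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return gen_expression_dataset(small_cfg)


@pytest.fixture()
def tiny_screen() -> pd.DataFrame:
    """Three drugs x two doses, hand-checkable numbers."""
    rows = []
    for drug, pcts, lives in [
        ("a", (12, 10), (480, 500)),
        ("b", (22, 20), (490, 510)),
        ("c", (35, 30), (500, 520)),
    ]:
        rows.append((drug, 1.0, pcts[0], lives[0]))
        rows.append((drug, 10.0, pcts[1], lives[1]))
    return pd.DataFrame(rows, columns=["drug", "dose", "pct_differentiated", "live_cells"])


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
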