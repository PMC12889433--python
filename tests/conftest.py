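import numpy as np
import pandas as pd
import pytest

from bamscape.synthetic_data import SyntheticConfig


@pytest.fixture
def toy_cells() -> pd.DataFrame:
    """Two clusters: A has 5 AD of 10 cells, B has 5 AD of 20."""
    rows = []
    for i in range(10):
        rows.append(("A", "AD" if i < 5 else "healthy"))
    for i in range(20):
        rows.append(("B", "AD" if i < 5 else "healthy"))
    return pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(len(rows))],
            "patient_id": ["p0"] * len(rows),
            "condition": [c for _, c in rows],
            "cluster": [cl for cl, _ in rows],
        }
    )


@pytest.fixture
def small_config() -> SyntheticConfig:
    return SyntheticConfig(
        seed=0,
        n_patients_per_condition=5,
        cells_per_patient_range=(200, 400),
        braak_fold_per_step=1.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
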