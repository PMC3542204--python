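import numpy as np
import pandas as pd
import pytest

from bnbmla.dataset import DiscreteDataset


def make_dataset(columns: dict[str, np.ndarray], target: str, arities: dict[str, int] | None = None) -> DiscreteDataset:
    """Build a DiscreteDataset from raw code columns (helper for tests)."""
    df = pd.DataFrame({k: np.asarray(v, dtype=np.int64) for k, v in columns.items()})
    if arities is None:
        arities = {c: max(int(df[c].max()) + 1, 2) if len(df) else 2 for c in df}
    roles = {c: ("outcome" if c == target else "snp") for c in df}
    return DiscreteDataset(data=df, arities=arities, target_name=target, variable_roles=roles)


@pytest.fixture(scope="session")
def copy_pair_dataset() -> DiscreteDataset:
    """Two perfectly dependent binary variables (deterministic copy), n=200."""
    rng = np.random.default_rng(12345)
    x = rng.integers(0, 2, 200)
    return make_dataset({"x": x, "y": x.copy()}, target="y")


@pytest.fixture(scope="session")
def empty_two_node_dataset() -> DiscreteDataset:
    """Two binary variables with zero observations (prior-only posterior)."""
    return make_dataset(
        {"a": np.array([], dtype=int), "b": np.array([], dtype=int)},
        target="b",
        arities={"a": 2, "b": 2},
    )


@pytest.fixture(scope="session")
def four_var_dataset() -> DiscreteDataset:
    """A 4-variable dataset with mixed dependence used against the oracle."""
    rng = np.random.default_rng(42)
    n = 300
    a = rng.integers(0, 3, n)
    b = (a + rng.integers(0, 2, n)) % 3
    c = rng.integers(0, 2, n)
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-(-0.5 + 0.8 * (a > 0))))).astype(int)
    return make_dataset({"a": a, "b": b, "c": c, "y": y}, target="y")
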