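import numpy as np
import pandas as pd
import pytest

from medtraj.datasets import MixedDataset, VariableMeta
from medtraj.synthetic import generate_branching_dataset, star_tree_spec


@pytest.fixture
def small_mixed() -> MixedDataset:
    """4x4 mixed table with one missing cell per kind of variable."""
    values = pd.DataFrame(
        {
            "sev": ["0", "1", "2", np.nan],
            "flag": ["no", np.nan, "yes", "no"],
            "grp": ["a", "b", "c", "a"],
            "bp": [120.0, 135.0, np.nan, 150.0],
        }
    )
    mask = values.isna()
    meta = [
        VariableMeta("sev", "ordinal", ("0", "1", "2")),
        VariableMeta("flag", "binary", ("no", "yes")),
        VariableMeta("grp", "categorical", ("a", "b", "c")),
        VariableMeta("bp", "continuous"),
    ]
    return MixedDataset(values=values, missing_mask=mask, meta=meta)


@pytest.fixture
def star3():
    """Seeded 3-armed star dataset with ground truth (low noise)."""
    spec = star_tree_spec(3, points_per_branch=100, noise=0.05, dim=3)
    ds, truth = generate_branching_dataset(spec, seed=11)
    return ds.values.to_numpy(dtype=float), truth


@pytest.fixture
def line_data():
    """Points densely sampled on a straight segment plus small noise."""
    rng = np.random.default_rng(5)
    t = rng.uniform(0, 1, 300)
    X = np.column_stack([t * 4.0, np.zeros_like(t), np.zeros_like(t)])
    return X + rng.normal(0, 0.05, X.shape)
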