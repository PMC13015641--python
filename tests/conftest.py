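import numpy as np
import pandas as pd
import pytest

from regsyn import CohortSchema, FeatureSpec, TabularDataset


@pytest.fixture
def mixed_schema() -> CohortSchema:
    """1 continuous + 1 binary + one 3-category covariate, binary outcome."""
    return CohortSchema(
        (
            FeatureSpec("x1", "continuous"),
            FeatureSpec("b1", "binary"),
            FeatureSpec("ins", "categorical", categories=("public", "private", "uninsured")),
            FeatureSpec("y", "binary", role="outcome"),
        )
    )


@pytest.fixture
def mixed_dataset(mixed_schema) -> TabularDataset:
    rng = np.random.default_rng(42)
    n = 40
    return TabularDataset(
        mixed_schema,
        pd.DataFrame(
            {
                "x1": rng.normal(1.5, 2.0, n),
                "b1": rng.integers(0, 2, n),
                "ins": rng.integers(0, 3, n),
                "y": rng.integers(0, 2, n),
            }
        ),
    )


def make_continuous_dataset(values_by_col: dict, outcome: str | None = None):
    """Small helper: all-continuous table; last column is the outcome."""
    names = list(values_by_col)
    out = outcome or names[-1]
    feats = tuple(
        FeatureSpec(nm, "continuous", role="outcome" if nm == out else "covariate")
        for nm in names
    )
    return TabularDataset(
        CohortSchema(feats), pd.DataFrame({k: np.asarray(v, float) for k, v in values_by_col.items()})
    )
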