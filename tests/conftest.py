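import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_series():
    """One default synthetic congeneric series (seed 1)."""
    from comsiakit import SyntheticSpec, generate_series

    return generate_series(SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def series_blocks(default_series):
    """Field blocks for the default series on the standard 2 Å lattice."""
    from comsiakit import build_grid, compute_all_fields

    grid = build_grid(default_series.molecules)
    return grid, compute_all_fields(default_series.molecules, grid)


@pytest.fixture(scope="session")
def train_blocks(default_series, series_blocks):
    """(blocks restricted to training rows, training activities)."""
    _, blocks = series_blocks
    train = default_series.table.subset("train")
    ids = list(train.ids)
    return {k: b.rows(ids) for k, b in blocks.items()}, train.pec50()


@pytest.fixture(scope="session")
def published_predictions():
    from comsiakit.datasets import load_model_predictions

    return load_model_predictions()


@pytest.fixture(scope="session")
def published_activities():
    from comsiakit.datasets import load_activity_frame

    return load_activity_frame()
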