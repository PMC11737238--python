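"""Shared fixtures: a small landscape, the default simulated cohort, and one
full pipeline run, all session-scoped so expensive simulations happen once."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from foxphase import pipeline
from foxphase.synthetic_telemetry import (
    SimScenario,
    simulate_landscape,
)

MASTER_SEED = 1


@pytest.fixture(scope="session")
def small_landscape():
    """A cheap 6 x 5 km landscape for raster/covariate unit tests."""
    return simulate_landscape((6_000.0, 5_000.0), seed=7, cell_size=10.0)


@pytest.fixture(scope="session")
def pipeline_result():
    """One full default pipeline run (12 individuals, five 300-tree forests)."""
    return pipeline.run(pipeline.PipelineConfig(seed=MASTER_SEED))


@pytest.fixture(scope="session")
def default_population(pipeline_result):
    """The simulated cohort behind the pipeline run, with ground truth."""
    return pipeline_result.population


def random_walk_fixes(
    seed: int,
    n: int = 400,
    start: str = "2022-01-01",
    step_minutes: float = 10.0,
    sd: float = 80.0,
    individual_id: str = "w1",
) -> pd.DataFrame:
    """A plain Gaussian random walk at a fixed cadence (test helper)."""
    rng = np.random.default_rng(seed)
    xy = np.cumsum(rng.normal(0.0, sd, size=(n, 2)), axis=0) + 5_000.0
    t = pd.date_range(start, periods=n, freq=f"{int(step_minutes)}min")
    return pd.DataFrame(
        {"individual_id": individual_id, "t": t, "x": xy[:, 0], "y": xy[:, 1]}
    )
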