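import numpy as np
import pytest

from likertnorm.data import ItemResponseMatrix
from likertnorm.pipeline import PipelineConfig, run_pipeline
from likertnorm.synthetic_mansa import (
    SimulationConfig,
    default_mansa_params,
    generate_grm_responses,
)


@pytest.fixture(scope="session")
def default_params():
    return default_mansa_params()


@pytest.fixture(scope="session")
def small_matrix():
    """400 respondents per group; enough for structural tests, cheap to fit."""
    return generate_grm_responses(SimulationConfig(n_per_group=400, seed=11))


@pytest.fixture(scope="session")
def big_reference_scores():
    """Reference-group summed scores at n=10,000 (calibration checks)."""
    m = generate_grm_responses(
        SimulationConfig(n_per_group=10_000, seed=3, covariates=False)
    )
    mask = np.asarray([g == "population" for g in m.group])
    return m.responses[mask].sum(axis=1)


@pytest.fixture(scope="session")
def pipeline_result():
    """Full pipeline on 2000/group synthetic data, fixed seed.

    Shared by the end-to-end and parameter-recovery tests; the generating
    parameters are the default fixture, so ``default_mansa_params()`` is the
    ground truth for recovery checks.
    """
    matrix = generate_grm_responses(SimulationConfig(n_per_group=2000, seed=3))
    return run_pipeline(PipelineConfig(), matrix)


@pytest.fixture()
def toy_matrix():
    resp = np.array(
        [
            [1, 2, 2],
            [2, 3, 1],
            [3, 3, 2],
            [4, 5, 4],
            [5, 4, 5],
            [6, 6, 5],
        ],
        dtype=float,
    )
    return ItemResponseMatrix(
        responses=resp,
        item_names=["i1", "i2", "i3"],
        group=np.array(["g"] * 6, dtype=object),
        n_categories=7,
    )
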