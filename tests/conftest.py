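"""Shared fixtures for the test suite.

The ``study_frame`` fixture runs a reduced version of the full Monte-Carlo
experiment (all 16 data conditions, three separate-calibration methods,
25 replications) exactly once per session; the recovery and outcome tests
read from it rather than re-running the pipeline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import ralisim as rl

STUDY_REPS = 40
STUDY_SEED = 20210706


@pytest.fixture(scope="session")
def study_frame() -> pd.DataFrame:
    """Per-replication estimates for the full condition grid (reduced reps)."""
    config = rl.StudyConfig(
        methods=("fpc", "mean_mean", "weighted_mean_mean"),
        n_replications=STUDY_REPS,
        master_seed=STUDY_SEED,
    )
    return rl.run_study_frame(config)


@pytest.fixture(scope="session")
def small_design() -> rl.StudyDesign:
    return rl.StudyDesign(sample_size=500)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def fitted_form():
    """One simulated form (t2, N=1500) with its free calibration."""
    design = rl.StudyDesign(sample_size=1500)
    rng = rl.substream_rng(123, "fitted-form")
    bank = rl.build_item_banks(design, rng)
    responses = rl.simulate_responses(
        rl.draw_abilities(design, 2, rng), bank.items_for_form(2), rng, timepoint=2
    )
    fit = rl.fit_mml_em(responses, rl.CalibrationSpec())
    return design, bank, responses, fit
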