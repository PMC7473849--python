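import warnings

import numpy as np
import pytest

from memdecode.pipeline_io import RunConfig, simulate_cohort


@pytest.fixture(scope="session")
def mini_cohort():
    """Small simulated cohort shared by decoding-level tests.

    8 subjects (4 per mapping group), 2 runs of 30 trials each, 12^3 grid
    with the default five-pattern suite and default noise.
    """
    cfg = RunConfig(
        n_subjects=8, n_categories=20, n_runs=2, grid_dims=(12, 12, 12), seed=7
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        designs, grid, specs, schedules, betas, residuals = simulate_cohort(cfg)
    return dict(
        config=cfg,
        designs=designs,
        grid=grid,
        specs={s.name: s for s in specs},
        schedules=schedules,
        betas=betas,
        residuals=residuals,
        subject_ids=[d.subject_id for d in designs],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
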