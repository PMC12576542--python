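import numpy as np
import pandas as pd
import pytest

import tauspread as tsp


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort exercising every downstream stage."""
    cfg = tsp.SimConfig(
        n_regions=30, n_modules=5, n_subjects=40, n_template_subjects=10,
        k_epicentres=5, seed=42,
    )
    return tsp.simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def toy_timeseries():
    rng = np.random.default_rng(5)
    n_frames, n_regions = 120, 8
    values = rng.standard_normal((n_frames, n_regions))
    motion = np.cumsum(rng.normal(0, 0.005, (n_frames, 6)), axis=0)
    nuisance = rng.standard_normal((n_frames, 2))
    return tsp.ParcelTimeseries(
        subject_id="sub-toy", values=values, tr=2.0, motion=motion, nuisance=nuisance,
        regions=tuple(f"R{i}" for i in range(n_regions)),
    )
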