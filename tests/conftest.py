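import numpy as np
import pandas as pd
import pytest

from nmrconfound.io_cohort import PeakTable, meta_from_center_counts, load_table1_counts
from nmrconfound.synthetic import SimConfig, simulate_cohort


def small_sim_config(seed=0, **overrides):
    """A compact two-cluster scenario for fast pipeline tests."""
    peaks = {f"{1 + j / 50:.3f}": 4.0 for j in range(20)}
    cfg = dict(
        n_per_cell={
            ("AA1", "PHT"): 20,
            ("AA1", "PA"): 20,
            ("BB1", "PHT"): 20,
            ("BB1", "PA"): 20,
        },
        centers={"AA1": 1, "BB1": 2},
        baseline_log_mean=peaks,
        baseline_log_sd={k: 0.3 for k in peaks},
        n_qc=20,
        n_hv=15,
        hv_center="AA1",
        lod=0.0,
        seed=seed,
    )
    cfg.update(overrides)
    return SimConfig(**cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def toy_table():
    """5 samples x 4 peaks with one non-detect."""
    vals = pd.DataFrame(
        [
            [1.0, 2.0, 3.0, 4.0],
            [2.0, 4.0, 6.0, 8.0],
            [1.5, np.nan, 4.5, 6.0],
            [1.0, 2.2, 2.9, 4.1],
            [0.9, 1.8, 3.2, 3.9],
        ],
        index=[f"s{i}" for i in range(5)],
        columns=["1.100", "2.200", "3.300", "4.400"],
    )
    return PeakTable(vals)


@pytest.fixture(scope="session")
def table1_meta():
    return meta_from_center_counts(load_table1_counts())


@pytest.fixture(scope="session")
def small_cohort():
    cfg = small_sim_config(seed=11)
    return simulate_cohort(cfg)
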