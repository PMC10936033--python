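import numpy as np
import pytest

from twamap.simulate import SimConfig, simulate_cohort


def make_series(t_minutes, values, op_id="op1"):
    """MapSeries helper with times given in minutes."""
    from twamap.types import MapSeries

    return MapSeries(op_id, np.asarray(t_minutes, dtype=float) * 60.0, values)


def random_piecewise_series(rng, op_id="r"):
    """Random piecewise-linear MAP series spanning ~2 hours, sampled at
    irregular 1–5 minute intervals (the data regime the resolution rule
    admits)."""
    from twamap.types import MapSeries

    gaps = rng.uniform(60.0, 300.0, 200)
    t = np.concatenate([[0.0], np.cumsum(gaps)])
    t = t[t <= 120 * 60.0]
    if t[-1] < 120 * 60.0:
        t = np.append(t, 120 * 60.0)
    v = np.clip(rng.uniform(50.0, 90.0) + np.cumsum(rng.normal(0, 5.0, t.size)), 40.0, 100.0)
    return MapSeries(op_id, t, v)


@pytest.fixture(scope="session")
def sim_cohort_small():
    """Full relational simulation: 60 clean patients + engineered failures."""
    cfg = SimConfig(
        n_patients=60,
        seed=42,
        n_no_cpb=2,
        n_invalid_cpb=1,
        n_low_resolution=2,
        n_no_baseline=1,
        n_reoperation=1,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def sim_tables_dir(sim_cohort_small, tmp_path_factory):
    d = tmp_path_factory.mktemp("simdata")
    sim_cohort_small.write_csv(d)
    return d
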