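import numpy as np
import pandas as pd
import pytest

from isochamber import engine, ingest, synthetic
from isochamber.config import SimConfig


def noise_free_config(**kw):
    base = dict(days=2, drought_start_day=0, drawdown_days=1.0, rewater_day=1,
                n_control=1, n_drought=1, plant_cv=0.0,
                noise_delta13c=0.0, noise_co2=0.0, seed=7)
    base.update(kw)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_config():
    return noise_free_config()


@pytest.fixture(scope="session")
def small_truth(small_config):
    return synthetic.simulate_truth(small_config)


@pytest.fixture(scope="session")
def small_stream(small_config, small_truth):
    return synthetic.synthesize_raw_stream(small_truth, small_config)


@pytest.fixture(scope="session")
def small_cycles(small_stream):
    return ingest.parse_cycles(small_stream)


@pytest.fixture(scope="session")
def small_fluxes(small_config, small_cycles):
    return engine.compute_fluxes(small_cycles, synthetic.chamber_table(small_config))


def align_to_truth(fluxes: pd.DataFrame, truth: pd.DataFrame,
                   cycle_interval_s: float) -> pd.DataFrame:
    """Join pipeline flux records onto truth rows by plant and cycle index."""
    f = fluxes.copy()
    f["cycle_idx"] = (f["time_s"] // cycle_interval_s).astype(int)
    return f.merge(truth, on=["plant_id", "cycle_idx"], suffixes=("_est", "_true"))


def max_rel_err(estimate, true, floor=1e-9):
    a = np.asarray(estimate, dtype=float)
    b = np.asarray(true, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    assert ok.any()
    return float(np.max(np.abs(a[ok] - b[ok]) / np.maximum(np.abs(b[ok]), floor)))
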