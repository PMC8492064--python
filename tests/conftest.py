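import numpy as np
import pandas as pd
import pytest

from nmpsim import (GeneratorConfig, SimConfig, SimResult, build_default_layout,
                    generate_nucleus_table, generate_tracks, run_simulation)
from nmpsim.config import FATES


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_run():
    """One reduced-scale mixed-regime run shared across read-only tests."""
    cfg = SimConfig(population_scale=0.1, total_time=3.0,
                    snapshot_interval=0.5)
    return run_simulation(cfg, seed=7)


@pytest.fixture(scope="session")
def nucleus_table():
    return generate_nucleus_table(GeneratorConfig(seed=3))


@pytest.fixture(scope="session")
def synthetic_tracks():
    return generate_tracks(GeneratorConfig(seed=4))


def make_result(snapshot_frames, times, config=None):
    """Assemble a SimResult from hand-built cell tables.

    Each frame is a list of (cell_id, state, x_unit, y_unit) tuples; ratio
    and parent are filled with placeholders.
    """
    config = config or SimConfig(population_scale=0.1)
    layout = build_default_layout(config)
    snaps = []
    for t, rows in zip(times, snapshot_frames):
        ids, states, xs, ys = zip(*rows)
        snaps.append(pd.DataFrame({
            "time_h": t,
            "cell_id": np.asarray(ids, dtype=np.int64),
            "parent_id": -1,
            "state": pd.Categorical(states, categories=list(FATES)),
            "ratio": 1.0,
            "x_unit": np.asarray(xs, dtype=float),
            "y_unit": np.asarray(ys, dtype=float),
        }))
    return SimResult(config=config, layout=layout, snapshots=snaps,
                     snapshot_times=list(times), switch_events=[], rng_seed=0)
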