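import numpy as np
import pandas as pd
import pytest

from cncorr import EventScript, TrajectoryPair, cn_series_from_pairs, simulate_events


@pytest.fixture
def rng():
    return np.random.default_rng(20160927)


def random_cn_series(rng, n=50, cell_id="cell"):
    """A CN series from random displacement pairs (almost surely all defined)."""
    ccd_vecs = rng.normal(size=(n, 2))
    ncd_vecs = rng.normal(size=(n, 2))
    return cn_series_from_pairs(ccd_vecs, ncd_vecs, cell_id=cell_id)


@pytest.fixture
def straight_traj():
    """Cell moves 1 um/min along x, nucleus follows at 1.5 um/min (detachment-like)."""
    times = np.arange(11.0)
    cell = np.column_stack([times, np.zeros(11)])
    nuc = np.column_stack([1.5 * times, np.zeros(11)])
    return TrajectoryPair("straight", times, cell, nuc)


@pytest.fixture
def detachment_traj():
    traj, _ = simulate_events(EventScript.uniform("detachment", 60, seed=0))
    return traj


@pytest.fixture
def trajectory_csv(tmp_path):
    """A one-cell 61-row trajectory table at 1-min spacing."""
    rs = np.random.default_rng(7)
    t = np.arange(61.0)
    df = pd.DataFrame(
        {
            "frame": np.arange(61),
            "time_min": t,
            "cell_x_um": np.cumsum(rs.normal(size=61)),
            "cell_y_um": np.cumsum(rs.normal(size=61)),
            "nuc_x_um": np.cumsum(rs.normal(size=61)),
            "nuc_y_um": np.cumsum(rs.normal(size=61)),
            "cell_id": "c1",
        }
    )
    path = tmp_path / "traj.csv"
    df.to_csv(path, index=False)
    return path
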