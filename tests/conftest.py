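import numpy as np
import pandas as pd
import pytest

from axokin.event_extraction import DetectionConfig, process_trajectory
from axokin.synthetic_data import SimConfig, sample_cohort, generate_bout


@pytest.fixture(scope="session")
def detection():
    return DetectionConfig()


@pytest.fixture(scope="session")
def noiseless_config():
    return SimConfig().noiseless()


@pytest.fixture(scope="session")
def noiseless_bout(noiseless_config, detection):
    """One noise-free simulated bout with its ground truth and record."""
    rng = np.random.default_rng(11)
    ind = sample_cohort(noiseless_config, rng)[0]
    traj, gt = generate_bout(ind, noiseless_config, rng, 1, detection)
    record = process_trajectory(traj, ind.svl, detection)
    return traj, gt, record


@pytest.fixture(scope="session")
def record_table():
    """Record-tier table of 25 variables over the study-shaped cohort."""
    from axokin.synthetic_data import sample_records

    return sample_records(SimConfig(), seed=42)


def write_pose_csv(path, landmarks_px, scorer="net"):
    """Write a pose CSV in the 3-header-row tracker dialect (pixels)."""
    n = len(next(iter(landmarks_px.values()))["x"])
    cols = {(scorer, "frame", "coords"): np.arange(n)}
    for name, parts in landmarks_px.items():
        for coord in ("x", "y", "likelihood"):
            cols[(scorer, name, coord)] = np.asarray(parts[coord], dtype=float)
    df = pd.DataFrame(cols)
    df.columns = pd.MultiIndex.from_tuples(df.columns)
    df.to_csv(path, index=False)
    return path
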