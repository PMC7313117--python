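import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from cpforage import SimConfig, simulate_study
from cpforage.simulate import MODES

settings.register_profile("repro", deadline=None, derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study shared by the slower integration tests."""
    cfg = SimConfig(n_individuals=8, seed=42)
    bundle, truth = simulate_study(cfg)
    return cfg, bundle, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_fixes(times, lats, lons, individual="A", habitat=None):
    df = pd.DataFrame(
        {
            "individual_id": individual,
            "t": pd.to_datetime(times),
            "lat": lats,
            "lon": lons,
        }
    )
    if habitat is not None:
        df["habitat"] = habitat
    return df


def quadrant_points(n, seed, sep=1.0):
    """Well-separated 4-quadrant (speed, turn) clouds with Markov run structure.

    Returns (points, labels) where labels are the generating modes.  ``sep``
    scales the separation between low and high centres.
    """
    rng = np.random.default_rng(seed)
    centres = {
        "perch": (0.3, 0.2),
        "intensive_search": (2.0 * sep + 0.5, 2.2),
        "relocation": (8.0 * sep + 1.0, 0.2),
        "extensive_search": (8.0 * sep + 1.0, 2.2),
    }
    sds = {
        "perch": (0.15, 0.12),
        "intensive_search": (0.5, 0.25),
        "relocation": (1.0, 0.12),
        "extensive_search": (1.0, 0.25),
    }
    # persistent behaviour runs
    labels = []
    state = rng.integers(4)
    for _ in range(n):
        if rng.random() > 0.85:
            state = rng.integers(4)
        labels.append(MODES[state])
    pts = np.empty((n, 2))
    for i, lab in enumerate(labels):
        c, s = centres[lab], sds[lab]
        pts[i, 0] = max(rng.normal(c[0], s[0]), 0.01)
        pts[i, 1] = float(np.clip(rng.normal(c[1], s[1]), 0.0, np.pi))
    return pts, labels
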