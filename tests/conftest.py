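import numpy as np
import pandas as pd
import pytest

from nerdmap.tracking import TrajectorySet


def brownian_tracks(D, n_tracks, n_frames, frame_spacing=0.010, sigma=0.0,
                    origin=(0.0, 0.0), spread=0.0, seed=0, track_offset=0):
    """Pure-numpy Brownian trajectory table, independent of the simulator.

    Used as the analytic oracle for the MSD estimator chain: displacements
    are exact Gaussian increments with variance 2·D·Δt per axis, plus
    optional i.i.d. localization noise of sd ``sigma`` per coordinate.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for t in range(n_tracks):
        start = np.asarray(origin, dtype=float)
        if spread:
            start = start + rng.uniform(-spread, spread, 2)
        steps = rng.normal(0.0, np.sqrt(2 * D * frame_spacing), (n_frames, 2))
        pos = start + np.cumsum(steps, axis=0)
        if sigma:
            pos = pos + rng.normal(0.0, sigma, pos.shape)
        for f in range(n_frames):
            rows.append((t + track_offset, f, pos[f, 0], pos[f, 1], 500.0))
    df = pd.DataFrame(rows,
                      columns=["track_id", "frame", "x_um", "y_um", "mass"])
    return TrajectorySet(data=df, frame_spacing=frame_spacing)


@pytest.fixture
def make_brownian():
    return brownian_tracks


@pytest.fixture
def uniform_density_sampler():
    """Density sampler spanning the experimentally observed range."""
    return lambda rng, size: rng.uniform(0.0, 2000.0, size)
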