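import numpy as np
import pytest

from oriturn.io import TrackSet, Trajectory
from oriturn.simulate import DiffusionModel, SimulationConfig, TrackLengthLaw

DT = 0.041  # 24.5 Hz stream acquisition


def make_track(track_id, coords, frames=None, dt=DT):
    coords = np.asarray(coords, dtype=float)
    if frames is None:
        frames = np.arange(len(coords))
    return Trajectory(track_id=track_id, frames=np.asarray(frames),
                      x=coords[:, 0], y=coords[:, 1], frame_interval=dt)


@pytest.fixture
def stationary_track():
    return make_track("still", np.zeros((5, 2)))


@pytest.fixture
def brownian_tracks():
    """1,000 free tracks at the mobile-population coefficient 0.51 um^2/s."""
    model = DiffusionModel(components=[(0.51, 1.0)])
    config = SimulationConfig(
        seed=42, frame_interval=DT,
        track_length_law=TrackLengthLaw("geometric", 5.7, 2),
    )
    from oriturn.simulate import simulate_brownian_tracks

    return simulate_brownian_tracks(model, 1000, config)
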