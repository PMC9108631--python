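import numpy as np
import pytest

from dprtrack import MotionModel, Trajectory, simulate_trajectory
from dprtrack.simulate import DEFAULT_OPTICS


@pytest.fixture
def optics():
    return DEFAULT_OPTICS


def make_track(xy, frames=None, dt=1.0, track_id=0):
    xy = np.asarray(xy, dtype=float)
    if frames is None:
        frames = np.arange(len(xy))
    frames = np.asarray(frames)
    return Trajectory(track_id=track_id, frames=frames, t=frames * dt, xy=xy)


def simulate_ensemble(model: MotionModel, n_tracks: int, n_frames: int,
                      dt: float, seed: int):
    """Simulate n_tracks i.i.d. trajectories with per-track child seeds."""
    ss = np.random.SeedSequence(seed)
    out = []
    for i, child in enumerate(ss.spawn(n_tracks)):
        traj, truth = simulate_trajectory(model, n_frames, dt, child,
                                          track_id=i)
        out.append((traj, truth))
    return out


def brute_force_msd(track: Trajectory):
    """All-ordered-pairs time-averaged MSD oracle (independent of the
    implementation's vectorized path)."""
    frames = track.frames
    lags, msds, counts = [], [], []
    dt = float(np.min(np.diff(track.t) / np.diff(frames)))
    for n in range(1, int(frames[-1] - frames[0]) + 1):
        sq = []
        for i in range(len(frames)):
            for j in range(len(frames)):
                if frames[j] - frames[i] == n:
                    d = track.xy[j] - track.xy[i]
                    sq.append(float(d @ d))
        if sq:
            lags.append(n * dt)
            msds.append(sum(sq) / len(sq))
            counts.append(len(sq))
    return np.array(lags), np.array(msds), np.array(counts)
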