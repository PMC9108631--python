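"""Reading and writing movies, trajectory tables and ground truth.

Movies are multi-page TIFF stacks (one page per frame; two-channel data as
channel-interleaved pages, declared at read time).  Trajectories travel as
CSV with columns ``track_id, frame, t_s, x_um, y_um``; gaps are absent rows.
Frame indices are 0-based; positions are in µm.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .simulate import GroundTruth, Trajectory

__all__ = [
    "read_movie",
    "write_movie",
    "read_tracks",
    "write_tracks",
    "write_ground_truth",
    "read_config",
    "write_config",
    "TRACK_COLUMNS",
]

TRACK_COLUMNS = ["track_id", "frame", "t_s", "x_um", "y_um"]


def write_movie(movie: np.ndarray, path) -> None:
    """Write a (T, H, W) or (T, C, H, W) stack as multi-page TIFF.

    Multi-channel stacks are flattened to channel-interleaved pages
    (frame0/ch0, frame0/ch1, frame1/ch0, ...).
    """
    movie = np.asarray(movie)
    if movie.ndim == 4:
        t, c, h, w = movie.shape
        movie = movie.reshape(t * c, h, w)
    elif movie.ndim != 3:
        raise ValueError("movie must be (T, H, W) or (T, C, H, W)")
    tifffile.imwrite(str(path), movie)


def read_movie(path, n_channels: int = 1) -> np.ndarray:
    """Read a multi-page TIFF stack; lossless for integer data.

    With ``n_channels > 1`` the pages are assumed channel-interleaved and
    the result has shape (T, C, H, W); otherwise (T, H, W).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with tifffile.TiffFile(str(path)) as tif:
        pages = [p.asarray() for p in tif.pages]
    shapes = {p.shape for p in pages}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent page shapes in {path}: {shapes}")
    stack = np.stack(pages)
    if n_channels > 1:
        if len(pages) % n_channels:
            raise ValueError("page count not divisible by channel count")
        t = len(pages) // n_channels
        stack = stack.reshape(t, n_channels, *pages[0].shape)
    return stack


def tracks_to_frame(tracks: list[Trajectory]) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        for i in range(tr.n_points):
            rows.append((tr.track_id, int(tr.frames[i]), float(tr.t[i]),
                         float(tr.xy[i, 0]), float(tr.xy[i, 1])))
    return pd.DataFrame(rows, columns=TRACK_COLUMNS)


def write_tracks(tracks: list[Trajectory], path) -> None:
    """Write trajectories as CSV; gap frames are simply absent rows."""
    tracks_to_frame(tracks).to_csv(path, index=False)


def read_tracks(path) -> list[Trajectory]:
    """Read a trajectory CSV back into Trajectory objects."""
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    out = []
    for tid, grp in df.groupby("track_id", sort=True):
        frames = grp["frame"].to_numpy(dtype=int)
        if np.any(np.diff(frames) < 1):
            raise ValueError(f"non-monotone frames in track {tid}")
        out.append(Trajectory(
            track_id=int(tid), frames=frames,
            t=grp["t_s"].to_numpy(dtype=float),
            xy=grp[["x_um", "y_um"]].to_numpy(dtype=float)))
    return out


def write_ground_truth(truths: list[GroundTruth], path) -> None:
    """Ground-truth CSV: one row per particle per frame."""
    rows = []
    for gt in truths:
        m = gt.model
        for i in range(len(gt.frames)):
            rows.append((gt.particle_id, int(gt.frames[i]), float(gt.t[i]),
                         float(gt.xy_true[i, 0]), float(gt.xy_true[i, 1]),
                         gt.channel, gt.coloc_label or "none", m.kind,
                         m.D, m.v[0], m.v[1], m.R))
    pd.DataFrame(rows, columns=[
        "particle_id", "frame", "t_s", "x_um", "y_um", "channel",
        "coloc_label", "model_kind", "D", "vx", "vy", "R",
    ]).to_csv(path, index=False)


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
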