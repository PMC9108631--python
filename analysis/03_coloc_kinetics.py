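#!/usr/bin/env python
"""Two-channel CL/NCL organelle kinetics.

Segments the organelle channel per frame (median + global Otsu), splits
objects into colocalized (CL) and non-colocalized (NCL) against the
aggregate channel, tracks both populations, and compares displacement,
speed and size with Welch's t test.  Writes the per-track table and the
comparison table.
"""

from pathlib import Path

import pandas as pd

from dprtrack import (LinkingConfig, compare_populations, segment_objects,
                      simulate_two_channel, split_colocalized, track_objects)
from dprtrack.simulate import DEFAULT_OPTICS, TwoChannelKinetics

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results" / "analysis"


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    opt = DEFAULT_OPTICS
    n_frames = 40
    movie, truths = simulate_two_channel(
        30, 0.4, TwoChannelKinetics(), opt, n_frames, (256, 256), seed=1)
    frames_objects, frames_labels = [], []
    for f in range(n_frames):
        labels_img, objs = segment_objects(movie[f, 0],
                                           pixel_size=opt.pixel_size)
        lab = ({} if not objs
               else split_colocalized(labels_img, movie[f, 1], 0.3)[0])
        frames_objects.append(objs)
        frames_labels.append(lab)
    tracks = track_objects(frames_objects, frames_labels,
                           LinkingConfig(1.0, 1.0, 5), 1.0)
    tracks = [t for t in tracks if len(t.frames) >= n_frames // 2]
    pd.DataFrame([{
        "object_id": t.object_id, "n_frames": len(t.frames),
        "label": t.majority_label, "displacement_um": t.net_displacement,
        "speed_um_s": t.mean_speed, "size_um2": t.mean_size,
    } for t in tracks]).to_csv(RESULTS / "coloc_tracks.csv", index=False)
    rows = []
    for metric in ("displacement", "speed", "size"):
        c = compare_populations(tracks, metric)
        rows.append(vars(c))
        rel = c.cl_mean / c.ncl_mean
        print(f"{metric:12s}: CL {c.cl_mean:.3f} vs NCL {c.ncl_mean:.3f} "
              f"(ratio {rel:.2f}), Welch t = {c.t_stat:+.2f}, "
              f"p = {c.p_value:.2g}")
    pd.DataFrame(rows).to_csv(RESULTS / "coloc_comparisons.csv", index=False)
    n_cl = sum(t.majority_label == "CL" for t in tracks)
    print(f"{len(tracks)} tracks ({n_cl} CL / {len(tracks) - n_cl} NCL); "
          f"simulated design: CL at half NCL speed and 1.5x NCL area")


if __name__ == "__main__":
    main()
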