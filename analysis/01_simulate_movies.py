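#!/usr/bin/env python
"""Simulate the ground-truthed demo data used by the downstream analyses.

Writes a 60-frame mixed-kinetics single-channel movie and a two-channel
organelle movie (40% colocalized fraction).  TIFF stacks and the per-frame
ground-truth tables go to scratch/ (large, regenerable).
"""

from pathlib import Path

from dprtrack import PipelineConfig
from dprtrack.io import write_ground_truth, write_movie
from dprtrack.pipeline import simulate_mixed_movie
from dprtrack.simulate import TwoChannelKinetics, simulate_two_channel

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results" / "analysis"
SCRATCH = ROOT / "scratch" / "analysis"


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    cfg = PipelineConfig(seed=1)
    movie, truths = simulate_mixed_movie(cfg)
    write_movie(movie, SCRATCH / "mixed_kinetics.tif")
    write_ground_truth(truths, SCRATCH / "mixed_kinetics_truth.csv")
    kinds = [t.model.kind for t in truths]
    print(f"single-channel movie: {movie.shape[0]} frames, "
          f"{movie.shape[1]}x{movie.shape[2]} px, {len(truths)} particles "
          f"({kinds.count('brownian')} brownian, "
          f"{kinds.count('directed')} directed, "
          f"{kinds.count('confined')} confined)")
    movie2, truths2 = simulate_two_channel(
        30, cfg.cl_fraction, TwoChannelKinetics(), cfg.optics, 40,
        (256, 256), seed=cfg.seed)
    write_movie(movie2, SCRATCH / "two_channel.tif")
    write_ground_truth(truths2, SCRATCH / "two_channel_truth.csv")
    n_cl = sum(t.coloc_label == "CL" for t in truths2)
    print(f"two-channel movie: 40 frames, 256x256 px, "
          f"{len(truths2)} organelles of which {n_cl} colocalized (CL)")


if __name__ == "__main__":
    main()
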