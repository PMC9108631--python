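"""Ground-truthed synthetic time-lapse movies of moving fluorescent particles.

Generates 2D trajectories under Brownian, directed (diffusion + constant
drift) or confined (reflecting circular corral) kinetics, and renders them
into single- or two-channel camera frames with a pixel-integrated Gaussian
PSF, Poisson shot noise and Gaussian read noise.  Every rendered particle is
paired with a :class:`GroundTruth` record so downstream detection, linking
and motion analysis can be scored against known answers.

Units: positions in micrometres, time in seconds, intensities in camera
counts.  Pixel (0, 0) has its centre at the coordinate origin; x increases
with column index, y with row index.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special

__all__ = [
    "MotionModel",
    "OpticsModel",
    "GroundTruth",
    "Trajectory",
    "simulate_trajectory",
    "render_movie",
    "simulate_two_channel",
    "DEFAULT_OPTICS",
]


@dataclass(frozen=True)
class MotionModel:
    """Generative kinetics of a single particle.

    Parameters
    ----------
    kind : {'brownian', 'directed', 'confined'}
    D : float
        Translational diffusion coefficient (µm²/s, ≥ 0).
    v : tuple of float
        Drift velocity (µm/s); used only when ``kind == 'directed'``.
    R : float
        Confinement (corral) radius (µm); used only when ``kind == 'confined'``.
    sigma_loc : float
        Static localization error s.d. per coordinate (µm, ≥ 0), added to the
        reported positions but not to the true path.
    """

    kind: str
    D: float = 0.0
    v: tuple[float, float] = (0.0, 0.0)
    R: float = 0.0
    sigma_loc: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("brownian", "directed", "confined"):
            raise ValueError(f"unknown motion kind {self.kind!r}")
        if self.D < 0:
            raise ValueError("D must be >= 0")
        if self.sigma_loc < 0:
            raise ValueError("sigma_loc must be >= 0")
        if self.kind == "confined" and not self.R > 0:
            raise ValueError("confined motion requires R > 0")
        if self.kind == "directed" and math.hypot(*self.v) == 0:
            raise ValueError("directed motion requires |v| > 0")


@dataclass(frozen=True)
class OpticsModel:
    """Acquisition model: geometry, photon budget and camera noise."""

    pixel_size: float = 0.19  # µm/px
    psf_sigma: float = 0.2  # µm
    frame_interval: float = 1.0  # s
    photons_per_particle: float = 1000.0
    background: float = 50.0  # counts/px
    read_noise_sd: float = 2.0  # counts
    bit_depth: int = 16

    def __post_init__(self) -> None:
        for name in ("pixel_size", "psf_sigma", "frame_interval",
                     "photons_per_particle", "background"):
            if getattr(self, name) < 0 or (
                name in ("pixel_size", "psf_sigma", "frame_interval")
                and getattr(self, name) <= 0
            ):
                raise ValueError(f"{name} must be positive")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")
        if self.bit_depth <= 0:
            raise ValueError("bit_depth must be positive")
        if self.psf_sigma < self.pixel_size / 4:
            raise ValueError("psf_sigma must be >= pixel_size/4 (sampling)")


DEFAULT_OPTICS = OpticsModel()


@dataclass
class Trajectory:
    """Time-ordered 2D positions of one tracked particle; frames may gap."""

    track_id: int
    frames: np.ndarray  # (n,) int, strictly increasing
    t: np.ndarray  # (n,) seconds
    xy: np.ndarray  # (n, 2) µm

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.t = np.asarray(self.t, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if np.any(np.diff(self.frames) < 1):
            raise ValueError("frames must be strictly increasing")

    @property
    def n_points(self) -> int:
        return len(self.frames)

    @property
    def duration(self) -> float:
        """Elapsed time between first and last observed frame (s)."""
        return float(self.t[-1] - self.t[0])


@dataclass
class GroundTruth:
    """True path and generative parameters of one rendered particle."""

    particle_id: int
    model: MotionModel
    frames: np.ndarray
    t: np.ndarray
    xy_true: np.ndarray  # (n, 2) µm, noise-free
    channel: int = 0
    coloc_label: str | None = None  # 'CL' | 'NCL' | None
    radius: float = 0.0  # rendered disc radius (µm); 0 => point emitter


def _reflect_into_disc(p0: np.ndarray, p1: np.ndarray, center: np.ndarray,
                       R: float) -> np.ndarray:
    """Specular reflection of segment p0→p1 at the circle |p - center| = R.

    Assumes |p0 - center| <= R.  Repeats until the endpoint is inside; falls
    back to radial clamping if reflection stalls numerically.
    """
    for _ in range(16):
        d = p1 - center
        r1 = float(np.hypot(*d))
        if r1 <= R:
            return p1
        u = p1 - p0
        a = float(u @ u)
        if a == 0:
            break
        b = 2.0 * float((p0 - center) @ u)
        c = float((p0 - center) @ (p0 - center)) - R * R
        disc = b * b - 4 * a * c
        if disc < 0:
            break
        s = (-b + math.sqrt(disc)) / (2 * a)
        s = min(max(s, 0.0), 1.0)
        hit = p0 + s * u
        n = (hit - center) / R  # outward normal at the crossing point
        rest = p1 - hit
        p1 = hit + rest - 2.0 * float(rest @ n) * n
        p0 = hit
    # numerical fallback: clamp radially onto the boundary
    d = p1 - center
    r1 = float(np.hypot(*d))
    if r1 > R:
        p1 = center + d * (R / r1)
    return p1


def simulate_trajectory(
    model: MotionModel,
    n_frames: int,
    dt: float,
    seed,
    start: tuple[float, float] = (0.0, 0.0),
    track_id: int = 0,
) -> tuple[Trajectory, GroundTruth]:
    """Simulate one trajectory under ``model``.

    Brownian steps are i.i.d. Gaussian with per-axis variance ``2 D dt``;
    directed motion adds ``v dt`` drift per step; confined motion reflects
    each Brownian step specularly at a circle of radius ``R`` centred on the
    start point.  Independent Gaussian localization error of s.d.
    ``sigma_loc`` is added per coordinate to the observed (not the true)
    positions.  Identical ``seed`` gives identical output.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    rng = np.random.default_rng(seed)
    start = np.asarray(start, dtype=float)
    steps = rng.normal(0.0, math.sqrt(2.0 * model.D * dt), size=(n_frames - 1, 2))
    if model.kind == "directed":
        steps = steps + np.asarray(model.v, dtype=float) * dt
    xy = np.empty((n_frames, 2))
    xy[0] = start
    if model.kind == "confined":
        for i in range(1, n_frames):
            xy[i] = _reflect_into_disc(xy[i - 1].copy(),
                                       xy[i - 1] + steps[i - 1], start, model.R)
    else:
        xy[1:] = start + np.cumsum(steps, axis=0)
    noise = (rng.normal(0.0, model.sigma_loc, size=xy.shape)
             if model.sigma_loc > 0 else 0.0)
    frames = np.arange(n_frames)
    t = frames * dt
    traj = Trajectory(track_id=track_id, frames=frames, t=t, xy=xy + noise)
    truth = GroundTruth(particle_id=track_id, model=model, frames=frames,
                        t=t, xy_true=xy)
    return traj, truth


def _integrated_gaussian_patch(x_px: float, y_px: float, sigma_px: float,
                               shape: tuple[int, int], halfwidth: int):
    """Pixel-integrated unit-mass 2D Gaussian in a local window.

    Returns (rows, cols, patch) where ``patch[r, c]`` is the flux falling in
    pixel (rows[r], cols[c]); erf differences over pixel edges, so photometry
    is correct even for sigma below one pixel.
    """
    r0 = max(int(round(y_px)) - halfwidth, 0)
    r1 = min(int(round(y_px)) + halfwidth + 1, shape[0])
    c0 = max(int(round(x_px)) - halfwidth, 0)
    c1 = min(int(round(x_px)) + halfwidth + 1, shape[1])
    if r0 >= r1 or c0 >= c1:
        return None
    rows = np.arange(r0, r1)
    cols = np.arange(c0, c1)
    s = math.sqrt(2.0) * sigma_px
    ey = 0.5 * (special.erf((rows + 0.5 - y_px) / s)
                - special.erf((rows - 0.5 - y_px) / s))
    ex = 0.5 * (special.erf((cols + 0.5 - x_px) / s)
                - special.erf((cols - 0.5 - x_px) / s))
    return rows, cols, np.outer(ey, ex)


def _disc_patch(x_px: float, y_px: float, radius_px: float, sigma_px: float,
                shape: tuple[int, int]):
    """Anti-aliased uniform disc blurred by the PSF, unit total mass."""
    from scipy.ndimage import gaussian_filter

    halfwidth = int(math.ceil(radius_px + 4 * sigma_px)) + 1
    r0 = max(int(round(y_px)) - halfwidth, 0)
    r1 = min(int(round(y_px)) + halfwidth + 1, shape[0])
    c0 = max(int(round(x_px)) - halfwidth, 0)
    c1 = min(int(round(x_px)) + halfwidth + 1, shape[1])
    if r0 >= r1 or c0 >= c1:
        return None
    rows = np.arange(r0, r1)
    cols = np.arange(c0, c1)
    dist = np.hypot(rows[:, None] - y_px, cols[None, :] - x_px)
    coverage = np.clip(radius_px - dist + 0.5, 0.0, 1.0)
    blurred = gaussian_filter(coverage, sigma_px, mode="constant")
    total = blurred.sum()
    if total <= 0:
        return None
    return rows, cols, blurred / total


def render_movie(
    truths: list[GroundTruth],
    optics: OpticsModel,
    n_frames: int,
    shape: tuple[int, int],
    seed,
) -> np.ndarray:
    """Render ground-truth particles into a (n_frames, H, W) uint16 stack.

    Each particle contributes a pixel-integrated Gaussian (or PSF-blurred
    disc when ``truth.radius > 0``) of total flux ``photons_per_particle``
    at its true position; per-pixel Poisson noise is applied to signal plus
    background, Gaussian read noise added, and the result clipped to the
    camera bit depth.  Deterministic under a fixed seed.
    """
    h, w = int(shape[0]), int(shape[1])
    if h <= 0 or w <= 0:
        raise ValueError("empty field shape")
    rng = np.random.default_rng(seed)
    p = optics.pixel_size
    sigma_px = optics.psf_sigma / p
    halfwidth = max(int(math.ceil(5 * sigma_px)), 3)
    vmax = 2 ** optics.bit_depth - 1
    movie = np.empty((n_frames, h, w), dtype=np.uint16)
    for f in range(n_frames):
        signal = np.zeros((h, w))
        for truth in truths:
            idx = np.searchsorted(truth.frames, f)
            if idx >= len(truth.frames) or truth.frames[idx] != f:
                continue
            x_px = truth.xy_true[idx, 0] / p
            y_px = truth.xy_true[idx, 1] / p
            if truth.radius > 0:
                patch = _disc_patch(x_px, y_px, truth.radius / p, sigma_px,
                                    (h, w))
            else:
                patch = _integrated_gaussian_patch(x_px, y_px, sigma_px,
                                                   (h, w), halfwidth)
            if patch is None:
                continue
            rows, cols, flux = patch
            signal[np.ix_(rows, cols)] += optics.photons_per_particle * flux
        counts = rng.poisson(signal + optics.background).astype(float)
        if optics.read_noise_sd > 0:
            counts += rng.normal(0.0, optics.read_noise_sd, size=counts.shape)
        movie[f] = np.clip(np.round(counts), 0, vmax).astype(np.uint16)
    return movie


@dataclass(frozen=True)
class TwoChannelKinetics:
    """Per-class motion and size parameters for the organelle simulation.

    Defaults encode the qualitative design under study: colocalized (CL)
    organelles move at half the speed of non-colocalized (NCL) ones (Brownian
    speed scales with sqrt(D), hence D_CL = D_NCL / 4) and have 1.5x the
    area (radius ratio sqrt(1.5)).
    """

    ncl_model: MotionModel = field(
        default_factory=lambda: MotionModel("brownian", D=0.05))
    cl_model: MotionModel = field(
        default_factory=lambda: MotionModel("brownian", D=0.0125))
    ncl_radius: float = 0.3  # µm
    cl_radius: float = 0.3 * math.sqrt(1.5)  # µm, 1.5x the NCL area
    # photon budgets; bright stains so the global-Otsu segmentation pathway
    # sees a clearly bimodal histogram, as in well-exposed organelle movies
    organelle_photons: float = 3000.0
    aggregate_photons: float = 5000.0


def simulate_two_channel(
    n_objects: int,
    cl_fraction: float,
    kinetics: TwoChannelKinetics,
    optics: OpticsModel,
    n_frames: int,
    shape: tuple[int, int],
    seed,
) -> tuple[np.ndarray, list[GroundTruth]]:
    """Two-channel organelle movie with a known colocalized fraction.

    Channel 0 holds every organelle (disc of per-class radius convolved with
    the PSF); a ``floor(cl_fraction * n_objects)`` subset additionally
    carries a co-moving channel-1 point signal (the aggregate).  Returns a
    (n_frames, 2, H, W) stack and one GroundTruth per rendered object, with
    ``coloc_label`` set.
    """
    if not 0.0 <= cl_fraction <= 1.0:
        raise ValueError("cl_fraction must be in [0, 1]")
    if n_objects < 1:
        raise ValueError("n_objects must be >= 1")
    n_cl = int(math.floor(cl_fraction * n_objects))
    h, w = int(shape[0]), int(shape[1])
    p = optics.pixel_size
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    child_seeds = ss.spawn(n_objects + 1)
    place_rng = np.random.default_rng(child_seeds[0])
    # keep objects clear of the border for the whole movie
    margin = 6 * max(kinetics.cl_radius, kinetics.ncl_radius,
                     optics.psf_sigma) + 1.0
    truths: list[GroundTruth] = []
    for i in range(n_objects):
        is_cl = i < n_cl
        model = kinetics.cl_model if is_cl else kinetics.ncl_model
        radius = kinetics.cl_radius if is_cl else kinetics.ncl_radius
        start = (place_rng.uniform(margin, w * p - margin),
                 place_rng.uniform(margin, h * p - margin))
        _, truth = simulate_trajectory(model, n_frames, optics.frame_interval,
                                       child_seeds[i + 1], start=start,
                                       track_id=i)
        truth.channel = 0
        truth.coloc_label = "CL" if is_cl else "NCL"
        truth.radius = radius
        truths.append(truth)
    ch2_truths = []
    for truth in truths:
        if truth.coloc_label != "CL":
            continue
        agg = GroundTruth(particle_id=truth.particle_id, model=truth.model,
                          frames=truth.frames, t=truth.t,
                          xy_true=truth.xy_true, channel=1,
                          coloc_label="CL", radius=0.6 * truth.radius)
        ch2_truths.append(agg)
    render_seeds = ss.spawn(2)
    opt1 = dataclasses.replace(optics,
                               photons_per_particle=kinetics.organelle_photons)
    opt2 = dataclasses.replace(optics,
                               photons_per_particle=kinetics.aggregate_photons)
    ch1 = render_movie(truths, opt1, n_frames, (h, w), render_seeds[0])
    ch2 = render_movie(ch2_truths, opt2, n_frames, (h, w), render_seeds[1])
    movie = np.stack([ch1, ch2], axis=1)
    return movie, truths
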