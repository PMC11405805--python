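"""Ground-truthed simulator for single-molecule membrane-binding movies.

Generates the statistical structure a supported-lipid-bilayer TIRF
experiment produces: molecules arrive at the membrane as a homogeneous
Poisson process with intensity ``kon * concentration * area``, dwell for an
exponential-mixture residence time (a fast-dissociating fraction ``alpha``
with time constant ``tau_fast`` plus a slow fraction with ``tau_slow``),
optionally censored by first-order photobleaching, diffuse as 2D Brownian
motion with one or two mobile species plus an immobile fraction, and are
observed at discrete frames with Gaussian localization error.  Movies can
be rendered as Gaussian spots on a Poisson background.

All randomness flows from one `numpy.random.Generator` (PCG64) seeded from
the configuration, so a fixed seed reproduces every output bit-for-bit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .trajectories import Trajectory, TrajectorySet

__all__ = [
    "SimConfig",
    "BindingModel",
    "DiffusionModel",
    "GroundTruth",
    "MoleculeRecord",
    "simulate_dwell_times",
    "simulate_arrivals",
    "simulate_trajectories",
    "render_movie",
    "simulate_bulk_trace",
]


@dataclass
class SimConfig:
    """Imaging geometry and acquisition settings.

    Lengths in μm, times in seconds.  ``frame_interval`` defaults to the
    52 ms fast-acquisition setting (19 fps); 102 ms (10 fps) is the usual
    slow alternative.
    """

    field_width: float = 20.0
    field_height: float = 20.0
    pixel_size: float = 0.16
    frame_interval: float = 0.052
    n_frames: int = 600
    localization_sigma: float = 0.02
    psf_sigma: float = 1.0  # pixels
    photons_per_spot: float = 500.0
    background_mean: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("field_width", "field_height", "pixel_size", "frame_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.localization_sigma < 0:
            raise ValueError("localization_sigma must be >= 0")

    @property
    def area(self) -> float:
        """Field area in μm²."""
        return self.field_width * self.field_height

    @property
    def duration(self) -> float:
        """Total movie duration in seconds."""
        return self.n_frames * self.frame_interval

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class BindingModel:
    """Membrane association/dissociation parameters.

    ``kon`` is the association rate constant in events per (μM · μm² · s);
    arrivals over duration T and area A are Poisson with mean
    ``kon * concentration * A * T``.  Dwell times are drawn from
    ``alpha_fast * Exp(tau_fast) + (1 - alpha_fast) * Exp(tau_slow)``;
    ``bleach_rate`` (per s) censors them by an independent exponential
    photobleaching clock (0 disables bleaching).
    """

    kon: float = 184.0
    concentration: float = 5e-5  # μM (50 pM)
    alpha_fast: float = 1.0
    tau_fast: float = 1.0
    tau_slow: float = 1.0
    bleach_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha_fast <= 1.0:
            raise ValueError("alpha_fast must lie in [0, 1]")
        if self.tau_fast <= 0 or self.tau_slow <= 0:
            raise ValueError("time constants must be > 0")
        if self.tau_fast > self.tau_slow:
            raise ValueError("tau_fast must be <= tau_slow")
        if self.kon < 0 or self.concentration < 0 or self.bleach_rate < 0:
            raise ValueError("rates and concentration must be >= 0")

    @property
    def mean_dwell(self) -> float:
        """Mean of the (uncensored) dwell-time mixture, in seconds."""
        return self.alpha_fast * self.tau_fast + (1 - self.alpha_fast) * self.tau_slow


@dataclass
class DiffusionModel:
    """Lateral mobility: up to two Brownian species plus an immobile fraction.

    Each step of a mobile molecule over interval τ has independent Gaussian
    x and y increments with variance ``2 D τ``.  ``frac_species1`` is the
    fraction of the *mobile* population diffusing with ``D1`` (D1 <= D2).
    """

    frac_species1: float = 1.0
    D1: float = 0.16
    D2: float = 0.16
    immobile_frac: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_species1 <= 1.0:
            raise ValueError("frac_species1 must lie in [0, 1]")
        if not 0.0 <= self.immobile_frac <= 1.0:
            raise ValueError("immobile_frac must lie in [0, 1]")
        if self.D1 < 0 or self.D2 < 0:
            raise ValueError("diffusion coefficients must be >= 0")
        if self.D1 > self.D2:
            raise ValueError("D1 must be <= D2")


@dataclass
class MoleculeRecord:
    """Ground truth for one simulated molecule."""

    arrival_time: float
    true_dwell: float
    observed_dwell: float  # min(true dwell, bleach time)
    species: int  # 0 immobile, 1 species1 (D1), 2 species2 (D2)
    frames: np.ndarray
    x_true: np.ndarray
    y_true: np.ndarray
    touches_movie_start: bool = False
    touches_movie_end: bool = False


@dataclass
class GroundTruth:
    """Per-molecule truth for a simulated movie."""

    molecules: list[MoleculeRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.molecules)

    def to_json(self, path) -> None:
        records = []
        for m in self.molecules:
            d = asdict(m)
            d["frames"] = np.asarray(m.frames).tolist()
            d["x_true"] = np.asarray(m.x_true).tolist()
            d["y_true"] = np.asarray(m.y_true).tolist()
            records.append(d)
        with open(path, "w") as fh:
            json.dump(records, fh)


def _draw_dwells(n: int, model: BindingModel, rng: np.random.Generator) -> np.ndarray:
    fast = rng.random(n) < model.alpha_fast
    dwells = np.where(
        fast,
        rng.exponential(model.tau_fast, size=n),
        rng.exponential(model.tau_slow, size=n),
    )
    if model.bleach_rate > 0:
        bleach = rng.exponential(1.0 / model.bleach_rate, size=n)
        dwells = np.minimum(dwells, bleach)
    return dwells


def simulate_dwell_times(
    n: int,
    model: BindingModel,
    frame_interval: float,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
):
    """Draw membrane dwell times from the exponential-mixture model.

    Returns ``(continuous, quantized)``: the continuous dwells and their
    frame-discretized versions ``ceil(dwell / frame_interval) * frame_interval``
    (a molecule alive for any part of a frame is counted in it, so observed
    dwells are positive multiples of the frame interval).

    Parameters
    ----------
    n : number of molecules.
    model : dwell-time mixture; ``bleach_rate > 0`` censors each dwell by an
        independent exponential photobleaching time.
    frame_interval : acquisition interval Δt in seconds.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if frame_interval <= 0:
        raise ValueError("frame_interval must be > 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    continuous = _draw_dwells(int(n), model, rng)
    quantized = np.ceil(continuous / frame_interval) * frame_interval
    return continuous, quantized


def simulate_arrivals(
    kon: float,
    concentration: float,
    area: float,
    duration: float,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Event times of a homogeneous Poisson membrane-arrival process.

    Intensity is ``kon * concentration * area`` (events/s); the returned
    sorted times lie in ``[0, duration)``.  ``concentration`` in μM, ``area``
    in μm², ``kon`` per (μM · μm² · s).
    """
    if kon < 0 or concentration < 0:
        raise ValueError("kon and concentration must be >= 0")
    if area <= 0 or duration <= 0:
        raise ValueError("area and duration must be > 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    mean_count = kon * concentration * area * duration
    n = rng.poisson(mean_count)
    return np.sort(rng.uniform(0.0, duration, size=n))


def _reflect(pos: np.ndarray, low: float, high: float) -> np.ndarray:
    """Fold coordinates back into [low, high] by mirror reflection."""
    span = high - low
    pos = np.mod(pos - low, 2 * span)
    pos = np.where(pos > span, 2 * span - pos, pos)
    return pos + low


def simulate_trajectories(
    config: SimConfig,
    binding: BindingModel,
    diffusion: Optional[DiffusionModel] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[TrajectorySet, GroundTruth]:
    """Simulate a movie's worth of membrane-binding trajectories.

    Molecules arrive as a Poisson process over the movie, land at uniform
    random positions, diffuse with their species' coefficient under
    reflecting boundaries, and are detected in every frame whose temporal
    midpoint falls within their observed (bleach-censored) dwell.  Observed
    positions carry independent Gaussian localization error.  Molecules
    present in the first or last movie frame are flagged in the ground
    truth — the standard track filters must remove them.
    """
    if diffusion is None:
        diffusion = DiffusionModel()
    if rng is None:
        rng = config.rng()
    dt = config.frame_interval
    T = config.duration
    W, H = config.field_width, config.field_height
    if W * H <= 0:
        raise ValueError("field area must be > 0")

    arrivals = simulate_arrivals(binding.kon, binding.concentration, W * H, T, rng=rng)
    n = len(arrivals)
    if n:
        fast = rng.random(n) < binding.alpha_fast
        true_dwells = np.where(
            fast,
            rng.exponential(binding.tau_fast, size=n),
            rng.exponential(binding.tau_slow, size=n),
        )
        if binding.bleach_rate > 0:
            bleach = rng.exponential(1.0 / binding.bleach_rate, size=n)
            obs_dwells = np.minimum(true_dwells, bleach)
        else:
            obs_dwells = true_dwells
    else:
        true_dwells = obs_dwells = np.empty(0)

    truth = GroundTruth()
    trajectories: list[Trajectory] = []
    tid = 0
    midpoints = (np.arange(config.n_frames) + 0.5) * dt
    for arrival, true_dwell, dwell in zip(arrivals, true_dwells, obs_dwells):
        # species: immobile, or one of the two mobile Brownian species
        if rng.random() < diffusion.immobile_frac:
            species, D = 0, 0.0
        elif rng.random() < diffusion.frac_species1:
            species, D = 1, diffusion.D1
        else:
            species, D = 2, diffusion.D2
        alive = (midpoints >= arrival) & (midpoints < arrival + dwell)
        frames = np.nonzero(alive)[0]
        if len(frames) == 0:
            truth.molecules.append(
                MoleculeRecord(
                    float(arrival), float(true_dwell), float(dwell), species,
                    frames, np.empty(0), np.empty(0),
                )
            )
            continue
        k = len(frames)
        x = np.empty(k)
        y = np.empty(k)
        x[0] = rng.uniform(0, W)
        y[0] = rng.uniform(0, H)
        if k > 1:
            sigma_step = math.sqrt(2 * D * dt)
            x[1:] = x[0] + np.cumsum(rng.normal(0, sigma_step, k - 1)) if D > 0 else x[0]
            y[1:] = y[0] + np.cumsum(rng.normal(0, sigma_step, k - 1)) if D > 0 else y[0]
            x = _reflect(x, 0.0, W)
            y = _reflect(y, 0.0, H)
        rec = MoleculeRecord(
            arrival_time=float(arrival),
            true_dwell=float(true_dwell),
            observed_dwell=float(dwell),
            species=species,
            frames=frames,
            x_true=x,
            y_true=y,
            touches_movie_start=bool(frames[0] == 0),
            touches_movie_end=bool(frames[-1] == config.n_frames - 1),
        )
        truth.molecules.append(rec)
        x_obs = x + rng.normal(0, config.localization_sigma, k) if config.localization_sigma > 0 else x
        y_obs = y + rng.normal(0, config.localization_sigma, k) if config.localization_sigma > 0 else y
        x_obs = np.clip(x_obs, 0.0, W)
        y_obs = np.clip(y_obs, 0.0, H)
        trajectories.append(Trajectory(tid, frames, x_obs, y_obs, dt))
        tid += 1

    tset = TrajectorySet(
        trajectories,
        frame_interval=dt,
        n_movie_frames=config.n_frames,
        field_width=W,
        field_height=H,
    )
    return tset, truth


def render_movie(
    tset: TrajectorySet,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    noise: bool = True,
) -> np.ndarray:
    """Render trajectories as a 16-bit movie stack (n_frames, H, W) pixels.

    Each detection becomes a 2D Gaussian of ``psf_sigma`` pixels carrying
    ``photons_per_spot`` total photons; the expected image (spots plus
    ``background_mean``) is Poisson-sampled unless ``noise=False``.  Spots
    off the field are clipped, never wrapped.
    """
    if rng is None:
        rng = config.rng()
    h_px = int(round(config.field_height / config.pixel_size))
    w_px = int(round(config.field_width / config.pixel_size))
    stack = np.full((config.n_frames, h_px, w_px), float(config.background_mean))
    sig = config.psf_sigma
    half = max(1, int(math.ceil(4 * sig)))
    amp = config.photons_per_spot / (2 * math.pi * sig**2)
    for traj in tset:
        for f, x, y in zip(traj.frames, traj.x, traj.y):
            cx = x / config.pixel_size
            cy = y / config.pixel_size
            x0, x1 = int(math.floor(cx)) - half, int(math.floor(cx)) + half + 1
            y0, y1 = int(math.floor(cy)) - half, int(math.floor(cy)) + half + 1
            xs = np.arange(max(x0, 0), min(x1, w_px))
            ys = np.arange(max(y0, 0), min(y1, h_px))
            if len(xs) == 0 or len(ys) == 0:
                continue  # spot entirely off-field: clipped
            gx = np.exp(-((xs - cx) ** 2) / (2 * sig**2))
            gy = np.exp(-((ys - cy) ** 2) / (2 * sig**2))
            stack[f, ys[0] : ys[-1] + 1, xs[0] : xs[-1] + 1] += amp * np.outer(gy, gx)
    if noise:
        stack = rng.poisson(stack).astype(np.uint16)
    else:
        stack = np.clip(np.round(stack), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    return stack


def simulate_bulk_trace(
    t_half: float,
    plateau: float,
    noise_sd: float = 0.0,
    n_points: int = 200,
    duration: Optional[float] = None,
    hill: float = 4.0,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
):
    """Phenomenological sigmoid for a bulk membrane-recruitment time series.

    A Hill-type curve ``plateau * t^h / (t^h + t_half^h)`` rising from 0 to
    ``plateau`` and crossing half-maximum exactly at ``t_half``, with optional
    additive Gaussian noise.  Returns a :class:`~smtirf.bulk.MembraneTimeSeries`.
    This is a stand-in for reaction traces, not a mechanistic kinetic model.
    """
    from .bulk import MembraneTimeSeries

    if duration is None:
        duration = 4.0 * t_half if t_half > 0 else 1.0
    if not (0 <= t_half <= duration):
        raise ValueError("t_half must lie within the time range")
    t = np.linspace(0.0, duration, int(n_points))
    if plateau == 0:
        y = np.zeros_like(t)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            y = plateau * t**hill / (t**hill + t_half**hill)
        y[t == 0] = 0.0 if t_half > 0 else plateau
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        y = y + rng.normal(0, noise_sd, len(t))
    return MembraneTimeSeries(time=t, intensity=y)
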