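"""Step-size distributions and 2D Brownian diffusion fits.

For a molecule diffusing in 2D with coefficient D, the frame-to-frame step
length r over lag time τ follows the Rayleigh-type density

    f(r) = r / (2 D τ) * exp(-r² / (4 D τ))

with mean step length sqrt(π D τ).  A two-species population mixes two such
densities with fraction ``alpha`` of species 1 (D1 <= D2).  Steps are pooled
across trajectories at a single lag, binned at fixed width (default 0.01 μm)
and normalized to probability density before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .trajectories import TrajectorySet

__all__ = [
    "StepDensity",
    "DiffusionFit",
    "DiffusionFitError",
    "compute_steps",
    "build_density",
    "fit_step_density",
    "mean_displacement",
    "per_cell_displacement",
    "rayleigh_density",
]


class DiffusionFitError(RuntimeError):
    """Raised when the step-size density fit fails to converge."""


def compute_steps(tset: TrajectorySet, lag: int = 1) -> np.ndarray:
    """Euclidean displacements between detections ``lag`` frames apart.

    Pooled over all trajectories (only tracks with > lag detections
    contribute).  The corresponding lag time is ``lag * frame_interval``.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    parts = [t.steps(lag) for t in tset if len(t) > lag]
    if not parts:
        return np.empty(0)
    return np.concatenate(parts)


def rayleigh_density(r, D, tau):
    """Single-species 2D Brownian step-length density."""
    return r / (2 * D * tau) * np.exp(-(r**2) / (4 * D * tau))


def _density2(r, D1, D2, alpha, tau):
    return alpha * rayleigh_density(r, D1, tau) + (1 - alpha) * rayleigh_density(
        r, D2, tau
    )


@dataclass
class StepDensity:
    """Binned probability density of step lengths at one lag time."""

    steps: np.ndarray
    bin_width: float
    tau: float
    bin_centers: np.ndarray
    density: np.ndarray

    @property
    def n(self) -> int:
        return len(self.steps)

    def integral(self) -> float:
        return float(self.density.sum() * self.bin_width)


def build_density(
    steps: Sequence[float],
    bin_width: float = 0.01,
    tau: float = 0.052,
    min_steps: int = 100,
) -> StepDensity:
    """Histogram step lengths at fixed bin width, normalized to density.

    Bins run from 0 to just past the largest step; zero-count bins are kept
    (they enter the fit with density 0).  The density integrates to 1.
    """
    steps = np.asarray(steps, dtype=float)
    if len(steps) < min_steps:
        raise ValueError(f"need >= {min_steps} steps, got {len(steps)}")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    n_bins = int(np.ceil(steps.max() / bin_width)) + 1 if steps.max() > 0 else 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(steps, bins=edges)
    density = counts / (len(steps) * bin_width)
    centers = (edges[:-1] + edges[1:]) / 2
    return StepDensity(
        steps=steps, bin_width=bin_width, tau=tau, bin_centers=centers, density=density
    )


@dataclass
class DiffusionFit:
    """Fitted diffusion coefficients from a step-size density.

    ``alpha`` is the fraction of species 1 (D1 <= D2); for order 1 only
    ``D1`` is defined.  ``degenerate`` flags an order-2 fit that collapsed
    (alpha pinned near 0/1 or D1 ≈ D2).
    """

    order: int
    D1: float
    D2: Optional[float] = None
    alpha: Optional[float] = None
    D1_se: float = np.nan
    D2_se: Optional[float] = None
    alpha_se: Optional[float] = None
    rss: float = np.nan
    n: int = 0
    degenerate: bool = False


def fit_step_density(
    density: StepDensity, order: int = 1, seed: int = 0
) -> DiffusionFit:
    """Least-squares fit of the one- or two-species Brownian step model.

    Multi-start; constraints D1 <= D2 (enforced by sorting after the fit)
    and alpha in [0, 1].  Raises :class:`DiffusionFitError` on
    non-convergence.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    min_n = 1000 if order == 1 else 10000
    if density.n < min_n:
        raise ValueError(f"order-{order} fit needs >= {min_n} steps, got {density.n}")
    r = density.bin_centers
    y = density.density
    tau = density.tau
    # moment-based initial guess: mean step = sqrt(pi D tau)
    mean_step = float(np.mean(density.steps))
    D0 = max(mean_step**2 / (np.pi * tau), 1e-6)
    rng = np.random.default_rng(seed)

    if order == 1:
        f = lambda rr, D: rayleigh_density(rr, D, tau)
        starts = [(D0,)] + [(D0 * rng.uniform(0.3, 3.0),) for _ in range(3)]
        bounds = ([1e-9], [np.inf])
    else:
        f = lambda rr, D1, D2, alpha: _density2(rr, D1, D2, alpha, tau)
        starts = [(D0 / 3, D0 * 3, 0.5)] + [
            (
                D0 * rng.uniform(0.1, 1.0),
                D0 * rng.uniform(1.0, 10.0),
                rng.uniform(0.2, 0.8),
            )
            for _ in range(3)
        ]
        bounds = ([1e-9, 1e-9, 0.0], [np.inf, np.inf, 1.0])

    best = None
    for p0 in starts:
        try:
            popt, pcov = optimize.curve_fit(f, r, y, p0=p0, bounds=bounds, maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((y - f(r, *popt)) ** 2))
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)
    if best is None:
        raise DiffusionFitError(f"order-{order} step-density fit did not converge")
    popt, pcov, rss = best
    se = np.sqrt(np.diag(pcov))
    if order == 1:
        return DiffusionFit(
            order=1, D1=float(popt[0]), D1_se=float(se[0]), rss=rss, n=density.n
        )
    D1, D2, alpha = popt
    se1, se2, sea = se
    if D1 > D2:
        D1, D2 = D2, D1
        se1, se2 = se2, se1
        alpha = 1.0 - alpha
    # degenerate when a component carries (statistically) no weight or the
    # two coefficients are indistinguishable
    degenerate = (
        alpha < 0.05
        or alpha > 0.95
        or D2 / max(D1, 1e-12) < 1.5
        or (np.isfinite(sea) and (alpha <= 2 * sea or 1 - alpha <= 2 * sea))
    )
    return DiffusionFit(
        order=2,
        D1=float(D1),
        D2=float(D2),
        alpha=float(alpha),
        D1_se=float(se1),
        D2_se=float(se2),
        alpha_se=float(sea),
        rss=rss,
        n=density.n,
        degenerate=degenerate,
    )


def mean_displacement(steps: Sequence[float]) -> tuple[float, float]:
    """Mean and SD of step lengths (μm) over one lag interval."""
    steps = np.asarray(steps, dtype=float)
    if len(steps) == 0:
        raise ValueError("steps must be nonempty")
    return float(steps.mean()), float(steps.std(ddof=1)) if len(steps) > 1 else 0.0


def per_cell_displacement(cell_steps: dict, groups: Optional[dict] = None):
    """Per-cell mean displacement with an optional two-group t-test.

    Parameters
    ----------
    cell_steps : mapping cell_id -> step-length sample (μm).
    groups : mapping cell_id -> group label (two labels for the test).

    Returns (table, group_means, group_sds, t_statistic, p_value); the test
    entries are None unless exactly two groups with >= 2 cells each.
    """
    import pandas as pd

    rows = [
        {
            "cell": cid,
            "group": groups.get(cid) if groups else None,
            "mean_step": float(np.mean(s)),
            "n_steps": len(s),
        }
        for cid, s in cell_steps.items()
        if len(s) > 0
    ]
    table = pd.DataFrame(rows)
    means: dict = {}
    sds: dict = {}
    t_stat = p_val = None
    if groups and len(table):
        for label, sub in table.groupby("group"):
            means[label] = float(sub["mean_step"].mean())
            sds[label] = float(sub["mean_step"].std(ddof=1))
        labels = sorted(means)
        if len(labels) == 2:
            a = table.loc[table["group"] == labels[0], "mean_step"]
            b = table.loc[table["group"] == labels[1], "mean_step"]
            if len(a) >= 2 and len(b) >= 2:
                t_stat, p_val = (float(v) for v in stats.ttest_ind(a, b, equal_var=True))
    return table, means, sds, t_stat, p_val
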