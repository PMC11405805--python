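"""Dwell-time survival analysis with exponential-mixture fitting.

A molecule's dwell time is how long it stays detected on the membrane,
``(detections - 1) * frame_interval``.  Pooled dwell times are summarized
by the empirical survival function S(t) = 1 - CDF(t) evaluated at integer
multiples of the frame interval and displayed as log10 S(t).  The survival
curve is fit with

    S(t) = exp(-t / tau)                                   (one species)
    S(t) = alpha * exp(-t / tau1) + (1 - alpha) * exp(-t / tau2)

where ``alpha`` is by convention the fraction of the *fast*-dissociating
population (tau1 <= tau2).  Model order is chosen by an extra
sum-of-squares F-test with a degeneracy guard.  Fitting is done on the
linear survival scale by default; a log10-scale objective is available
(the two weight the sparse long-dwell tail differently — neither is
claimed to replicate any particular graphing package bit-for-bit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .trajectories import TrajectorySet

__all__ = [
    "DwellSurvival",
    "ExpMixtureFit",
    "FitError",
    "compute_dwell_times",
    "build_survival",
    "fit_survival",
    "select_model",
    "classify_transient",
    "per_cell_summary",
    "PerCellSummary",
]


class FitError(RuntimeError):
    """Raised when a survival fit fails to converge from every start."""


def compute_dwell_times(tset: TrajectorySet) -> np.ndarray:
    """Dwell time of each trajectory in seconds: (detections - 1) x Δt.

    Single-detection tracks have no measurable dwell and should have been
    removed by the track filters; their presence is an error.
    """
    dwells = []
    for traj in tset:
        if len(traj) < 2:
            raise ValueError(
                f"track {traj.id} has a single detection; filter tracks "
                "(min_frames >= 2) before computing dwell times"
            )
        dwells.append((len(traj) - 1) * tset.frame_interval)
    return np.asarray(dwells)


@dataclass
class DwellSurvival:
    """Empirical survival curve of a dwell-time sample.

    ``bin_edges`` are k * frame_interval for k = 0..K; ``survival`` is
    1 - CDF at each edge.  ``log_curve()`` returns the usable (S > 0)
    portion on the log10 scale, which is what gets plotted and what the
    log-objective fit uses.
    """

    dwell_times: np.ndarray
    frame_interval: float
    bin_edges: np.ndarray
    survival: np.ndarray
    n: int

    @property
    def log10_survival(self) -> np.ndarray:
        """log10 S at each bin edge; -inf where S = 0."""
        with np.errstate(divide="ignore"):
            return np.log10(self.survival)

    def usable(self) -> tuple[np.ndarray, np.ndarray]:
        """(t, S) at edges where S > 0."""
        mask = self.survival > 0
        return self.bin_edges[mask], self.survival[mask]

    def log_curve(self) -> tuple[np.ndarray, np.ndarray]:
        """(t, log10 S) at edges where S > 0."""
        t, s = self.usable()
        return t, np.log10(s)

    @property
    def fittable(self) -> bool:
        return np.count_nonzero(self.survival > 0) >= 3


def build_survival(
    dwells: Sequence[float], frame_interval: float, min_dwells: int = 10
) -> DwellSurvival:
    """Build the binned survival curve of a dwell-time sample.

    The empirical CDF is evaluated at every multiple of the frame interval
    up to the longest dwell; survival is 1 - CDF.  Output is invariant to
    the ordering of the input sample.
    """
    dwells = np.sort(np.asarray(dwells, dtype=float))
    if len(dwells) < min_dwells:
        raise ValueError(f"need >= {min_dwells} dwell times, got {len(dwells)}")
    if frame_interval <= 0:
        raise ValueError("frame_interval must be > 0")
    n = len(dwells)
    kmax = int(np.ceil(dwells[-1] / frame_interval - 1e-9))
    edges = np.arange(kmax + 1) * frame_interval
    # CDF(t) = fraction of dwells <= t (half-open tolerance for float grid)
    cdf = np.searchsorted(dwells, edges * (1 + 1e-12), side="right") / n
    surv = 1.0 - cdf
    sample = DwellSurvival(
        dwell_times=dwells,
        frame_interval=frame_interval,
        bin_edges=edges,
        survival=surv,
        n=n,
    )
    if not sample.fittable:
        warnings.warn("survival curve has fewer than 3 usable points; unfittable")
    return sample


def _model_order1(t, tau):
    return np.exp(-t / tau)


def _model_order2(t, tau1, tau2, alpha):
    return alpha * np.exp(-t / tau1) + (1 - alpha) * np.exp(-t / tau2)


@dataclass
class ExpMixtureFit:
    """Result of an exponential(-mixture) survival fit.

    For ``order == 1`` only ``tau1`` is defined.  ``alpha`` is the fraction
    of the fast component (tau1 <= tau2).  Standard errors come from the
    Jacobian at the optimum; ``rss`` is the residual sum of squares on the
    objective scale used for the fit.
    """

    order: int
    tau1: float
    tau2: Optional[float] = None
    alpha: Optional[float] = None
    tau1_se: float = np.nan
    tau2_se: Optional[float] = None
    alpha_se: Optional[float] = None
    rss: float = np.nan
    n: int = 0
    n_points: int = 0
    objective: str = "linear"

    @property
    def mean_dwell(self) -> float:
        """Model-implied mean dwell time in seconds."""
        if self.order == 1:
            return self.tau1
        return self.alpha * self.tau1 + (1 - self.alpha) * self.tau2

    def as_dict(self) -> dict:
        return {
            "order": self.order,
            "tau1": self.tau1,
            "tau2": self.tau2,
            "alpha": self.alpha,
            "tau1_se": self.tau1_se,
            "tau2_se": self.tau2_se,
            "alpha_se": self.alpha_se,
            "rss": self.rss,
            "n": self.n,
        }


def _starts_order1(tau0: float, rng: np.random.Generator) -> list[tuple]:
    return [(tau0,)] + [(tau0 * rng.uniform(0.3, 3.0),) for _ in range(3)]


def _starts_order2(tau0: float, rng: np.random.Generator) -> list[tuple]:
    base = (tau0, 5 * tau0, 0.8)
    jitter = [
        (
            tau0 * rng.uniform(0.3, 1.5),
            5 * tau0 * rng.uniform(0.5, 3.0),
            rng.uniform(0.2, 0.95),
        )
        for _ in range(3)
    ]
    return [base] + jitter


def fit_survival(
    curve: DwellSurvival,
    order: int = 1,
    objective: str = "linear",
    seed: int = 0,
) -> ExpMixtureFit:
    """Least-squares fit of the exponential(-mixture) model to a survival curve.

    Parameters
    ----------
    curve : the binned survival sample.
    order : 1 (single exponential) or 2 (two-component mixture).
    objective : ``"linear"`` fits S(t) directly; ``"log10"`` fits log10 S(t)
        on the S > 0 points with inverse-variance weights (delta method),
        which emphasizes the tail without letting its noisiest edges
        dominate.
    seed : seeds the jittered multi-start initial guesses.

    Raises :class:`FitError` if no start converges.  Parameters are ordered
    so tau1 <= tau2 with alpha the fast fraction.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    t, s = curve.usable()
    if len(t) < 2 * order + 1:
        raise FitError(
            f"survival curve has {len(t)} usable points; need >= {2 * order + 1}"
        )
    sigma = None
    if objective == "log10":
        y = np.log10(s)
        # inverse-variance weights: delta-method sd of log10 S is
        # sqrt((1 - S) / (n S)) / ln 10, so the sparse tail does not
        # dominate the objective
        sigma = np.sqrt(np.maximum(1 - s, 1e-12) / (curve.n * s)) / np.log(10)
        sigma = np.maximum(sigma, sigma[sigma > 0].min())
        if order == 1:
            f = lambda tt, tau: np.log10(_model_order1(tt, tau))
        else:
            f = lambda tt, tau1, tau2, alpha: np.log10(
                np.maximum(_model_order2(tt, tau1, tau2, alpha), 1e-300)
            )
    elif objective == "linear":
        y = s
        f = _model_order1 if order == 1 else _model_order2
    else:
        raise ValueError("objective must be 'linear' or 'log10'")

    rng = np.random.default_rng(seed)
    tau0 = float(np.median(curve.dwell_times)) / np.log(2)
    if order == 1:
        starts = _starts_order1(tau0, rng)
        bounds = ([1e-9], [np.inf])
    else:
        starts = _starts_order2(tau0, rng)
        bounds = ([1e-9, 1e-9, 0.0], [np.inf, np.inf, 1.0])

    best = None
    for p0 in starts:
        try:
            popt, pcov = optimize.curve_fit(
                f, t, y, p0=p0, sigma=sigma, bounds=bounds, maxfev=20000
            )
        except (RuntimeError, ValueError):
            continue
        resid = y - f(t, *popt)
        if sigma is not None:
            resid = resid / sigma
        rss = float(np.sum(resid**2))
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)
    if best is None:
        raise FitError(f"order-{order} survival fit did not converge from any start")
    popt, pcov, rss = best
    se = np.sqrt(np.diag(pcov))

    if order == 1:
        return ExpMixtureFit(
            order=1,
            tau1=float(popt[0]),
            tau1_se=float(se[0]),
            rss=rss,
            n=curve.n,
            n_points=len(t),
            objective=objective,
        )
    tau1, tau2, alpha = popt
    se1, se2, sea = se
    if tau1 > tau2:  # enforce the fast-fraction convention
        tau1, tau2 = tau2, tau1
        se1, se2 = se2, se1
        alpha = 1.0 - alpha
    return ExpMixtureFit(
        order=2,
        tau1=float(tau1),
        tau2=float(tau2),
        alpha=float(alpha),
        tau1_se=float(se1),
        tau2_se=float(se2),
        alpha_se=float(sea),
        rss=rss,
        n=curve.n,
        n_points=len(t),
        objective=objective,
    )


def select_model(
    curve: DwellSurvival,
    p_threshold: float = 0.01,
    min_tau_ratio: float = 2.0,
    min_fraction: float = 0.05,
    objective: str = "linear",
    seed: int = 0,
) -> tuple[int, ExpMixtureFit]:
    """Choose one- versus two-exponential model for a survival curve.

    Fits both orders; the two-component model is accepted only if the
    extra sum-of-squares F-test rejects the single exponential at
    ``p < p_threshold`` *and* the mixture is non-degenerate:
    tau2/tau1 >= ``min_tau_ratio`` and the fast fraction alpha in
    [``min_fraction``, 0.99].  The survival points are serially correlated,
    which makes the nominal F-test anti-conservative; the fraction guard is
    what keeps spurious few-percent components from being accepted on
    genuinely single-exponential samples.  Returns ``(order, fit)`` for
    the selected model.  Never considers more than two components.
    """
    fit1 = fit_survival(curve, order=1, objective=objective, seed=seed)
    try:
        fit2 = fit_survival(curve, order=2, objective=objective, seed=seed)
    except FitError:
        return 1, fit1
    n = fit1.n_points
    df2 = n - 3
    if df2 <= 0 or fit2.rss <= 0:
        return 1, fit1
    F = ((fit1.rss - fit2.rss) / 2.0) / (fit2.rss / df2)
    p = stats.f.sf(F, 2, df2) if F > 0 else 1.0
    degenerate = (
        fit2.tau2 / fit2.tau1 < min_tau_ratio
        or not (min_fraction <= fit2.alpha <= 0.99)
    )
    if p < p_threshold and not degenerate:
        return 2, fit2
    return 1, fit1


def classify_transient(dwells: Sequence[float], threshold: float = 0.104) -> float:
    """Fraction of dwell times strictly below ``threshold`` seconds.

    The default, 104 ms, is two frames at the 52 ms acquisition interval:
    molecules seen for at most two frames count as transient visitors.
    """
    dwells = np.asarray(dwells, dtype=float)
    if len(dwells) == 0:
        raise ValueError("dwells must be nonempty")
    return float(np.mean(dwells < threshold))


@dataclass
class PerCellSummary:
    """Cell-resolved dwell fits and a two-group comparison.

    One survival fit per cell; the comparison is a standard pooled-variance
    unpaired two-tailed t-test on the cell-level tau1 values.
    """

    table: "pd.DataFrame"
    group_means: dict
    group_sds: dict
    t_statistic: Optional[float] = None
    p_value: Optional[float] = None
    excluded: list = field(default_factory=list)


def per_cell_summary(
    cell_dwells: dict,
    groups: Optional[dict] = None,
    frame_interval: float = 0.052,
    order: int = 1,
    objective: str = "linear",
    seed: int = 0,
) -> PerCellSummary:
    """Fit each cell's dwell distribution and compare two groups.

    Parameters
    ----------
    cell_dwells : mapping cell_id -> dwell-time sample (s).
    groups : mapping cell_id -> group label.  With exactly two labels
        (each with >= 2 fittable cells) an unpaired two-tailed t-test on
        cell-level tau1 is reported.
    order : exponential model order fitted per cell.

    Unfittable cells are excluded and listed in ``excluded``.
    """
    import pandas as pd

    rows = []
    excluded = []
    for cell_id, dwells in cell_dwells.items():
        label = groups.get(cell_id) if groups else None
        try:
            curve = build_survival(dwells, frame_interval)
            fit = fit_survival(curve, order=order, objective=objective, seed=seed)
        except (ValueError, FitError) as err:
            warnings.warn(f"cell {cell_id} excluded: {err}")
            excluded.append(cell_id)
            continue
        rows.append(
            {
                "cell": cell_id,
                "group": label,
                "order": fit.order,
                "tau1": fit.tau1,
                "tau2": fit.tau2,
                "alpha": fit.alpha,
                "n": fit.n,
            }
        )
    table = pd.DataFrame(rows)
    group_means: dict = {}
    group_sds: dict = {}
    t_stat = p_val = None
    if groups and len(table):
        for label, sub in table.groupby("group"):
            group_means[label] = float(sub["tau1"].mean())
            group_sds[label] = float(sub["tau1"].std(ddof=1))
        labels = sorted(group_means)
        if len(labels) == 2:
            a = table.loc[table["group"] == labels[0], "tau1"]
            b = table.loc[table["group"] == labels[1], "tau1"]
            if len(a) >= 2 and len(b) >= 2:
                t_stat, p_val = stats.ttest_ind(a, b, equal_var=True)
                t_stat, p_val = float(t_stat), float(p_val)
    return PerCellSummary(
        table=table,
        group_means=group_means,
        group_sds=group_sds,
        t_statistic=t_stat,
        p_value=p_val,
        excluded=excluded,
    )
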