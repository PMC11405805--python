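"""Independent oracles used to cross-check the package's estimators.

These deliberately avoid the code paths they validate: the mixture fit is
checked against a direct maximum-likelihood fit of the *continuous* dwell
sample, and the trajectory filter against a plain rule-by-rule loop.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import optimize


def mle_exp_mixture(dwells, order=2, n_starts=5, seed=0):
    """Maximum-likelihood fit of a 1- or 2-component exponential mixture.

    Works on the continuous dwell sample.  Returns (params, se) where
    params is (tau,) for order 1 and (tau1, tau2, alpha) with tau1 <= tau2
    and alpha the fast fraction for order 2; se from the inverse observed
    information (central-difference Hessian).
    """
    t = np.asarray(dwells, dtype=float)
    rng = np.random.default_rng(seed)

    if order == 1:
        tau = t.mean()  # closed-form MLE
        se = tau / math.sqrt(len(t))
        return (tau,), (se,)

    def nll(theta):
        tau1, tau2, alpha = theta
        if tau1 <= 0 or tau2 <= 0 or not (0 < alpha < 1):
            return 1e12
        pdf = alpha / tau1 * np.exp(-t / tau1) + (1 - alpha) / tau2 * np.exp(-t / tau2)
        return -np.sum(np.log(np.maximum(pdf, 1e-300)))

    m = t.mean()
    starts = [(m / 2, 3 * m, 0.7)] + [
        (m * rng.uniform(0.2, 1.0), m * rng.uniform(1.5, 6.0), rng.uniform(0.3, 0.9))
        for _ in range(n_starts - 1)
    ]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            nll,
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 5000},
        )
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    # observed information by central differences
    h = np.maximum(np.abs(theta) * 1e-4, 1e-6)
    H = np.empty((3, 3))
    for i in range(3):
        for j in range(3):
            ei = np.eye(3)[i] * h[i]
            ej = np.eye(3)[j] * h[j]
            H[i, j] = (
                nll(theta + ei + ej)
                - nll(theta + ei - ej)
                - nll(theta - ei + ej)
                + nll(theta - ei - ej)
            ) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.maximum(np.diag(cov), 0))
    except np.linalg.LinAlgError:
        se = np.full(3, np.nan)
    tau1, tau2, alpha = theta
    se1, se2, sea = se
    if tau1 > tau2:
        tau1, tau2 = tau2, tau1
        se1, se2 = se2, se1
        alpha = 1 - alpha
    return (tau1, tau2, alpha), (se1, se2, sea)


def filter_oracle(tset, rules):
    """Brute-force survivor IDs: re-check every rule with plain loops."""
    survivors = []
    for traj in tset.trajectories:
        frames = list(traj.frames)
        xs = list(traj.x)
        ys = list(traj.y)
        bad = False
        if rules.drop_first_frame_starts and frames[0] == 0:
            bad = True
        if (
            rules.drop_last_frame_ends
            and tset.n_movie_frames is not None
            and frames[-1] == tset.n_movie_frames - 1
        ):
            bad = True
        if len(frames) < rules.min_frames:
            bad = True
        max_disp = max(
            math.hypot(x - xs[0], y - ys[0]) for x, y in zip(xs, ys)
        )
        if max_disp < rules.min_total_displacement:
            bad = True
        if (
            rules.edge_margin > 0
            and tset.field_width is not None
            and tset.field_height is not None
        ):
            for x, y in zip(xs, ys):
                if (
                    x < rules.edge_margin
                    or y < rules.edge_margin
                    or x > tset.field_width - rules.edge_margin
                    or y > tset.field_height - rules.edge_margin
                ):
                    bad = True
                    break
        if (
            rules.max_duration is not None
            and (len(frames) - 1) * tset.frame_interval > rules.max_duration
        ):
            bad = True
        if not bad:
            survivors.append(traj.id)
    return survivors
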