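"""Membrane association kinetics: binding frequencies and k_ON.

The binding frequency at one solution concentration is the slope of the
cumulative binding-event count versus time (ordinary least squares) divided
by the observed membrane area, in events · μm⁻² · s⁻¹.  The association
rate constant k_ON is the zero-intercept regression slope of frequency
against concentration: frequency must vanish at zero concentration, so the
intercept is fixed at the origin (a free-intercept fit is available as a
diagnostic).  The canonical unit is events per (μM · μm² · s); the per-nM
value is exactly 1000-fold smaller.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = ["BindingEventLog", "KOnEstimate", "binding_frequency", "estimate_kon"]


@dataclass
class BindingEventLog:
    """Binding-event times observed on one membrane at one concentration.

    ``times`` in seconds within [0, duration]; ``area`` in μm²;
    ``concentration`` in μM.
    """

    times: np.ndarray
    area: float
    duration: float
    concentration: float

    def __post_init__(self) -> None:
        self.times = np.sort(np.asarray(self.times, dtype=float))
        if self.area <= 0:
            raise ValueError("area must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if len(self.times) and (
            self.times[0] < 0 or self.times[-1] > self.duration
        ):
            raise ValueError("event times must lie within [0, duration]")

    @property
    def n_events(self) -> int:
        return len(self.times)


def binding_frequency(log: BindingEventLog) -> float:
    """Binding frequency of one event log, events · μm⁻² · s⁻¹.

    OLS slope of cumulative event count versus event time, divided by the
    observation area.  Doubling the area at fixed event stream halves the
    result exactly.  Fewer than 10 events triggers a warning (the estimate
    is still returned; zero events give 0).
    """
    n = log.n_events
    if n < 10:
        warnings.warn(
            f"only {n} binding events; frequency estimate is unreliable",
            stacklevel=2,
        )
    if n == 0:
        return 0.0
    if n == 1:
        # a single point has no regression slope; fall back to count/duration
        return 1.0 / (log.area * log.duration)
    cumulative = np.arange(1, n + 1, dtype=float)
    slope, _, _, _, _ = stats.linregress(log.times, cumulative)
    return float(slope) / log.area


@dataclass
class KOnEstimate:
    """Association rate constant from a concentration series.

    ``kon`` in events per (μM · μm² · s); ``kon_per_nM`` is the same value
    per nM (exactly kon / 1000).  ``frequencies`` maps concentration (μM)
    to measured frequency.  ``single_concentration`` flags the degenerate
    one-point estimate f/C.
    """

    kon: float
    se: float
    frequencies: dict = field(default_factory=dict)
    intercept_diagnostic: Optional[tuple] = None
    single_concentration: bool = False

    @property
    def kon_per_nM(self) -> float:
        return self.kon / 1000.0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "kon_per_uM_um2_s": self.kon,
                    "kon_per_nM_um2_s": self.kon_per_nM,
                    "se": self.se,
                    "frequencies_per_um2_s": {
                        str(c): f for c, f in self.frequencies.items()
                    },
                    "single_concentration": self.single_concentration,
                },
                fh,
                indent=2,
            )


def estimate_kon(logs: Sequence[BindingEventLog]) -> KOnEstimate:
    """Estimate k_ON from binding-event logs across concentrations.

    Regresses per-log binding frequency on concentration with the intercept
    fixed at zero; the slope is k_ON with its regression standard error.
    A free-intercept OLS (slope, intercept) is attached as a diagnostic.
    With a single distinct concentration the ratio frequency/concentration
    is returned and flagged.
    """
    if not logs:
        raise ValueError("need at least one event log")
    conc = np.array([lg.concentration for lg in logs], dtype=float)
    freq = np.array([binding_frequency(lg) for lg in logs])
    frequencies = {float(c): float(f) for c, f in zip(conc, freq)}
    if np.any(conc <= 0):
        raise ValueError("concentrations must be > 0")

    if len(np.unique(conc)) < 2:
        warnings.warn(
            "single concentration: k_ON taken as frequency/concentration",
            stacklevel=2,
        )
        kon = float(np.mean(freq / conc))
        return KOnEstimate(
            kon=kon, se=np.nan, frequencies=frequencies, single_concentration=True
        )

    # zero-intercept least squares: slope = sum(fC) / sum(C^2)
    kon = float(np.sum(freq * conc) / np.sum(conc**2))
    resid = freq - kon * conc
    dof = len(conc) - 1
    se = float(np.sqrt(np.sum(resid**2) / dof / np.sum(conc**2)))

    diag = None
    if len(conc) >= 3:
        res = stats.linregress(conc, freq)
        diag = (float(res.slope), float(res.intercept))
    return KOnEstimate(
        kon=kon, se=se, frequencies=frequencies, intercept_diagnostic=diag
    )
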