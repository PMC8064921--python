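"""Per-plot logistic canopy-coverage dynamics and light interception.

Canopy coverage (% of plot area, from aerial RGB imagery) over days after
planting (DAP) follows a three-parameter logistic,

    y(t) = k*y0 / (y0 + (k - y0) * exp(-mu_max * t)),

with y0 the initial coverage, k the maximum coverage (carrying capacity,
<= 100%), and mu_max the maximum relative growth rate (1/day). From each
plot's fit the module derives:

* AGR40 — mean of the analytic growth rate dy/dt over DAP 1..40 (%/day),
  an early-vigour summary;
* daily intercepted photosynthetically active radiation (PAR), taking
  coverage/100 as the instantaneous interception fraction;
* Ei — light-interception efficiency, the ratio of seasonal intercepted
  PAR to seasonal incident PAR.

Incident PAR is a fixed fraction of global solar radiation
(``par_fraction``, default 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    CoverageError,
    DegenerateDataError,
    InsufficientDataError,
    InvalidArgumentError,
)

PAR_FRACTION_DEFAULT = 0.5


@dataclass
class LogisticFit:
    """Estimated logistic canopy-curve parameters for one plot."""

    y0: float
    k: float
    mu_max: float
    rss: float = 0.0
    converged: bool = True

    def __post_init__(self):
        if not (0 < self.y0 <= self.k <= 100.0 + 1e-9):
            raise InvalidArgumentError(
                f"require 0 < y0 <= k <= 100, got y0={self.y0}, k={self.k}"
            )
        if self.mu_max < 0:
            raise InvalidArgumentError(f"mu_max must be >= 0, got {self.mu_max}")


@dataclass
class ParSeries:
    """Daily incident and intercepted PAR over an interception window."""

    dap: np.ndarray
    incident: np.ndarray
    intercepted: np.ndarray

    @property
    def cum_intercepted(self) -> np.ndarray:
        return np.cumsum(self.intercepted)

    @property
    def total_incident(self) -> float:
        return float(np.sum(self.incident))

    @property
    def total_intercepted(self) -> float:
        return float(np.sum(self.intercepted))


def logistic_value(fit: LogisticFit, t):
    """Canopy coverage (%) at DAP ``t`` (scalar or array)."""
    t = np.asarray(t, dtype=float)
    y0, k, mu = fit.y0, fit.k, fit.mu_max
    out = k * y0 / (y0 + (k - y0) * np.exp(-mu * t))
    return float(out) if out.ndim == 0 else out


def growth_rate(fit: LogisticFit, t):
    """Analytic first derivative dy/dt of the logistic curve (%/day)."""
    t = np.asarray(t, dtype=float)
    y0, k, mu = fit.y0, fit.k, fit.mu_max
    e = np.exp(-mu * t)
    denom = (y0 + (k - y0) * e) ** 2
    out = k * y0 * (k - y0) * mu * e / denom
    return float(out) if out.ndim == 0 else out


def agr40(fit: LogisticFit, n_days: int = 40, integral: bool = False) -> float:
    """Mean daily canopy growth rate over the first ``n_days`` after planting.

    The default is the mean of the analytic derivative on the integer grid
    t = 1..n_days; ``integral=True`` uses the exact integral mean
    (y(n_days) - y(0)) / n_days instead.
    """
    if integral:
        return (logistic_value(fit, n_days) - logistic_value(fit, 0)) / n_days
    grid = np.arange(1, n_days + 1, dtype=float)
    return float(np.mean(growth_rate(fit, grid)))


def fit_logistic(cc_series, max_nfev: int = 2000) -> LogisticFit:
    """Least-squares logistic fit to (DAP, coverage %) pairs.

    Multi-start nonlinear least squares: y0 starts at the minimum observed
    coverage (clamped to >= 0.1), k at the maximum observed (clamped to
    <= 100), and mu_max at each of {0.05, 0.1, 0.2}. Bounds are
    0 < y0 <= k <= 100 and 0 <= mu_max <= 1. A fit that fails to converge
    from every start is returned flagged, not raised.
    """
    arr = np.asarray(cc_series, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise InvalidArgumentError("cc_series must be (DAP, coverage) pairs")
    if arr.shape[0] < 4:
        raise InsufficientDataError(
            f"logistic fit needs >= 4 points, got {arr.shape[0]}"
        )
    t, y = arr[:, 0], arr[:, 1]
    if np.any(np.diff(t) <= 0):
        raise InvalidArgumentError("DAP values must be strictly increasing")

    y0_init = float(np.clip(y.min(), 0.1, 100.0))
    k_init = float(np.clip(y.max(), y0_init, 100.0))

    def residuals(params):
        y0, k, mu = params
        return k * y0 / (y0 + (k - y0) * np.exp(-mu * t)) - y

    lower = np.array([1e-6, 1e-6, 0.0])
    upper = np.array([100.0, 100.0, 1.0])
    best = None
    for mu_init in (0.05, 0.1, 0.2):
        x0 = np.clip([y0_init, k_init, mu_init], lower, upper)
        try:
            sol = least_squares(
                residuals, x0, bounds=(lower, upper), max_nfev=max_nfev
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return LogisticFit(y0_init, k_init, 0.0, rss=float(np.sum(
            (y - y.mean()) ** 2)), converged=False)
    y0, k, mu = best.x
    y0 = min(max(y0, 1e-6), 100.0)
    k = min(max(k, y0), 100.0)
    rss = float(np.sum(residuals([y0, k, mu]) ** 2))
    return LogisticFit(float(y0), float(k), float(mu), rss=rss,
                       converged=bool(best.success))


def intercepted_par(
    fit: LogisticFit,
    weather,
    window: tuple[int, int],
    par_fraction: float = PAR_FRACTION_DEFAULT,
) -> ParSeries:
    """Daily incident and intercepted PAR over ``window`` = (start, end) DAP.

    ``weather`` maps DAP to daily global solar radiation (MJ/m2): either a
    mapping/Series indexed by DAP or a 2-column array of (DAP, solar).
    Incident PAR is ``par_fraction`` times solar radiation; the intercepted
    share on day t is the logistic coverage fraction y(t)/100.
    """
    start, end = int(window[0]), int(window[1])
    if end < start:
        raise InvalidArgumentError("window end must be >= start")
    if hasattr(weather, "items"):
        table = {int(k): float(v) for k, v in weather.items()}
    else:
        arr = np.asarray(weather, dtype=float)
        table = {int(d): float(s) for d, s in arr}
    days = np.arange(start, end + 1)
    missing = [d for d in days if d not in table]
    if missing:
        raise CoverageError(
            f"weather does not cover DAP {missing[0]}..{missing[-1]} "
            f"of the requested window {start}..{end}"
        )
    incident = np.array([table[d] for d in days]) * float(par_fraction)
    fraction = logistic_value(fit, days.astype(float)) / 100.0
    return ParSeries(dap=days, incident=incident, intercepted=incident * fraction)


def light_interception_efficiency(series: ParSeries) -> float:
    """Ei: total intercepted over total incident PAR, as a fraction in [0, 1]."""
    if series.total_incident <= 0:
        raise DegenerateDataError("total incident PAR must be positive")
    return series.total_intercepted / series.total_incident
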