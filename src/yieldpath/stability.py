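"""Finlay-Wilkinson joint regression and cross-environment rank stability.

The joint regression models line i in environment j as

    y_ij = mu + g_i + (1 + b_i) h_j + e_ij

with environment index h_j and per-line sensitivity slope 1 + b_i: slope 1
is average responsiveness (type II stability when the slope sits near 1),
slopes > 1.5 mark lines that outperform only in favorable environments
(type III) and slopes < 0.5 lines that do relatively better in poor
environments (type IV). The fit is alternating least squares with the
identifiability constraints sum g = sum b = sum h = 0 applied every
iteration; with an identity relationship between lines this coincides with
the mode of the Bayesian formulation commonly used for this model.

Rank-based stability uses Kendall's tau in the no-tie-correction (tau-a)
form: (concordant - discordant) / (n(n-1)/2) over all unordered pairs,
ties counting toward neither.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, InsufficientDataError, InvalidArgumentError

SLOPE_HIGH = 1.5   # type III threshold
SLOPE_LOW = 0.5    # type IV threshold
TYPE_II_BAND = 0.25


@dataclass
class FWFit:
    mu: float
    g: pd.Series          # per-line main effect, sum 0
    b: pd.Series          # per-line slope deviation, sum 0
    h: pd.Series          # per-environment index, sum 0
    residuals: pd.DataFrame
    converged: bool
    iterations: int

    @property
    def slopes(self) -> pd.Series:
        return (1.0 + self.b).rename("slope")


@dataclass
class StabilitySummary:
    slopes: pd.Series
    types: pd.Series
    iqr: float
    minimum: float
    maximum: float


def fw_regression(
    y: pd.DataFrame, tol: float = 1e-10, max_iter: int = 500
) -> FWFit:
    """Alternating-least-squares Finlay-Wilkinson fit.

    ``y`` is a line x environment table; lines with any missing environment
    are dropped (the joint regression needs each line observed everywhere).
    Raises on fewer than 2 environments or on environments with no variance
    to regress on.
    """
    y = pd.DataFrame(y).dropna(axis=0, how="any")
    n, m = y.shape
    if m < 2:
        raise InsufficientDataError(f"need >= 2 environments, got {m}")
    if n < 2:
        raise InsufficientDataError(f"need >= 2 complete lines, got {n}")
    vals = y.to_numpy(dtype=float)

    mu = vals.mean()
    h = vals.mean(axis=0) - mu
    if np.allclose(h, 0.0, atol=1e-12) or np.ptp(h) == 0:
        raise DegenerateDataError(
            "environment means carry no variance; slopes are not estimable"
        )
    g = vals.mean(axis=1) - mu
    slopes = np.ones(n)

    prev_rss = np.inf
    converged = False
    for iteration in range(1, max_iter + 1):
        # environments given slopes: weighted regression of deviations
        dev = vals - mu - g[:, None]
        h = (slopes @ dev) / (slopes @ slopes)
        h = h - h.mean()
        if np.allclose(h, 0.0):
            raise DegenerateDataError("environment index collapsed to zero")
        # lines given h: per-line OLS of y_ij on h_j
        hh = float(h @ h)
        slopes = (vals - vals.mean(axis=1, keepdims=True)) @ h / hh
        intercepts = vals.mean(axis=1)
        # identifiability: mean slope 1 (scale absorbed into h), sums zero
        s_mean = slopes.mean()
        if abs(s_mean) > 1e-12:
            h = h * s_mean
            slopes = slopes / s_mean
        mu = intercepts.mean()
        g = intercepts - mu
        resid = vals - (mu + g[:, None] + slopes[:, None] * h[None, :])
        rss = float((resid ** 2).sum())
        if prev_rss - rss < tol * max(prev_rss, 1.0):
            converged = True
            break
        prev_rss = rss

    b = slopes - 1.0
    b -= b.mean()  # exact constraint against accumulated rounding
    resid_sd = float(np.sqrt(rss / max(n * m - 2 * n - m, 1)))
    if np.ptp(h) < 2.0 * resid_sd:
        warnings.warn(
            "environment index range is small relative to the residual "
            "scale; joint-regression slopes are poorly determined",
            stacklevel=2,
        )
    return FWFit(
        mu=float(mu),
        g=pd.Series(g - g.mean(), index=y.index, name="g"),
        b=pd.Series(b, index=y.index, name="b"),
        h=pd.Series(h - h.mean(), index=y.columns, name="h"),
        residuals=pd.DataFrame(resid, index=y.index, columns=y.columns),
        converged=converged, iterations=iteration,
    )


def classify_stability(fit: FWFit, type_ii_band: float = TYPE_II_BAND) -> StabilitySummary:
    """Slope-based stability typing with summary dispersion statistics.

    slope > 1.5 -> III; slope < 0.5 -> IV; |slope - 1| <= ``type_ii_band``
    -> II; anything else in [0.5, 1.5] is left unclassified. IQR uses
    linear quantile interpolation.
    """
    slopes = fit.slopes

    def label(s: float) -> str:
        if s > SLOPE_HIGH:
            return "III"
        if s < SLOPE_LOW:
            return "IV"
        if abs(s - 1.0) <= type_ii_band:
            return "II"
        return "unclassified"

    types = slopes.map(label).rename("stability_type")
    q1, q3 = np.percentile(slopes.to_numpy(), [25, 75])
    return StabilitySummary(
        slopes=slopes, types=types, iqr=float(q3 - q1),
        minimum=float(slopes.min()), maximum=float(slopes.max()),
    )


def kendall_tau(x, y) -> float:
    """Kendall's tau-a: (concordant - discordant) / (n(n-1)/2).

    Tied pairs in either argument count toward neither term (no tie
    correction in the denominator).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidArgumentError("x and y must be equal-length 1-d arrays")
    n = x.size
    if n < 2:
        raise InsufficientDataError("need >= 2 observations")
    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    prod = sx * sy
    concordant_minus_discordant = prod[np.triu_indices(n, k=1)].sum()
    return float(concordant_minus_discordant / (n * (n - 1) / 2.0))


def cross_env_stability(
    values_by_env: dict[str, pd.Series] | pd.DataFrame,
) -> pd.DataFrame:
    """Environment x environment Kendall tau over shared lines.

    ``values_by_env`` maps environment -> per-line values (or a line x env
    frame). Pairs with fewer than 2 shared lines get NaN with a warning.
    """
    if isinstance(values_by_env, pd.DataFrame):
        values_by_env = {c: values_by_env[c] for c in values_by_env.columns}
    envs = list(values_by_env)
    out = pd.DataFrame(np.eye(len(envs)), index=envs, columns=envs)
    for i, ea in enumerate(envs):
        for j in range(i + 1, len(envs)):
            eb = envs[j]
            a = values_by_env[ea].dropna()
            b = values_by_env[eb].dropna()
            shared = a.index.intersection(b.index)
            if len(shared) < 2:
                warnings.warn(
                    f"environments {ea!r} and {eb!r} share "
                    f"{len(shared)} line(s); tau undefined",
                    stacklevel=2,
                )
                tau = np.nan
            else:
                tau = kendall_tau(a.loc[shared].to_numpy(),
                                  b.loc[shared].to_numpy())
            out.loc[ea, eb] = out.loc[eb, ea] = tau
    return out
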