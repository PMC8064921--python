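"""Physiological efficiencies and derived plot traits.

Grain yield decomposes multiplicatively into three efficiencies: light
interception (Ei, from the canopy module), radiation-use efficiency
(RUE, g aboveground dry matter per MJ intercepted PAR) and apparent
harvest index (HI, seed dry weight over total aboveground dry matter).
This module computes RUE by both the regression (slope) and single-sample
(ratio) estimators, HI, the Beer-Lambert light extinction coefficient K,
the phenology intervals (reproductive length RL = R8 - R1 and seed-filling
length SFL = R7 - R5), and the plant-count covariate adjustment applied to
biomass samplings before any of them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import (
    DegenerateDataError,
    InsufficientDataError,
    InvalidArgumentError,
    InvalidPhenologyError,
)


@dataclass(frozen=True)
class LightProfile:
    """One paired light reading: PPFD below (I) and above (I0) the canopy
    at the plot's maximum leaf area index."""

    i_below: float
    i_above: float
    lai: float

    def __post_init__(self):
        if not (0 < self.i_below <= self.i_above):
            raise InvalidArgumentError(
                f"require 0 < I <= I0, got I={self.i_below}, I0={self.i_above}"
            )
        if self.lai <= 0:
            raise InvalidArgumentError(f"LAI must be positive, got {self.lai}")


def adjust_biomass(
    biomass_table: pd.DataFrame,
    value_col: str = "dry_matter",
    count_col: str = "n_plants",
) -> pd.DataFrame:
    """Covariate-standardize biomass samplings to the grand-mean plant count.

    Per sampling date, fits dry matter ~ RIL + environment + replication +
    n_plants and returns each plot's fitted-plus-residual value evaluated at
    the grand-mean plant count, i.e. y - beta * (n - mean(n)). With equal
    plant counts the data are returned unchanged. The adjustment preserves
    each sampling date's grand mean (least-squares centering).

    Expects columns: ril, env, replication, sampling_dap, ``count_col``,
    ``value_col``.
    """
    required = {"ril", "env", "replication", "sampling_dap", count_col, value_col}
    missing = required - set(biomass_table.columns)
    if missing:
        raise InvalidArgumentError(f"biomass table missing columns: {sorted(missing)}")
    if (biomass_table[count_col] <= 0).any():
        raise InvalidArgumentError("all plots must have n_plants > 0")

    out = biomass_table.copy()
    adjusted = np.empty(len(out), dtype=float)
    for dap, idx in out.groupby("sampling_dap").groups.items():
        sub = out.loc[idx]
        counts = sub[count_col].to_numpy(dtype=float)
        if np.ptp(counts) == 0:
            adjusted[out.index.get_indexer(idx)] = sub[value_col].to_numpy(float)
            continue
        df = sub.rename(columns={value_col: "_y", count_col: "_n"})
        # build the factor design greedily (factors take priority over the
        # covariate): a factor that would make the design rank-deficient or
        # saturated is dropped with a warning
        factor_terms, dropped = [], []
        for factor in ("ril", "env", "replication"):
            if df[factor].nunique() < 2:
                continue
            candidate = factor_terms + [f"C({factor})"]
            exog = smf.ols(f"_y ~ {' + '.join(candidate)} + _n", data=df).exog
            if (np.linalg.matrix_rank(exog[:, :-1]) == exog.shape[1] - 1
                    and exog.shape[0] > exog.shape[1] - 1):
                factor_terms = candidate
            else:
                dropped.append(factor)
        if dropped:
            warnings.warn(
                f"sampling {dap}: factors {dropped} confounded with the "
                "design; dropped from the biomass adjustment",
                stacklevel=2,
            )
        terms = factor_terms + ["_n"]
        model = smf.ols(f"_y ~ {' + '.join(terms)}", data=df)
        n_col = list(model.exog_names).index("_n")
        without_n = np.delete(model.exog, n_col, axis=1)
        proj = without_n @ np.linalg.lstsq(without_n, model.exog[:, n_col],
                                           rcond=None)[0]
        if np.allclose(proj, model.exog[:, n_col], atol=1e-8):
            raise DegenerateDataError(
                f"plant count is confounded with factors {factor_terms} at "
                f"sampling {dap}; biomass cannot be covariate-adjusted"
            )
        fit = model.fit()
        beta = fit.params["_n"]
        adjusted[out.index.get_indexer(idx)] = (
            df["_y"].to_numpy(float) - beta * (counts - counts.mean())
        )
    out[value_col + "_adj"] = adjusted
    return out


def rue_slope(biomass_points, force_origin: bool = False) -> float:
    """RUE as the OLS slope of dry matter on cumulative intercepted PAR.

    ``biomass_points`` is a sequence of (cum_intercepted MJ/m2, dry matter
    g/m2) pairs — one per biomass sampling. The intercept is estimated
    freely unless ``force_origin``.
    """
    arr = np.asarray(biomass_points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise InsufficientDataError("need >= 2 (cum PAR, dry matter) points")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise DegenerateDataError("all cumulative-PAR abscissae are equal")
    if force_origin:
        return float(np.sum(x * y) / np.sum(x * x))
    exog = sm.add_constant(x)
    return float(sm.OLS(y, exog).fit().params[1])


def rue_ratio(total_dm: float, cum_intercepted: float) -> float:
    """RUE as the single-sampling ratio: total dry matter / cumulative PAR."""
    if cum_intercepted <= 0:
        raise InvalidArgumentError("cumulative intercepted PAR must be positive")
    return float(total_dm) / float(cum_intercepted)


def harvest_index(seed_weight: float, total_dm: float) -> float:
    """Apparent HI: seed weight (0% moisture) over total aboveground dry matter."""
    if total_dm <= 0:
        raise InvalidArgumentError("total dry matter must be positive")
    if seed_weight < 0 or seed_weight > total_dm:
        raise InvalidArgumentError(
            f"seed weight must lie in [0, total dry matter]: "
            f"{seed_weight} vs {total_dm} (check units/moisture basis)"
        )
    return float(seed_weight) / float(total_dm)


def extinction_coefficient(profile: LightProfile) -> float:
    """Beer-Lambert K from one below/above-canopy light pair: ln(I0/I)/LAI."""
    return float(np.log(profile.i_above / profile.i_below) / profile.lai)


def phenology_traits(r1: float, r5: float, r7: float, r8: float) -> tuple[float, float]:
    """Reproductive length RL = R8 - R1 and seed-filling length SFL = R7 - R5.

    R7 = R5 (zero seed-filling length) is tolerated with a warning; any
    other ordering violation raises.
    """
    if not (r1 < r5 <= r7 < r8):
        raise InvalidPhenologyError(
            f"require R1 < R5 <= R7 < R8, got ({r1}, {r5}, {r7}, {r8})"
        )
    if r7 == r5:
        warnings.warn("R7 == R5: seed-filling length is 0", stacklevel=2)
    return float(r8 - r1), float(r7 - r5)
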