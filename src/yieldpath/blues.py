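"""Per-environment stage-one mixed model and BLUE extraction.

For each trait within each environment the plot phenotype is modelled as

    Y_ijk = mu + f(x) + alpha_i + (alpha beta)_ij + delta_k + e_ijk

with intercept mu, a fixed nearest-neighbour spatial covariate f(x) (the
mean phenotype of the four rook-adjacent plots), fixed RIL effects delta_k
(the BLUEs, under a sum-to-zero contrast), and random replication alpha_i,
replication-by-block (alpha beta)_ij and residual terms.

The REML fit profiles the residual variance and optimizes the two
variance ratios (replication and rep-by-block relative to residual) on the
restricted log-likelihood; with only ~66 random-effect levels the Woodbury
identity keeps every evaluation cheap regardless of plot count. BLUEs are
reported as intercept + delta_k, so any constant convention cancels after
per-environment standardization.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .errors import DegenerateDataError, InsufficientDataError, InvalidArgumentError

logger = logging.getLogger(__name__)


def spatial_covariate(
    plots: pd.DataFrame,
    value_col: str,
    row_col: str = "row",
    col_col: str = "col",
) -> pd.Series:
    """Mean phenotype of each plot's four rook-adjacent neighbours.

    Edge and corner plots average whatever neighbours exist (1-3); diagonal
    neighbours are never used. A plot with no planted neighbour at all gets
    the field mean, with a warning.
    """
    pos = {
        (int(r), int(c)): v
        for r, c, v in zip(plots[row_col], plots[col_col], plots[value_col])
    }
    if len(pos) != len(plots):
        raise InvalidArgumentError("duplicate (row, col) positions in plot table")
    grand = float(plots[value_col].mean())
    out = np.empty(len(plots))
    isolated = 0
    for i, (r, c) in enumerate(zip(plots[row_col], plots[col_col])):
        vals = [
            pos[key]
            for key in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1))
            if key in pos
        ]
        if vals:
            out[i] = float(np.mean(vals))
        else:
            out[i] = grand
            isolated += 1
    if isolated:
        warnings.warn(
            f"{isolated} plot(s) have no rook neighbours; covariate set to "
            "the environment mean",
            stacklevel=2,
        )
    return pd.Series(out, index=plots.index, name="f_x")


@dataclass
class StageOneModel:
    trait: str
    env: str
    mu: float
    blues: pd.Series                 # per-RIL BLUE (mu + delta_k)
    f_x: pd.Series                   # the spatial covariate used (or zeros)
    beta_spatial: float
    varcomp: dict[str, float]        # replication, rep_block, residual
    loglik: float
    converged: bool
    unreplicated: list[str]


def _reml_objective(log_gammas, zs, xtx, xty, ztx, zty, ztz, yty, n, p):
    """Negative restricted log-likelihood profiled over the residual variance.

    V = sigma2 (I + sum_r gamma_r Z_r Z_r'); all products are cached blocks.
    """
    gammas = np.exp(log_gammas)
    d = np.concatenate([np.full(z.shape[1], g) for z, g in zip(zs, gammas)])
    q = d.size
    sd = np.sqrt(d)
    m = np.eye(q) + (sd[:, None] * ztz * sd[None, :])
    lm = np.linalg.cholesky(m)
    logdet_v = 2.0 * np.log(np.diag(lm)).sum()

    # Woodbury: A'V^-1 B (in sigma2-free units) = A'B - (A'Z D^.5) M^-1 (D^.5 Z'B)
    xtz_s = ztx.T * sd[None, :]           # p x q
    ytz_s = zty * sd                      # q
    wx = np.linalg.solve(lm, xtz_s.T)     # q x p
    wy = np.linalg.solve(lm, ytz_s)       # q
    xvx = xtx - wx.T @ wx
    xvy = xty - wx.T @ wy
    yvy = float(yty - wy @ wy)

    lx = np.linalg.cholesky(xvx + 1e-10 * np.eye(p))
    logdet_xvx = 2.0 * np.log(np.diag(lx)).sum()
    beta = np.linalg.solve(xvx + 1e-10 * np.eye(p), xvy)
    rss = yvy - xvy @ beta
    sigma2 = max(rss / (n - p), 1e-12)
    return 0.5 * ((n - p) * np.log(sigma2) + logdet_v + logdet_xvx
                  + (n - p)), beta, sigma2, gammas


def fit_stage_one(
    plots: pd.DataFrame,
    trait: str,
    use_spatial: bool = True,
    env: str = "",
    max_iter: int = 200,
) -> StageOneModel:
    """REML fit of the stage-one model for one trait in one environment.

    ``plots`` needs columns ril, replication, block, row, col and the trait.
    Returns per-RIL BLUEs, the spatial coefficient, and variance components
    (replication, replication-by-block, residual). Boundary solutions
    (a variance estimated at ~0) are kept with a warning rather than raised.
    """
    needed = {"ril", "replication", "block", "row", "col", trait}
    missing = needed - set(plots.columns)
    if missing:
        raise InvalidArgumentError(f"plot table missing columns: {sorted(missing)}")
    data = plots.dropna(subset=[trait]).reset_index(drop=True)
    if len(data) < 5:
        raise InsufficientDataError(f"too few plots ({len(data)}) for {trait}")
    if data["replication"].nunique() < 2:
        raise InsufficientDataError("need >= 2 replications")

    y = data[trait].to_numpy(dtype=float)
    n = y.size

    rils = sorted(data["ril"].unique())
    ril_idx = data["ril"].map({r: i for i, r in enumerate(rils)}).to_numpy()
    counts = np.bincount(ril_idx, minlength=len(rils))
    unreplicated = [r for r, c in zip(rils, counts) if c < 2]

    # sum-to-zero RIL contrasts: columns for all but the last RIL
    n_r = len(rils)
    ril_x = np.zeros((n, n_r - 1))
    for j in range(n_r - 1):
        ril_x[ril_idx == j, j] = 1.0
    ril_x[ril_idx == n_r - 1, :] = -1.0

    cols = [np.ones((n, 1))]
    f_x = pd.Series(np.zeros(n), index=data.index, name="f_x")
    beta_spatial = 0.0
    spatial_used = False
    if use_spatial:
        f_x = spatial_covariate(data, trait)
        if np.ptp(f_x.to_numpy()) > 1e-12:
            cols.append((f_x.to_numpy() - f_x.mean()).reshape(-1, 1))
            spatial_used = True
        else:
            logger.info("spatial covariate constant for %s/%s; dropped",
                        env, trait)
    cols.append(ril_x)
    x = np.hstack(cols)
    p = x.shape[1]
    if n <= p:
        raise InsufficientDataError(
            f"{n} plots cannot identify {p} fixed effects for {trait}"
        )

    reps = sorted(data["replication"].unique())
    z_rep = np.zeros((n, len(reps)))
    for j, r in enumerate(reps):
        z_rep[(data["replication"] == r).to_numpy(), j] = 1.0
    rb = list(map(tuple, data[["replication", "block"]].drop_duplicates()
                  .sort_values(["replication", "block"]).to_numpy()))
    rb_map = {k: i for i, k in enumerate(rb)}
    z_blk = np.zeros((n, len(rb)))
    for i, key in enumerate(zip(data["replication"], data["block"])):
        z_blk[i, rb_map[tuple(key)]] = 1.0
    zs = [z_rep, z_blk]
    z_all = np.hstack(zs)

    xtx, xty = x.T @ x, x.T @ y
    ztx, zty, ztz = z_all.T @ x, z_all.T @ y, z_all.T @ z_all
    yty = float(y @ y)

    def nll(log_gammas):
        val, *_ = _reml_objective(
            log_gammas, zs, xtx, xty, ztx, zty, ztz, yty, n, p
        )
        return val

    best = None
    for start in ([-2.0, -2.0], [0.0, 0.0], [-6.0, -6.0]):
        res = minimize(nll, start, method="Nelder-Mead",
                       options={"maxiter": max_iter, "xatol": 1e-8,
                                "fatol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    val, beta, sigma2, gammas = _reml_objective(
        best.x, zs, xtx, xty, ztx, zty, ztz, yty, n, p
    )
    var_rep, var_blk = gammas[0] * sigma2, gammas[1] * sigma2
    if min(gammas) < 1e-7:
        warnings.warn(
            f"variance component at boundary (~0) for {env}/{trait}",
            stacklevel=2,
        )

    mu = float(beta[0])
    offset = 2 if spatial_used else 1
    beta_spatial = float(beta[1]) if spatial_used else 0.0
    deltas = np.append(beta[offset:], -beta[offset:].sum())
    blues = pd.Series(mu + deltas, index=rils, name=trait)

    return StageOneModel(
        trait=trait, env=env, mu=mu, blues=blues, f_x=f_x,
        beta_spatial=beta_spatial,
        varcomp={"replication": float(var_rep),
                 "rep_block": float(var_blk),
                 "residual": float(sigma2)},
        loglik=float(-val), converged=bool(best.success or val < np.inf),
        unreplicated=unreplicated,
    )


def standardize_by_env(blues: pd.DataFrame) -> pd.DataFrame:
    """Z-score every trait column (sample SD, n-1 denominator).

    Missing entries stay missing; a zero-variance trait raises with its name.
    """
    out = blues.copy()
    for col in out.columns:
        vals = out[col].astype(float)
        if vals.notna().sum() < 2:
            raise DegenerateDataError(f"trait {col!r} has < 2 non-missing values")
        sd = vals.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise DegenerateDataError(f"trait {col!r} has zero variance")
        out[col] = (vals - vals.mean()) / sd
    return out


def corrected_phenotypes(
    plots: pd.DataFrame, trait: str, env: str = ""
) -> pd.Series:
    """Plot phenotypes corrected for replication and incomplete block.

    Fixed-effect adjustment used as the joint-regression input: subtract the
    OLS replication and replication-by-block effect estimates from a model
    with RIL, replication and rep-by-block (no spatial covariate), keeping
    all genetic effects in the data. Returns one value per plot.
    """
    data = plots.dropna(subset=[trait])
    y = data[trait].to_numpy(dtype=float)
    design = pd.get_dummies(
        data[["replication", "block"]].astype(str).agg("_".join, axis=1),
        dtype=float,
    )
    rep_d = pd.get_dummies(data["replication"].astype(str), dtype=float)
    ril_d = pd.get_dummies(data["ril"].astype(str), dtype=float)
    x = np.hstack([ril_d.to_numpy(), rep_d.to_numpy(), design.to_numpy()])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    n_ril = ril_d.shape[1]
    nuisance = x[:, n_ril:] @ beta[n_ril:]
    corrected = y - (nuisance - nuisance.mean())
    return pd.Series(corrected, index=data.index, name=trait)
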