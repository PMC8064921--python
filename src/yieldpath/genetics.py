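"""Kinship construction and multitrait additive-genetic covariance.

The genomic relationship matrix follows VanRaden's first method: with
dosage matrix M (lines x markers) and allele frequencies p,

    K = (M - 2p)(M - 2p)' / (2 * sum_m p_m (1 - p_m)).

The additive-genetic (G) and residual (R) trait covariance matrices come
from kinship mixed models on per-line means of the standardized
cross-environment BLUEs (the entry-mean basis, which is also the basis on
which narrow-sense heritabilities are reported):

    y_t = mu_t + u_t + e_t,   u ~ N(0, G x K),  e ~ N(0, R x I).

Rotating by the eigenvectors of K decorrelates lines, so the restricted
likelihood factorizes over lines with per-line 2x2 (or 1x1) covariance
d_i G + R. Each trait is fitted univariately for (G_ii, R_ii); every pair
is then fitted bivariately for the two covariances with the variances held
at their univariate estimates, the assembled G and R are bent to the
nearest PSD matrices (eigenvalue clipping, diagonal preserved) and the
perturbation norms reported. Because BLUEs averaged over environments are
the observations, R absorbs environmental and G-by-E covariance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

from .errors import DegenerateDataError, InvalidArgumentError
from .synthetic import SNPMatrix
from .utils import bend_psd

logger = logging.getLogger(__name__)


@dataclass
class KinshipMatrix:
    lines: list[str]
    values: np.ndarray

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.lines, columns=self.lines)


@dataclass
class GeneticFit:
    traits: list[str]
    G: pd.DataFrame
    R: pd.DataFrame
    h2: pd.Series
    n_lines_used: int
    method: str = "pairwise-bivariate-REML"
    bending_norm_G: float = 0.0
    bending_norm_R: float = 0.0


def kinship_vanraden(snps: SNPMatrix | np.ndarray, line_ids=None) -> KinshipMatrix:
    """VanRaden genomic relationship matrix from 0/1/2 dosages."""
    if isinstance(snps, SNPMatrix):
        m = snps.genotypes.astype(float)
        lines = list(snps.line_ids)
    else:
        m = np.asarray(snps, dtype=float)
        lines = list(line_ids) if line_ids is not None else [
            f"L{i}" for i in range(m.shape[0])
        ]
    if m.shape[0] < 2:
        raise InvalidArgumentError("kinship needs >= 2 lines")
    p = m.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise DegenerateDataError("all markers are monomorphic")
    m, p = m[:, poly], p[poly]
    w = m - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    k = (w @ w.T) / denom
    return KinshipMatrix(lines, 0.5 * (k + k.T))


def _univariate_reml(y: np.ndarray, d: np.ndarray, x: np.ndarray):
    """REML for y = X b + u + e on the kinship eigenbasis.

    ``d`` are kinship eigenvalues; per-observation variance is
    sigma_g^2 d_i + sigma_e^2. Profiles sigma_e^2 and optimizes the ratio
    lambda = sigma_g^2 / sigma_e^2 on a log grid + local refinement.
    Returns (sigma_g^2, sigma_e^2, restricted loglik).
    """
    n, p = y.size, x.shape[1]

    def profile(log_lam):
        lam = np.exp(log_lam)
        v = lam * d + 1.0
        xv = x / v[:, None]
        xvx = x.T @ xv
        xvy = xv.T @ y
        beta = np.linalg.solve(xvx, xvy)
        r = y - x @ beta
        rss = float(r @ (r / v))
        sigma_e = max(rss / (n - p), 1e-12)
        nll = 0.5 * ((n - p) * np.log(sigma_e) + np.log(v).sum()
                     + np.log(np.linalg.det(xvx)) + (n - p))
        return nll, sigma_e

    grid = np.linspace(-8, 6, 29)
    best_ll = min(grid, key=lambda g: profile(g)[0])
    res = minimize_scalar(
        lambda g: profile(g)[0],
        bracket=None, bounds=(best_ll - 1.0, best_ll + 1.0), method="bounded",
        options={"xatol": 1e-8},
    )
    log_lam = res.x if res.fun <= profile(best_ll)[0] else best_ll
    nll, sigma_e = profile(log_lam)
    lam = np.exp(log_lam)
    return lam * sigma_e, sigma_e, -nll


def _bivariate_pair(y1, y2, d, g11, r11, g22, r22):
    """REML estimate of (g12, r12) with the variances held fixed.

    Observations on the kinship eigenbasis are independent pairs with
    covariance Sigma_i = d_i G + R; the two correlations are parameterized
    through atanh to keep both matrices PD during optimization.
    """
    n = y1.size
    ones = np.ones(n)

    def nll(params):
        rho_g, rho_r = np.tanh(params)
        g12 = rho_g * np.sqrt(g11 * g22)
        r12 = rho_r * np.sqrt(r11 * r22)
        s11 = d * g11 + r11
        s22 = d * g22 + r22
        s12 = d * g12 + r12
        det = s11 * s22 - s12 ** 2
        if np.any(det <= 0):
            return 1e12
        # GLS intercepts per trait from the accumulated 2x2 system
        i11 = s22 / det
        i22 = s11 / det
        i12 = -s12 / det
        a = np.array([[i11.sum(), i12.sum()], [i12.sum(), i22.sum()]])
        b = np.array([i11 @ y1 + i12 @ y2, i12 @ y1 + i22 @ y2])
        mu = np.linalg.solve(a, b)
        e1, e2 = y1 - mu[0], y2 - mu[1]
        quad = i11 @ (e1 * e1) + 2.0 * (i12 @ (e1 * e2)) + i22 @ (e2 * e2)
        sign, logdet_a = np.linalg.slogdet(a)
        if sign <= 0:
            return 1e12
        return 0.5 * (np.log(det).sum() + quad + logdet_a)

    best = None
    for start in ([0.0, 0.0], [1.0, 0.0], [-1.0, 0.0]):
        res = minimize(nll, start, method="Nelder-Mead",
                       options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    # restart from the incumbent: recovers from a collapsed simplex on the
    # flat ridge that appears when a variance sits at the zero boundary
    res = minimize(nll, best.x, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
    if res.fun < best.fun:
        best = res
    rho_g, rho_r = np.tanh(best.x)
    return (rho_g * np.sqrt(g11 * g22), rho_r * np.sqrt(r11 * r22),
            bool(best.fun < 1e11))


def fit_multitrait(
    blues: pd.DataFrame | dict[str, pd.DataFrame],
    kin: KinshipMatrix,
    psd_floor: float = 1e-6,
) -> GeneticFit:
    """G and R covariance matrices from standardized per-environment BLUEs.

    ``blues`` is either a stacked long-format frame with a 'ril' column (or
    ril index) and one column per trait — several rows per line when several
    environments contribute — or a dict env -> (ril x trait) frame. Rows are
    averaged per line (entry-mean basis) before the kinship REML.
    """
    if isinstance(blues, dict):
        stacked = pd.concat(
            [f.rename_axis("ril").reset_index() for f in blues.values()],
            ignore_index=True,
        )
    else:
        stacked = blues.copy()
        if "ril" not in stacked.columns:
            stacked = stacked.rename_axis("ril").reset_index()
    traits = [c for c in stacked.columns if c != "ril"]
    if len(traits) < 2:
        raise InvalidArgumentError("need >= 2 traits")
    means = stacked.groupby("ril")[traits].mean()

    common = [line for line in kin.lines if line in means.index]
    if len(common) < 10:
        raise InvalidArgumentError(
            f"only {len(common)} lines shared between BLUEs and kinship"
        )
    k_frame = kin.frame().loc[common, common]
    y_all = means.loc[common, traits]

    d, u = np.linalg.eigh(k_frame.to_numpy())
    d = np.clip(d, 0.0, None)
    rot = {t: u.T @ y_all[t].to_numpy(dtype=float) for t in traits}
    x = (u.T @ np.ones(len(common)))[:, None]

    n_t = len(traits)
    g = np.zeros((n_t, n_t))
    r = np.zeros((n_t, n_t))
    for i, t in enumerate(traits):
        g[i, i], r[i, i], _ = _univariate_reml(rot[t], d, x)
    for i in range(n_t):
        for j in range(i + 1, n_t):
            if g[i, i] <= 1e-10 or g[j, j] <= 1e-10:
                g[i, j] = g[j, i] = 0.0
                r[i, j] = r[j, i] = 0.0
                continue
            g12, r12, ok = _bivariate_pair(
                rot[traits[i]], rot[traits[j]], d,
                g[i, i], r[i, i], g[j, j], r[j, j],
            )
            if not ok:
                warnings.warn(
                    f"bivariate REML failed for ({traits[i]}, {traits[j]}); "
                    "covariance set to 0",
                    stacklevel=2,
                )
                g12, r12 = 0.0, 0.0
            g[i, j] = g[j, i] = g12
            r[i, j] = r[j, i] = r12

    g_bent, g_norm = bend_psd(g, floor=psd_floor)
    r_bent, r_norm = bend_psd(r, floor=psd_floor)
    logger.info("PSD bending: |dG|=%.3g |dR|=%.3g", g_norm, r_norm)

    h2 = pd.Series(
        np.diag(g_bent) / np.maximum(np.diag(g_bent) + np.diag(r_bent), 1e-12),
        index=traits, name="h2",
    )
    return GeneticFit(
        traits=traits,
        G=pd.DataFrame(g_bent, index=traits, columns=traits),
        R=pd.DataFrame(r_bent, index=traits, columns=traits),
        h2=h2, n_lines_used=len(common),
        bending_norm_G=g_norm, bending_norm_R=r_norm,
    )


def genetic_correlations(fit: GeneticFit, min_h2: float = 0.02) -> pd.DataFrame:
    """G_ij / sqrt(G_ii G_jj); the diagonal is exactly 1.

    A trait whose genetic variance is negligible (heritability below
    ``min_h2``, i.e. the REML solution sits at the zero-variance boundary)
    has no defined genetic correlation: its off-diagonal entries are
    returned missing rather than as the ratio of two near-zero numbers.
    """
    g = fit.G.to_numpy()
    sd = np.sqrt(np.diag(g))
    undefined = (sd == 0) | (fit.h2.to_numpy() < min_h2)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = g / np.outer(sd, sd)
    corr[undefined, :] = np.nan
    corr[:, undefined] = np.nan
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    return pd.DataFrame(corr, index=fit.traits, columns=fit.traits)


def heritability(fit: GeneticFit) -> pd.Series:
    """Narrow-sense h2 per trait on the entry-mean basis."""
    return fit.h2.copy()
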