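"""Synthetic maturity-controlled RIL field study with known ground truth.

Emulates the structure of the field experiment the pipeline analyses: a
family-structured panel of recombinant inbred lines (RILs) genotyped at
biallelic SNPs, evaluated in three environments in an alpha-lattice design
(2 replications x 32 incomplete blocks), with UAV-style canopy-coverage
time series, repeated biomass samplings, phenology scores, gas exchange,
light profiles and grain yield per plot.

Generation proceeds in three layers:

1. genotypes — two founder haplotypes per family, inbred recombinant
   progeny (near-homozygous, independent markers, no linkage map);
2. truth — additive breeding values linear in marker dosages whose
   across-line sample covariance matches a target G exactly (a linear
   second-moment correction is applied to the random marker effects),
   plus per-environment trait shifts and per-line G-by-E sensitivity
   multipliers averaging 1;
3. trial — per-plot latent traits = mean + env shift + breeding value +
   field effect (smooth spatial surface, block, replication) + residual
   drawn from a target R, pushed through the forward model: logistic
   canopy growth, biomass proportional to cumulative intercepted PAR times
   the line's radiation-use efficiency, grain as harvest index times final
   biomass, and Beer-Lambert light profiles.

Latent traits (per-line genetic parameters) and their defaults are
calibrated so that trait summaries of the emitted panel fall in the
published per-environment ranges; the default latent genetic correlation
matrix is seeded from the published additive-genetic correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import CoverageError, InvalidArgumentError
from .fixtures import read_table2_fixture
from .utils import bend_psd, check_psd, rng_from_seed

# ---------------------------------------------------------------------------
# latent genetic parameters

LATENTS = [
    "mu_max", "cc_max", "rue", "hi", "r1", "r5", "r7", "r8",
    "lai", "k_ext", "a", "iwue",
]

LATENT_MEANS = {
    "mu_max": 0.105, "cc_max": 81.0, "rue": 1.25, "hi": 0.40,
    "r1": 40.0, "r5": 73.0, "r7": 112.0, "r8": 119.0,
    "lai": 5.0, "k_ext": 0.47, "a": 27.0, "iwue": 20.0,
}

LATENT_SDS = {
    "mu_max": 0.011, "cc_max": 3.5, "rue": 0.12, "hi": 0.045,
    "r1": 2.6, "r5": 1.8, "r7": 2.6, "r8": 3.0,
    "lai": 1.0, "k_ext": 0.08, "a": 1.9, "iwue": 8.0,
}

#: narrow-sense heritability of each latent (published diagonal where the
#: latent maps to a published trait; invented for cc_max and r7)
LATENT_H2 = {
    "mu_max": 0.71, "cc_max": 0.60, "rue": 0.36, "hi": 0.68,
    "r1": 0.78, "r5": 0.71, "r7": 0.65, "r8": 0.69,
    "lai": 0.56, "k_ext": 0.43, "a": 0.20, "iwue": 0.20,
}

#: latent -> published-trait used to seed the default genetic correlations
_LATENT_TO_TABLE = {
    "mu_max": "AGR40", "rue": "RUE", "hi": "HI", "r1": "R1", "r5": "R5",
    "r8": "R8", "lai": "LAI", "k_ext": "K", "a": "A", "iwue": "iWUE",
}

#: per-environment shifts of the latent means (location-year effects)
DEFAULT_ENV_EFFECTS = {
    "E1": {"mu_max": 0.013, "r1": -0.6, "r5": -5.5, "r7": -3.5, "r8": -4.5,
           "lai": 0.3, "k_ext": 0.13, "rue": -0.04, "hi": -0.012, "iwue": 0.5},
    "E2": {"mu_max": -0.003, "r1": -0.3, "r5": 1.0, "r7": 0.5, "r8": 1.5,
           "lai": -0.9, "k_ext": -0.05, "rue": -0.02, "hi": 0.004, "iwue": -2.0},
    "E3": {"mu_max": -0.018, "r1": 0.9, "r5": 4.5, "r7": 3.0, "r8": 3.0,
           "lai": 0.6, "k_ext": -0.08, "rue": 0.0, "hi": 0.008, "iwue": 1.5},
}

#: per-trait sensitivity to the shared spatial field trend: soil gradients
#: push growth-related traits together (positive loadings of different
#: magnitude) and phenology weakly, so residuals are correlated but far
#: from collinear across traits
SPATIAL_LOADINGS = {
    "mu_max": 0.6, "cc_max": 0.5, "rue": 0.8, "hi": 0.4, "r1": -0.3,
    "r5": 0.3, "r7": 0.4, "r8": 0.5, "lai": 0.9, "k_ext": 0.3,
    "a": 0.5, "iwue": 0.4,
}

#: per-environment yield-potential deviation; each line's biomass responds
#: as 1 + slope_i * eta_e, so the average line (slope 1) experiences the
#: common environment quality and sensitive lines amplify it (mean ~ 0)
DEFAULT_ENV_INDEX = {"E1": -0.16, "E2": 0.06, "E3": 0.10}


def default_latent_correlation() -> pd.DataFrame:
    """Genetic correlation matrix of the latent traits.

    Entries between latents that map to published traits come from the
    packaged additive-genetic correlation table; cc_max and r7 (for which
    no published analogue exists) get mild invented values. The assembled
    matrix is bent to PSD with the diagonal kept at 1.
    """
    corr_tab, _ = read_table2_fixture()
    n = len(LATENTS)
    c = np.eye(n)
    for i, a in enumerate(LATENTS):
        for j, b in enumerate(LATENTS):
            if j >= i:
                continue
            ta, tb = _LATENT_TO_TABLE.get(a), _LATENT_TO_TABLE.get(b)
            if ta is not None and tb is not None:
                val = float(corr_tab.loc[ta, tb])
            elif "r7" in (a, b):
                other = b if a == "r7" else a
                if other in ("r5", "r8"):
                    val = 0.6
                else:
                    to = _LATENT_TO_TABLE.get(other)
                    val = (
                        0.5 * (corr_tab.loc["R5", to] + corr_tab.loc["R8", to])
                        if to else 0.1
                    )
            else:  # cc_max
                other = b if a == "cc_max" else a
                val = {"mu_max": 0.3, "lai": 0.25, "r7": 0.1}.get(other, 0.0)
            c[i, j] = c[j, i] = val
    bent, _ = bend_psd(c, floor=1e-4)
    return pd.DataFrame(bent, index=LATENTS, columns=LATENTS)


def default_g_target() -> pd.DataFrame:
    corr = default_latent_correlation().to_numpy()
    d = np.array([LATENT_SDS[t] * np.sqrt(LATENT_H2[t]) for t in LATENTS])
    return pd.DataFrame(corr * np.outer(d, d), index=LATENTS, columns=LATENTS)


def default_r_target() -> pd.DataFrame:
    d = np.array([LATENT_SDS[t] ** 2 * (1 - LATENT_H2[t]) for t in LATENTS])
    return pd.DataFrame(np.diag(d), index=LATENTS, columns=LATENTS)


# ---------------------------------------------------------------------------
# genotypes

@dataclass
class SNPMatrix:
    line_ids: list[str]
    genotypes: np.ndarray        # lines x markers, dosages in {0, 1, 2}
    allele_freqs: np.ndarray     # per-marker minor-allele frequency
    families: np.ndarray | None = None  # family index per line

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes)
        if self.genotypes.shape[0] != len(self.line_ids):
            raise InvalidArgumentError("genotypes rows must match line_ids")


def generate_genotypes(
    n_lines: int,
    n_families: int,
    n_snps: int,
    seed: int,
    het_rate: float = 0.02,
    max_redraws: int = 200,
) -> SNPMatrix:
    """Family-structured RIL genotypes.

    Two founder haplotypes per family carry alleles drawn at frequency 0.5;
    each RIL inherits, per marker, one founder allele (markers independent —
    no linkage map) and is homozygous for it except for residual
    heterozygosity ``het_rate`` (RILs after ~5 selfing generations).
    Markers monomorphic across the panel are redrawn so the returned matrix
    has exactly ``n_snps`` polymorphic markers. Deterministic given ``seed``.
    """
    if n_lines < 2 or n_snps < 10 or n_families < 1:
        raise InvalidArgumentError(
            "require n_lines >= 2, n_snps >= 10, n_families >= 1"
        )
    if n_families > n_lines:
        raise InvalidArgumentError("n_families cannot exceed n_lines")
    rng = rng_from_seed(seed)
    families = np.repeat(np.arange(n_families), -(-n_lines // n_families))[:n_lines]

    def draw(cols: int) -> np.ndarray:
        geno = np.empty((n_lines, cols), dtype=np.int8)
        for fam in range(n_families):
            rows = np.flatnonzero(families == fam)
            founders = rng.integers(0, 2, size=(2, cols))  # two haplotypes
            picks = rng.integers(0, 2, size=(len(rows), cols))
            alleles = founders[picks, np.arange(cols)]
            geno[rows] = 2 * alleles
        het = rng.random((n_lines, cols)) < het_rate
        geno[het] = 1
        return geno

    genotypes = draw(n_snps)
    for _ in range(max_redraws):
        mono = np.flatnonzero(np.ptp(genotypes, axis=0) == 0)
        if mono.size == 0:
            break
        genotypes[:, mono] = draw(mono.size)
    else:
        raise InvalidArgumentError(
            "could not generate a fully polymorphic marker set; "
            "increase n_lines or n_families"
        )
    p = genotypes.mean(axis=0) / 2.0
    maf = np.minimum(p, 1 - p)
    line_ids = [f"RIL{idx + 1:04d}" for idx in range(n_lines)]
    return SNPMatrix(line_ids, genotypes, maf, families=families)


# ---------------------------------------------------------------------------
# truth

@dataclass
class TruthRecord:
    traits: list[str]
    breeding_values: pd.DataFrame      # lines x traits
    G_true: pd.DataFrame
    R_true: pd.DataFrame
    env_effects: pd.DataFrame          # envs x traits mean shifts
    gxe_slopes: pd.Series              # per-line sensitivity, mean exactly 1
    seed: int
    marker_effects: np.ndarray | None = None
    spatial_surface: pd.DataFrame | None = None  # filled by simulate_trial


def simulate_truth(
    snps: SNPMatrix,
    G_target,
    R_target,
    seed: int,
    traits: list[str] | None = None,
    envs: tuple[str, ...] = ("E1", "E2", "E3"),
    env_effects: pd.DataFrame | None = None,
    gxe_slope_sd: float = 0.55,
) -> TruthRecord:
    """Draw additive breeding values with across-line covariance G_target.

    Marker effects are drawn i.i.d. normal per trait and then linearly
    recombined so that the sample covariance of the breeding values equals
    ``G_target`` exactly (second-moment matching); genetic values remain
    linear in marker dosages. ``R_target`` is carried through for the trial
    stage's plot-level residual draws.
    """
    G = pd.DataFrame(G_target).astype(float)
    R = pd.DataFrame(R_target).astype(float)
    if traits is None:
        traits = [str(c) for c in G.columns]
    traits = list(traits)
    if G.shape != (len(traits), len(traits)) or R.shape != G.shape:
        raise InvalidArgumentError("G_target and R_target must be square and match")
    check_psd(G.to_numpy(), "G_target")
    check_psd(R.to_numpy(), "R_target")

    rng = rng_from_seed(seed)
    n_lines = len(snps.line_ids)
    n_traits = len(traits)
    w = snps.genotypes.astype(float)
    w = w - w.mean(axis=0)

    g = G.to_numpy()
    wg, vg = np.linalg.eigh(g)
    g_half = (vg * np.sqrt(np.clip(wg, 0, None))) @ vg.T

    raw_effects = rng.standard_normal((w.shape[1], n_traits))
    u0 = w @ raw_effects
    if n_lines > n_traits:
        s = np.cov(u0, rowvar=False, ddof=1)
        s = np.atleast_2d(s)
        ws_, vs_ = np.linalg.eigh(s)
        s_inv_half = (vs_ * (1.0 / np.sqrt(np.maximum(ws_, 1e-12)))) @ vs_.T
        transform = s_inv_half @ g_half
    else:
        transform = g_half
    u = (u0 - u0.mean(axis=0)) @ transform
    marker_effects = raw_effects @ transform

    bv = pd.DataFrame(u, index=snps.line_ids, columns=traits)

    if env_effects is None:
        env_effects = pd.DataFrame(0.0, index=list(envs), columns=traits)
    else:
        env_effects = env_effects.reindex(index=list(envs), columns=traits).fillna(0.0)

    b = rng.normal(0.0, gxe_slope_sd, size=n_lines)
    b -= b.mean()
    gxe = pd.Series(1.0 + b, index=snps.line_ids, name="gxe_slope")

    return TruthRecord(
        traits=traits, breeding_values=bv,
        G_true=pd.DataFrame(g, index=traits, columns=traits),
        R_true=pd.DataFrame(R.to_numpy(), index=traits, columns=traits),
        env_effects=env_effects, gxe_slopes=gxe, seed=int(seed),
        marker_effects=marker_effects,
    )


# ---------------------------------------------------------------------------
# weather

def make_weather(
    envs=("E1", "E2", "E3"),
    n_days: int = 150,
    seed: int = 0,
    mean_solar: float = 15.0,
    amplitude: float = 5.0,
    daily_sd: float = 2.0,
) -> pd.DataFrame:
    """Sinusoidal seasonal incident solar radiation with daily noise.

    Daily global solar radiation (MJ/m2) peaks mid-season; defaults give a
    cumulative seasonal total near 2,000 MJ/m2, matching the magnitude of
    the study environments. Columns: env, dap, solar_MJ_m2.
    """
    rng = rng_from_seed(seed)
    frames = []
    for k, env in enumerate(envs):
        dap = np.arange(0, n_days + 1)
        base = mean_solar + (k - 1) * 0.4
        solar = base + amplitude * np.sin(np.pi * (dap + 10) / (n_days + 25))
        solar = np.clip(solar + rng.normal(0, daily_sd, dap.size), 1.0, None)
        frames.append(pd.DataFrame(
            {"env": env, "dap": dap, "solar_MJ_m2": np.round(solar, 3)}
        ))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# trial

@dataclass
class TrialLayout:
    envs: tuple[str, ...] = ("E1", "E2", "E3")
    n_reps: int = 2
    n_blocks: int = 32
    drop_fraction: float = 0.04
    #: RUE estimator per environment: 'slope' needs the multi-sampling
    #: schedule, 'ratio' the single late sampling
    rue_method: dict[str, str] = field(
        default_factory=lambda: {"E1": "ratio", "E2": "slope", "E3": "slope"}
    )
    sampling_daps: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: {"slope": (38, 58, 84), "ratio": (91,)}
    )
    flight_daps: tuple[int, ...] = (10, 22, 34, 46, 58, 70)
    env_index: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ENV_INDEX)
    )


@dataclass
class NoiseConfig:
    """Measurement/field noise of the emitted observations.

    The canopy-coverage noise is a plain additive Gaussian on each flight
    observation (the acquisition chain's error structure is not documented,
    so it is exposed here rather than asserted).
    """

    cc_sd: float = 2.0            # % coverage, additive per flight
    biomass_frac: float = 0.06    # multiplicative on each biomass sample
    seed_frac: float = 0.05       # multiplicative on seed weight
    lai_sd: float = 0.35
    ppfd_frac: float = 0.03
    a_sd: float = 1.0
    iwue_sd: float = 3.0
    y0_sd: float = 0.2
    spatial_amp: float = 0.30     # field trend, in latent-SD units
    block_sd: float = 0.25        # incomplete-block effect, latent-SD units
    rep_sd: float = 0.10
    plant_beta: float = 8.0       # g/m2 extra dry matter per extra plant
    plant_target: int = 15        # expected plants in the sampled row section

    @classmethod
    def zero(cls) -> "NoiseConfig":
        return cls(cc_sd=0, biomass_frac=0, seed_frac=0, lai_sd=0,
                   ppfd_frac=0, a_sd=0, iwue_sd=0, y0_sd=0, spatial_amp=0,
                   block_sd=0, rep_sd=0, plant_beta=0)


@dataclass
class PlotObservation:
    env: str
    replication: int
    block: int
    ril: str
    row: int
    col: int
    n_plants: int
    cc_series: list[tuple[float, float]]
    biomass_samples: list[tuple[float, float]]
    phenology: dict[str, int]          # keys r1, r5, r7, r8
    gas_exchange: tuple[float, float]  # (A, iWUE)
    lai_max: float
    light_pair: tuple[float, float]    # (I below, I0 above)
    seed_weight: float                 # g/m2 at 0% moisture
    total_dm: float                    # g/m2 aboveground dry matter at R8
    grain_yield: float                 # kg/ha at 13% moisture

    def validate(self) -> None:
        daps = [d for d, _ in self.cc_series]
        ccs = [c for _, c in self.cc_series]
        if any(np.diff(daps) <= 0):
            raise InvalidArgumentError("cc_series DAP must be strictly increasing")
        if min(ccs) < 0 or max(ccs) > 100:
            raise InvalidArgumentError("cc values must lie in [0, 100]")
        p = self.phenology
        if not (p["r1"] < p["r5"] <= p["r7"] < p["r8"]):
            raise InvalidArgumentError("phenology ordering violated")
        if self.n_plants <= 0 or self.lai_max <= 0:
            raise InvalidArgumentError("n_plants and lai_max must be positive")


@dataclass
class TrialData:
    plots: list[PlotObservation]
    weather: pd.DataFrame
    truth: TruthRecord
    layout: TrialLayout

    def plots_frame(self) -> pd.DataFrame:
        rows = []
        for i, p in enumerate(self.plots):
            rows.append({
                "plot_id": f"{p.env}_{p.replication}_{p.ril}",
                "env": p.env, "replication": p.replication, "block": p.block,
                "ril": p.ril, "row": p.row, "col": p.col,
                "n_plants": p.n_plants,
                "r1": p.phenology["r1"], "r5": p.phenology["r5"],
                "r7": p.phenology["r7"], "r8": p.phenology["r8"],
                "a_photo": p.gas_exchange[0], "iwue": p.gas_exchange[1],
                "lai_max": p.lai_max,
                "i_below": p.light_pair[0], "i_above": p.light_pair[1],
                "seed_weight": p.seed_weight, "total_dm": p.total_dm,
                "grain_yield": p.grain_yield,
            })
        return pd.DataFrame(rows)

    def cc_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.plots:
            pid = f"{p.env}_{p.replication}_{p.ril}"
            for dap, cc in p.cc_series:
                rows.append({"plot_id": pid, "env": p.env, "dap": dap, "cc": cc})
        return pd.DataFrame(rows)

    def biomass_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.plots:
            pid = f"{p.env}_{p.replication}_{p.ril}"
            for dap, dm in p.biomass_samples:
                rows.append({
                    "plot_id": pid, "env": p.env, "replication": p.replication,
                    "ril": p.ril, "sampling_dap": dap, "dry_matter": dm,
                    "n_plants": p.n_plants,
                })
        return pd.DataFrame(rows)


def _spatial_surface(n_rows: int, n_cols: int, rng) -> np.ndarray:
    """Smooth standardized field trend: low-order polynomial + AR-like noise."""
    r = (np.arange(n_rows)[:, None] - n_rows / 2) / max(n_rows, 1)
    c = (np.arange(n_cols)[None, :] - n_cols / 2) / max(n_cols, 1)
    coef = rng.normal(0, 1, size=5)
    surf = (coef[0] * r + coef[1] * c + coef[2] * r * c
            + coef[3] * r ** 2 + coef[4] * c ** 2)
    noise = rng.normal(0, 1, size=(n_rows, n_cols))
    for axis in (0, 1):  # two passes of a 3-tap smoother ~ AR(1) texture
        noise = (np.roll(noise, 1, axis) + noise + np.roll(noise, -1, axis)) / 3.0
    surf = surf + 0.6 * noise
    sd = surf.std()
    return (surf - surf.mean()) / (sd if sd > 0 else 1.0)


def simulate_trial(
    truth: TruthRecord,
    layout: TrialLayout | None = None,
    weather: pd.DataFrame | None = None,
    seed: int = 0,
    noise: NoiseConfig | None = None,
    par_fraction: float = 0.5,
) -> TrialData:
    """Generate the full plot-level field study from the truth record."""
    layout = layout or TrialLayout()
    noise = noise or NoiseConfig()
    if weather is None:
        weather = make_weather(layout.envs, seed=truth.seed)
    rng = rng_from_seed(seed)

    traits = truth.traits
    for t in LATENTS:
        if t not in traits:
            raise InvalidArgumentError(f"truth must carry latent trait {t!r}")
    lines = list(truth.breeding_values.index)
    n_lines = len(lines)
    sds = np.array([LATENT_SDS[t] for t in LATENTS])
    means = np.array([LATENT_MEANS[t] for t in LATENTS])

    r_true = truth.R_true.loc[LATENTS, LATENTS].to_numpy()
    wr, vr = np.linalg.eigh(r_true)
    r_half = (vr * np.sqrt(np.clip(wr, 0, None))) @ vr.T

    block_size = -(-n_lines // layout.n_blocks)
    n_rows, n_cols = layout.n_reps * layout.n_blocks, block_size

    plots: list[PlotObservation] = []
    surface_rows = []
    for env in layout.envs:
        wx = weather.loc[weather["env"] == env]
        if wx.empty:
            raise CoverageError(f"weather has no rows for environment {env!r}")
        solar = dict(zip(wx["dap"].astype(int), wx["solar_MJ_m2"].astype(float)))
        max_dap = max(solar)
        env_shift = truth.env_effects.loc[env, LATENTS].to_numpy(dtype=float)
        eta = layout.env_index.get(env, 0.0)
        surf = _spatial_surface(n_rows, n_cols, rng)
        loadings = np.array([SPATIAL_LOADINGS[t] for t in LATENTS])
        # block and replication effects independent across traits
        blk_eff = rng.normal(
            0, noise.block_sd,
            size=(layout.n_reps, layout.n_blocks, len(LATENTS)),
        )
        rep_eff = rng.normal(0, noise.rep_sd,
                             size=(layout.n_reps, len(LATENTS)))
        method = layout.rue_method.get(env, "slope")
        samp_daps = layout.sampling_daps[method]

        keep = rng.random((layout.n_reps, n_lines)) >= layout.drop_fraction
        for rep in range(layout.n_reps):
            order = rng.permutation(n_lines)
            for pos, line_idx in enumerate(order):
                if not keep[rep, line_idx]:
                    continue
                block = pos // block_size
                col = pos % block_size
                row = rep * layout.n_blocks + block
                ril = lines[line_idx]

                z_field = (noise.spatial_amp * surf[row, col] * loadings
                           + blk_eff[rep, block] + rep_eff[rep])
                latent = (means + env_shift
                          + truth.breeding_values.loc[ril, LATENTS].to_numpy()
                          + z_field * sds
                          + r_half @ rng.standard_normal(len(LATENTS)))
                lv = dict(zip(LATENTS, latent))

                mu = max(lv["mu_max"], 0.01)
                k = float(np.clip(lv["cc_max"], 5.0, 100.0))
                y0 = 1.0 + abs(rng.normal(0, noise.y0_sd)) if noise.y0_sd else 1.0
                rue = max(lv["rue"], 0.1)
                hi = float(np.clip(lv["hi"], 0.05, 0.90))
                r1 = int(round(max(lv["r1"], 20)))
                r5 = int(round(max(lv["r5"], r1 + 5)))
                r7 = int(round(max(lv["r7"], r5 + 1)))
                r8 = int(round(max(lv["r8"], r7 + 2)))
                if r8 > max_dap:
                    raise CoverageError(
                        f"weather for {env!r} ends at DAP {max_dap} but a plot "
                        f"matures at R8 = {r8}"
                    )
                lai = max(lv["lai"], 0.3)
                k_ext = max(lv["k_ext"], 0.05)

                days = np.arange(0, r8 + 1)
                cc_true = k * y0 / (y0 + (k - y0) * np.exp(-mu * days))
                ipar = np.array([solar[int(d)] for d in days]) * par_fraction \
                    * cc_true / 100.0
                cum_ipar = np.cumsum(ipar)
                # G-by-E: biomass responds to the environment's yield
                # potential eta in proportion to the line's sensitivity
                # (slope-1 lines track the environment mean response)
                gxe = truth.gxe_slopes[ril]
                scale = max(1.0 + gxe * eta, 0.1)

                n_plants = max(int(rng.poisson(noise.plant_target)), 5) \
                    if noise.plant_beta else noise.plant_target
                samples = []
                for d in samp_daps:
                    d = min(d, r8)
                    dm = rue * cum_ipar[d] * scale
                    dm += noise.plant_beta * (n_plants - noise.plant_target)
                    dm *= 1.0 + rng.normal(0, noise.biomass_frac)
                    samples.append((float(d), float(max(dm, 1.0))))
                dm_final = rue * cum_ipar[r8] * scale
                total_dm = float(max(
                    dm_final * (1.0 + rng.normal(0, noise.biomass_frac)), 1.0
                ))
                seed_wt = float(np.clip(
                    hi * dm_final * (1.0 + rng.normal(0, noise.seed_frac)),
                    0.0, total_dm,
                ))
                gy = seed_wt * 10.0 / 0.87  # g/m2 dry -> kg/ha at 13% moisture

                flights = [
                    (float(d), float(np.clip(
                        k * y0 / (y0 + (k - y0) * np.exp(-mu * d))
                        + rng.normal(0, noise.cc_sd), 0.0, 100.0)))
                    for d in layout.flight_daps
                ]
                lai_meas = max(lai + rng.normal(0, noise.lai_sd), 0.3)
                i0 = 1600.0
                i_below = i0 * np.exp(-k_ext * lai_meas) \
                    * (1.0 + rng.normal(0, noise.ppfd_frac))
                i_below = float(np.clip(i_below, 1e-3, i0))
                a_val = lv["a"] + rng.normal(0, noise.a_sd)
                iwue_val = max(lv["iwue"] + rng.normal(0, noise.iwue_sd), 0.2)

                plot = PlotObservation(
                    env=env, replication=rep + 1, block=block + 1, ril=ril,
                    row=row, col=col, n_plants=n_plants, cc_series=flights,
                    biomass_samples=samples,
                    phenology={"r1": r1, "r5": r5, "r7": r7, "r8": r8},
                    gas_exchange=(float(a_val), float(iwue_val)),
                    lai_max=float(lai_meas),
                    light_pair=(i_below, i0),
                    seed_weight=seed_wt, total_dm=total_dm,
                    grain_yield=float(gy),
                )
                plot.validate()
                plots.append(plot)
                surface_rows.append({
                    "env": env, "row": row, "col": col,
                    "surface": noise.spatial_amp * surf[row, col],
                })

    truth = replace(truth, spatial_surface=pd.DataFrame(surface_rows))
    return TrialData(plots=plots, weather=weather, truth=truth, layout=layout)


# ---------------------------------------------------------------------------
# one-call convenience

@dataclass
class PanelConfig:
    n_lines: int = 383
    n_families: int = 32
    n_snps: int = 3000
    layout: TrialLayout = field(default_factory=TrialLayout)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    gxe_slope_sd: float = 0.55
    par_fraction: float = 0.5


def simulate_panel(config: PanelConfig | None = None, seed: int = 0):
    """Genotypes + truth + trial in one deterministic call.

    Seeds for the three layers are derived from ``seed`` so distinct stages
    never share a stream.
    """
    config = config or PanelConfig()
    snps = generate_genotypes(
        config.n_lines, config.n_families, config.n_snps, seed=seed
    )
    env_effects = pd.DataFrame(DEFAULT_ENV_EFFECTS).T.reindex(
        index=list(config.layout.envs), columns=LATENTS
    ).fillna(0.0)
    truth = simulate_truth(
        snps, default_g_target(), default_r_target(), seed=seed + 1,
        traits=LATENTS, envs=tuple(config.layout.envs),
        env_effects=env_effects, gxe_slope_sd=config.gxe_slope_sd,
    )
    weather = make_weather(config.layout.envs, seed=seed + 2)
    trial = simulate_trial(
        truth, config.layout, weather, seed=seed + 3, noise=config.noise,
        par_fraction=config.par_fraction,
    )
    return snps, trial
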