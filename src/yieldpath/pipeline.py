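"""End-to-end orchestration: synthetic study -> traits -> BLUEs -> G/R ->
path + network + stability, with CSV contracts and a reproducibility
manifest.

Every stage is an importable function operating on data frames; the CSV
files written between stages are plain UTF-8 comma-separated tables with a
header row and empty cells for missing values, so any stage can be re-run
from its inputs alone. ``run_pipeline`` chains all stages and records a
manifest (package version, seeds, config hash, per-stage record counts).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .blues import corrected_phenotypes, fit_stage_one, standardize_by_env
from .canopy import (
    agr40,
    fit_logistic,
    intercepted_par,
    light_interception_efficiency,
)
from .errors import InvalidArgumentError
from .fixtures import TRAITS, read_table2_fixture
from .genetics import fit_multitrait, genetic_correlations, kinship_vanraden
from .network import lambda_grid, neighborhood_lasso, select_lambda
from .path import PathDiagram, default_diagram, implied_correlation_check, path_coefficients
from .physiology import (
    LightProfile,
    adjust_biomass,
    extinction_coefficient,
    harvest_index,
    phenology_traits,
    rue_ratio,
    rue_slope,
)
from .stability import classify_stability, cross_env_stability, fw_regression
from .synthetic import NoiseConfig, PanelConfig, TrialLayout, simulate_panel

logger = logging.getLogger(__name__)

STABILITY_TRAITS = ["Ei", "RUE", "HI", "GY"]


@dataclass
class PipelineConfig:
    seed: int = 1
    outdir: str = "results/pipeline"
    n_lines: int = 383
    n_families: int = 32
    n_snps: int = 3000
    drop_fraction: float = 0.04
    par_fraction: float = 0.5
    agr_days: int = 40
    interception_window: str = "planting_to_r8"  # or 'emergence_to_r8'
    emergence_dap: int = 8
    rue_method: dict[str, str] = field(
        default_factory=lambda: {"E1": "ratio", "E2": "slope", "E3": "slope"}
    )
    diagram: dict[str, list[str]] | None = None
    network_rule: str = "OR"
    network_gamma: float = 0.5
    lambda_points: int = 30
    lambda_min_ratio: float = 0.01
    fw_traits: list[str] = field(default_factory=lambda: list(STABILITY_TRAITS))
    type_ii_band: float = 0.25

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth = raw.pop("synthetic", {})
        raw.update(synth)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def panel_config(self) -> PanelConfig:
        layout = TrialLayout(
            drop_fraction=self.drop_fraction,
            rue_method=dict(self.rue_method),
        )
        return PanelConfig(
            n_lines=self.n_lines, n_families=self.n_families,
            n_snps=self.n_snps, layout=layout, noise=NoiseConfig(),
            par_fraction=self.par_fraction,
        )


# ---------------------------------------------------------------------------
# stages

def stage_simulate(config: PipelineConfig):
    snps, trial = simulate_panel(config.panel_config(), seed=config.seed)
    logger.info("simulate: %d plots, %d lines, %d markers",
                len(trial.plots), len(snps.line_ids), snps.genotypes.shape[1])
    return snps, trial


def compute_plot_traits(
    plots: pd.DataFrame,
    cc: pd.DataFrame,
    biomass: pd.DataFrame,
    weather: pd.DataFrame,
    par_fraction: float = 0.5,
    rue_method: dict[str, str] | None = None,
    agr_days: int = 40,
    window_start: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-plot trait table (Ei, AGR40, RUE, HI, K, RL, SFL, GY, A, iWUE,
    LAI, R1, R5, R8) plus the logistic canopy fits.

    Plots whose canopy fit does not converge are dropped from the trait
    table (they stay in the fit table, flagged).
    """
    rue_method = rue_method or {}
    weather_by_env = {
        env: dict(zip(sub["dap"].astype(int), sub["solar_MJ_m2"].astype(float)))
        for env, sub in weather.groupby("env")
    }
    biomass_adj = adjust_biomass(biomass)
    bio_by_plot = {
        pid: sub for pid, sub in biomass_adj.groupby("plot_id")
    }
    cc_by_plot = {pid: sub for pid, sub in cc.groupby("plot_id")}

    fit_rows, trait_rows = [], []
    n_dropped = 0
    for rec in plots.itertuples():
        pid = rec.plot_id
        series = cc_by_plot[pid][["dap", "cc"]].to_numpy(dtype=float)
        fit = fit_logistic(series)
        fit_rows.append({
            "plot_id": pid, "y0": fit.y0, "k": fit.k, "mu_max": fit.mu_max,
            "rss": fit.rss, "converged": fit.converged,
        })
        if not fit.converged:
            n_dropped += 1
            continue

        wtable = weather_by_env[rec.env]
        series_par = intercepted_par(
            fit, wtable, (window_start, int(rec.r8)), par_fraction
        )
        ei = light_interception_efficiency(series_par)
        cum = dict(zip(series_par.dap, series_par.cum_intercepted))

        bio = bio_by_plot.get(pid)
        rue_val = np.nan
        if bio is not None and len(bio):
            method = rue_method.get(rec.env, "slope" if len(bio) > 1 else "ratio")
            points = [
                (cum[int(min(d, rec.r8))], dm)
                for d, dm in zip(bio["sampling_dap"], bio["dry_matter_adj"])
            ]
            if method == "slope" and len(points) >= 2:
                rue_val = rue_slope(points)
            else:
                d, dm = points[-1]
                rue_val = rue_ratio(dm, d)

        hi = harvest_index(min(rec.seed_weight, rec.total_dm), rec.total_dm)
        k_coef = extinction_coefficient(
            LightProfile(rec.i_below, rec.i_above, rec.lai_max)
        )
        rl, sfl = phenology_traits(rec.r1, rec.r5, rec.r7, rec.r8)
        trait_rows.append({
            "plot_id": pid, "env": rec.env, "replication": rec.replication,
            "block": rec.block, "ril": rec.ril, "row": rec.row, "col": rec.col,
            "Ei": 100.0 * ei, "AGR40": agr40(fit, agr_days), "RUE": rue_val,
            "HI": hi, "K": k_coef, "RL": rl, "SFL": sfl,
            "GY": rec.grain_yield, "R1": rec.r1, "R5": rec.r5, "R8": rec.r8,
            "LAI": rec.lai_max, "A": rec.a_photo, "iWUE": rec.iwue,
        })
    if n_dropped:
        logger.info("traits: dropped %d non-converged canopy fits", n_dropped)
    return pd.DataFrame(trait_rows), pd.DataFrame(fit_rows)


def stage_blues(
    traits_plot: pd.DataFrame, trait_names: list[str] | None = None
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-environment BLUEs (standardized) and variance components."""
    trait_names = trait_names or TRAITS
    blues_by_env: dict[str, pd.DataFrame] = {}
    varcomp_rows = []
    for env, sub in traits_plot.groupby("env"):
        cols = {}
        for trait in trait_names:
            model = fit_stage_one(sub, trait, env=env)
            cols[trait] = model.blues
            varcomp_rows.append({
                "env": env, "trait": trait, **model.varcomp,
                "beta_spatial": model.beta_spatial,
            })
        blues = pd.DataFrame(cols)
        blues_by_env[env] = standardize_by_env(blues)
    return blues_by_env, pd.DataFrame(varcomp_rows)


def stage_genetics(blues_by_env: dict[str, pd.DataFrame], snps):
    kin = kinship_vanraden(snps)
    fit = fit_multitrait(blues_by_env, kin)
    corr = genetic_correlations(fit)
    return fit, corr


def _fill_undefined(corr: pd.DataFrame) -> pd.DataFrame:
    """Undefined genetic correlations (boundary-zero genetic variance) are
    imputed as 0 for the downstream matrix analyses, with a logged warning.
    The gcorr.csv output keeps them missing."""
    if corr.isna().to_numpy().any():
        affected = [t for t in corr.index if corr[t].isna().any()]
        logger.warning(
            "undefined genetic correlations for %s imputed as 0 for "
            "path/network analyses", affected,
        )
        corr = corr.fillna(0.0)
    return corr


def stage_path(corr: pd.DataFrame, diagram_spec: dict | None = None):
    diagram = (
        PathDiagram({k: list(v) for k, v in diagram_spec.items()})
        if diagram_spec else default_diagram()
    )
    corr = _fill_undefined(corr)
    result = path_coefficients(corr, diagram)
    check = implied_correlation_check(result, diagram, corr)
    return result, diagram, check


def stage_network(corr: pd.DataFrame, config: PipelineConfig, n_eff: int):
    corr = _fill_undefined(corr)
    grid = lambda_grid(corr, config.lambda_points, config.lambda_min_ratio)
    lam, scores = select_lambda(
        corr, n_eff=n_eff, grid=grid, rule=config.network_rule,
        gamma=config.network_gamma,
    )
    net = neighborhood_lasso(corr, lam, rule=config.network_rule)
    return net, scores


def stage_stability(
    traits_plot: pd.DataFrame,
    blues_by_env: dict[str, pd.DataFrame],
    fw_traits: list[str],
    type_ii_band: float = 0.25,
):
    """FW joint regression per trait + cross-environment Kendall matrices."""
    fw_results, summary_rows, taus = {}, [], {}
    for trait in fw_traits:
        cells = []
        for env, sub in traits_plot.groupby("env"):
            corrected = corrected_phenotypes(sub, trait, env=env)
            cell = (
                pd.DataFrame({"ril": sub.loc[corrected.index, "ril"],
                              "value": corrected})
                .groupby("ril")["value"].mean().rename(env)
            )
            cells.append(cell)
        table = pd.concat(cells, axis=1)
        fit = fw_regression(table)
        summary = classify_stability(fit, type_ii_band=type_ii_band)
        fw_results[trait] = (fit, summary)
        counts = summary.types.value_counts()
        summary_rows.append({
            "trait": trait, "iqr": summary.iqr, "min": summary.minimum,
            "max": summary.maximum,
            **{f"n_type_{t}": int(counts.get(t, 0))
               for t in ("II", "III", "IV", "unclassified")},
        })
        taus[trait] = cross_env_stability(
            pd.concat({e: b[trait] for e, b in blues_by_env.items()}, axis=1)
        )
    return fw_results, pd.DataFrame(summary_rows), taus


# ---------------------------------------------------------------------------
# full run

def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in dependency order and write all outputs.

    Returns the manifest dictionary (also written to manifest.json).
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    snps, trial = stage_simulate(config)
    plots = trial.plots_frame()
    cc = trial.cc_frame()
    biomass = trial.biomass_frame()
    plots.to_csv(out / "plots.csv", index=False)
    cc.to_csv(out / "cc.csv", index=False)
    biomass.to_csv(out / "biomass.csv", index=False)
    trial.weather.to_csv(out / "weather.csv", index=False)
    pd.DataFrame(
        snps.genotypes, index=snps.line_ids
    ).rename_axis("ril").to_csv(out / "snps.csv")
    trial.truth.breeding_values.rename_axis("ril").to_csv(out / "truth.csv")
    counts["plots"] = len(plots)

    traits_plot, canopy_fits = compute_plot_traits(
        plots, cc, biomass, trial.weather,
        par_fraction=config.par_fraction, rue_method=config.rue_method,
        agr_days=config.agr_days,
        window_start=(0 if config.interception_window == "planting_to_r8"
                      else config.emergence_dap),
    )
    traits_plot.to_csv(out / "traits_plot.csv", index=False)
    canopy_fits.to_csv(out / "canopy_fits.csv", index=False)
    counts["traits_plot"] = len(traits_plot)

    blues_by_env, varcomp = stage_blues(traits_plot)
    for env, frame in blues_by_env.items():
        frame.rename_axis("ril").to_csv(out / f"blues_{env}.csv")
    varcomp.to_csv(out / "varcomp.csv", index=False)
    counts["blues_envs"] = len(blues_by_env)

    fit, corr = stage_genetics(blues_by_env, snps)
    fit.G.rename_axis("trait").to_csv(out / "G.csv")
    fit.R.rename_axis("trait").to_csv(out / "R.csv")
    corr.rename_axis("trait").to_csv(out / "gcorr.csv")
    fit.h2.rename_axis("trait").to_csv(out / "h2.csv")
    counts["lines_in_genetic_fit"] = fit.n_lines_used

    path_result, diagram, check = stage_path(corr, config.diagram)
    path_result.coefficient_frame().to_csv(out / "path_coefficients.csv",
                                           index=False)
    effects = pd.DataFrame(
        [{"source": s, "target": t, "total": v,
          "direct": path_result.coefficients.get((t, s), 0.0),
          "indirect": v - path_result.coefficients.get((t, s), 0.0)}
         for (s, t), v in path_result.total.items()]
    )
    effects.to_csv(out / "effects.csv", index=False)
    check.to_csv(out / "implied_corr_check.csv", index=False)

    net, scores = stage_network(corr, config, n_eff=fit.n_lines_used)
    net.edge_frame().to_csv(out / "network_edges.csv", index=False)
    scores.to_csv(out / "network_lambda_path.csv", index=False)
    counts["network_edges"] = len(net.edges())

    fw_results, fw_summary, taus = stage_stability(
        traits_plot, blues_by_env, config.fw_traits, config.type_ii_band
    )
    slopes = pd.DataFrame(
        {t: res[0].slopes for t, res in fw_results.items()}
    )
    slopes.rename_axis("ril").to_csv(out / "fw_slopes.csv")
    fw_summary.to_csv(out / "stability_summary.csv", index=False)
    for trait, tau in taus.items():
        tau.rename_axis("env").to_csv(out / f"tau_{trait}.csv")
    counts["fw_lines"] = len(slopes)

    manifest = {
        "package": "yieldpath",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": dataclasses.asdict(config),
        "counts": counts,
        "outputs": sorted(p.name for p in out.glob("*.csv")),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def run_fixture_analysis(outdir: str | Path) -> dict:
    """Path + network analysis on the packaged correlation matrix only."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    corr, h2 = read_table2_fixture()
    result, diagram, check = stage_path(corr, None)
    result.coefficient_frame().to_csv(out / "path_coefficients.csv", index=False)
    check.to_csv(out / "implied_corr_check.csv", index=False)
    lam, scores = select_lambda(corr, n_eff=383)
    net = neighborhood_lasso(corr, lam)
    net.edge_frame().to_csv(out / "network_edges.csv", index=False)
    scores.to_csv(out / "network_lambda_path.csv", index=False)
    return {
        "coefficients": result.coefficients,
        "lambda": lam,
        "edges": net.edges(),
        "h2": h2.to_dict(),
    }
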