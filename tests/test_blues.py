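"""Stage-one mixed model: spatial covariate, REML, BLUEs, standardization."""

import numpy as np
import pandas as pd
import pytest

from yieldpath.blues import (
    corrected_phenotypes,
    fit_stage_one,
    spatial_covariate,
    standardize_by_env,
)
from yieldpath.errors import DegenerateDataError


def _grid_plots(values: np.ndarray) -> pd.DataFrame:
    rows, cols = values.shape
    recs = [
        {"row": r, "col": c, "y": values[r, c]}
        for r in range(rows) for c in range(cols)
    ]
    return pd.DataFrame(recs)


class TestSpatialCovariate:
    def test_interior_plot_mean_of_four(self):
        grid = np.array([[0, 10, 0], [20, 99, 30], [0, 40, 0]], dtype=float)
        plots = _grid_plots(grid)
        cov = spatial_covariate(plots, "y")
        center = plots[(plots.row == 1) & (plots.col == 1)].index[0]
        assert cov[center] == pytest.approx(25.0)

    def test_corner_uses_available_neighbours(self):
        grid = np.array([[99, 10.0], [20.0, 0.0]])
        plots = _grid_plots(grid)
        cov = spatial_covariate(plots, "y")
        corner = plots[(plots.row == 0) & (plots.col == 0)].index[0]
        assert cov[corner] == pytest.approx(15.0)

    def test_isolated_plot_gets_field_mean_with_warning(self):
        plots = pd.DataFrame(
            [{"row": 0, "col": 0, "y": 5.0}, {"row": 10, "col": 10, "y": 9.0}]
        )
        with pytest.warns(UserWarning, match="no rook neighbours"):
            cov = spatial_covariate(plots, "y")
        assert np.allclose(cov, 7.0)


def _synthetic_trial(
    n_lines=60, rep_sd=0.0, block_sd=0.0, noise_sd=0.0, trend=0.0,
    seed=0, n_blocks=6,
):
    """Alpha-lattice-style single-environment data with known line means."""
    rng = np.random.default_rng(seed)
    line_effects = rng.normal(0, 2.0, n_lines)
    block_size = -(-n_lines // n_blocks)
    rep_effects = rng.normal(0, rep_sd, 2)
    rows = []
    for rep in range(2):
        order = rng.permutation(n_lines)
        blk_effects = rng.normal(0, block_sd, n_blocks)
        for pos, line in enumerate(order):
            block = pos // block_size
            r, c = rep * n_blocks + block, pos % block_size
            y = (10.0 + line_effects[line] + rep_effects[rep]
                 + blk_effects[block] + trend * (r + c)
                 + rng.normal(0, noise_sd))
            rows.append({
                "ril": f"L{line:03d}", "replication": rep + 1,
                "block": block + 1, "row": r, "col": c, "y": y,
            })
    truth = pd.Series(
        10.0 + line_effects, index=[f"L{i:03d}" for i in range(n_lines)]
    )
    return pd.DataFrame(rows), truth


class TestFitStageOne:
    def test_exact_recovery_without_noise(self):
        plots, truth = _synthetic_trial()
        model = fit_stage_one(plots, "y", env="E1")
        assert np.allclose(
            model.blues.sort_index(), truth.sort_index(), atol=1e-7
        )
        assert model.varcomp["residual"] < 1e-6

    def test_rep_variance_recovery(self):
        # known replication variance 4.0; REML should land near it
        estimates = []
        for seed in range(20):
            plots, _ = _synthetic_trial(
                n_lines=200, rep_sd=2.0, noise_sd=1.0, seed=seed, n_blocks=20
            )
            model = fit_stage_one(plots, "y", use_spatial=False, env="E1")
            estimates.append(model.varcomp["replication"])
        assert abs(np.median(estimates) - 4.0) / 4.0 < 0.25

    def test_spatial_covariate_reduces_trend_bias(self):
        # with a planar field trend, including f(x) must not hurt and should
        # help the BLUEs (mean squared error against the generating truth)
        mse_with, mse_without = [], []
        for seed in range(6):
            plots, truth = _synthetic_trial(
                trend=0.8, noise_sd=0.5, seed=seed
            )
            with_fx = fit_stage_one(plots, "y", use_spatial=True, env="E1")
            without = fit_stage_one(plots, "y", use_spatial=False, env="E1")

            def mse(m):
                b = m.blues.sort_index() - truth.sort_index()
                b = b - b.mean()  # constant shifts are removed downstream
                return float((b ** 2).mean())

            mse_with.append(mse(with_fx))
            mse_without.append(mse(without))
        assert np.mean(mse_with) < np.mean(mse_without)

    def test_block_relabeling_leaves_blues_unchanged(self):
        plots, _ = _synthetic_trial(block_sd=1.5, noise_sd=0.8, seed=3)
        model_a = fit_stage_one(plots, "y", use_spatial=False, env="E1")
        relabeled = plots.copy()
        mapping = {1: 4, 2: 6, 3: 1, 4: 5, 5: 3, 6: 2}
        relabeled["block"] = relabeled["block"].map(mapping)
        model_b = fit_stage_one(relabeled, "y", use_spatial=False, env="E1")
        assert np.allclose(model_a.blues, model_b.blues, atol=1e-6)

    def test_matches_dense_gls_reference(self):
        # independent dense GLS at the same variance components must agree
        plots, _ = _synthetic_trial(
            n_lines=25, rep_sd=1.0, block_sd=1.0, noise_sd=0.7, seed=5,
            n_blocks=5,
        )
        model = fit_stage_one(plots, "y", use_spatial=False, env="E1")
        rils = sorted(plots["ril"].unique())
        n = len(plots)
        n_r = len(rils)
        ril_idx = plots["ril"].map({r: i for i, r in enumerate(rils)}).to_numpy()
        ril_x = np.zeros((n, n_r - 1))
        for j in range(n_r - 1):
            ril_x[ril_idx == j, j] = 1.0
        ril_x[ril_idx == n_r - 1, :] = -1.0
        x = np.hstack([np.ones((n, 1)), ril_x])
        z_rep = pd.get_dummies(plots["replication"]).to_numpy(float)
        z_blk = pd.get_dummies(
            plots["replication"].astype(str) + "_" + plots["block"].astype(str)
        ).to_numpy(float)
        v = (model.varcomp["replication"] * z_rep @ z_rep.T
             + model.varcomp["rep_block"] * z_blk @ z_blk.T
             + model.varcomp["residual"] * np.eye(n))
        vinv = np.linalg.inv(v)
        beta = np.linalg.solve(x.T @ vinv @ x, x.T @ vinv @ plots["y"].to_numpy())
        blues_ref = beta[0] + np.append(beta[1:], -beta[1:].sum())
        assert np.allclose(model.blues[rils].to_numpy(), blues_ref, atol=1e-6)


class TestStandardize:
    def test_hand_computed_z_scores(self):
        frame = pd.DataFrame({"t": [1.0, 2.0, 3.0]})
        out = standardize_by_env(frame)
        assert np.allclose(out["t"], [-1.0, 0.0, 1.0])  # n-1 denominator

    def test_idempotent(self):
        frame = pd.DataFrame({"t": [-1.0, 0.0, 1.0]})
        out = standardize_by_env(standardize_by_env(frame))
        assert np.allclose(out["t"], [-1.0, 0.0, 1.0])

    def test_rank_order_preserved(self):
        rng = np.random.default_rng(1)
        frame = pd.DataFrame({"t": rng.normal(10, 4, 30)})
        out = standardize_by_env(frame)
        assert (frame["t"].rank() == out["t"].rank()).all()

    def test_zero_variance_names_trait(self):
        frame = pd.DataFrame({"flat": [2.0, 2.0, 2.0], "ok": [1.0, 2.0, 4.0]})
        with pytest.raises(DegenerateDataError, match="flat"):
            standardize_by_env(frame)

    def test_missing_entries_stay_missing(self):
        frame = pd.DataFrame({"t": [1.0, np.nan, 3.0, 5.0]})
        out = standardize_by_env(frame)
        assert out["t"].isna().sum() == 1


class TestCorrectedPhenotypes:
    def test_removes_rep_and_block_effects(self):
        plots, truth = _synthetic_trial(rep_sd=3.0, block_sd=2.0, seed=7)
        corrected = corrected_phenotypes(plots, "y")
        per_line = (
            pd.DataFrame({"ril": plots["ril"], "v": corrected})
            .groupby("ril")["v"].mean()
        )
        resid = per_line.sort_index() - truth.sort_index()
        assert resid.std() < 0.2  # only line effects + grand shift remain
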