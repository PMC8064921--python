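"""Synthetic panel generator: genotypes, truth, trial invariants."""

import numpy as np
import pandas as pd
import pytest

from yieldpath.errors import CoverageError, InvalidArgumentError, NotPSDError
from yieldpath.genetics import kinship_vanraden
from yieldpath.synthetic import (
    LATENTS,
    NoiseConfig,
    PanelConfig,
    TrialLayout,
    default_g_target,
    default_r_target,
    generate_genotypes,
    make_weather,
    simulate_panel,
    simulate_trial,
    simulate_truth,
)


class TestGenotypes:
    def test_inbred_lines_are_near_homozygous(self):
        snps = generate_genotypes(4, 1, 10, seed=1)
        assert snps.genotypes.shape == (4, 10)
        assert set(np.unique(snps.genotypes)) <= {0, 1, 2}
        big = generate_genotypes(300, 10, 800, seed=1)
        hom = np.isin(big.genotypes, (0, 2)).mean()
        assert hom >= 0.95  # 2% residual heterozygosity target

    def test_deterministic_given_seed(self):
        a = generate_genotypes(4, 1, 10, seed=1)
        b = generate_genotypes(4, 1, 10, seed=1)
        assert np.array_equal(a.genotypes, b.genotypes)
        c = generate_genotypes(4, 1, 10, seed=2)
        assert not np.array_equal(a.genotypes, c.genotypes)

    def test_no_monomorphic_markers(self):
        snps = generate_genotypes(20, 4, 50, seed=9)
        assert np.all(np.ptp(snps.genotypes, axis=0) > 0)
        assert np.all(snps.allele_freqs > 0)

    def test_family_structure_visible_in_kinship(self):
        snps = generate_genotypes(200, 8, 500, seed=7)
        kin = kinship_vanraden(snps).values
        fam = snps.families
        same = np.equal.outer(fam, fam) & ~np.eye(len(fam), dtype=bool)
        within = kin[same].mean()
        between = kin[~np.equal.outer(fam, fam)].mean()
        assert within > between

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(InvalidArgumentError):
            generate_genotypes(1, 1, 100, seed=0)
        with pytest.raises(InvalidArgumentError):
            generate_genotypes(10, 1, 5, seed=0)
        with pytest.raises(InvalidArgumentError):
            generate_genotypes(10, 20, 100, seed=0)


class TestTruth:
    def test_zero_g_gives_zero_breeding_values(self):
        snps = generate_genotypes(50, 5, 100, seed=0)
        zero = pd.DataFrame(np.zeros((2, 2)), index=["a", "b"], columns=["a", "b"])
        truth = simulate_truth(snps, zero, np.eye(2) * 0.1, seed=0,
                               traits=["a", "b"])
        assert np.allclose(truth.breeding_values.to_numpy(), 0.0, atol=1e-10)

    def test_identity_g_sample_covariance(self):
        snps = generate_genotypes(2000, 100, 1200, seed=0)
        truth = simulate_truth(snps, np.eye(2), np.eye(2), seed=0,
                               traits=["a", "b"])
        cov = np.cov(truth.breeding_values.to_numpy(), rowvar=False, ddof=1)
        assert np.abs(cov - np.eye(2)).max() < 0.1

    def test_high_correlation_target_recovered(self):
        snps = generate_genotypes(1000, 50, 800, seed=1)
        g = np.array([[1.0, 0.9], [0.9, 1.0]])
        truth = simulate_truth(snps, g, np.eye(2), seed=1, traits=["a", "b"])
        corr = np.corrcoef(truth.breeding_values.to_numpy(), rowvar=False)
        assert 0.8 < corr[0, 1] < 1.0

    def test_gxe_slopes_average_to_one(self):
        snps = generate_genotypes(80, 8, 100, seed=2)
        truth = simulate_truth(snps, np.eye(2), np.eye(2), seed=2,
                               traits=["a", "b"])
        assert truth.gxe_slopes.mean() == pytest.approx(1.0, abs=1e-12)

    def test_non_psd_target_names_eigenvalue(self):
        snps = generate_genotypes(20, 2, 50, seed=0)
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(NotPSDError, match="eigenvalue") as err:
            simulate_truth(snps, bad, np.eye(2), seed=0, traits=["a", "b"])
        assert err.value.min_eigenvalue == pytest.approx(-1.0)


def _tiny_panel(seed=0, **noise_kwargs):
    cfg = PanelConfig(
        n_lines=30, n_families=3, n_snps=60,
        layout=TrialLayout(n_blocks=6, drop_fraction=0.0),
        noise=NoiseConfig(**noise_kwargs) if noise_kwargs else NoiseConfig(),
    )
    return cfg, *simulate_panel(cfg, seed=seed)


class TestTrial:
    def test_plot_bookkeeping_without_drops(self):
        cfg, snps, trial = _tiny_panel()
        assert len(trial.plots) == 3 * 2 * 30  # envs x reps x lines

    def test_drop_fraction_removes_plots(self):
        cfg = PanelConfig(n_lines=40, n_families=4, n_snps=60,
                          layout=TrialLayout(n_blocks=8, drop_fraction=0.2))
        _, trial = simulate_panel(cfg, seed=1)
        assert len(trial.plots) < 3 * 2 * 40

    def test_noise_free_harvest_index_identity(self):
        snps = generate_genotypes(20, 2, 60, seed=4)
        g = default_g_target()
        r = pd.DataFrame(np.zeros_like(default_r_target()),
                         index=LATENTS, columns=LATENTS)
        env_effects = pd.DataFrame(0.0, index=["E1"], columns=LATENTS)
        truth = simulate_truth(snps, g, r, seed=4, traits=LATENTS,
                               envs=("E1",), env_effects=env_effects)
        layout = TrialLayout(envs=("E1",), n_blocks=4, drop_fraction=0.0,
                             env_index={"E1": 0.0})
        trial = simulate_trial(truth, layout, seed=4, noise=NoiseConfig.zero())
        from yieldpath.synthetic import LATENT_MEANS
        for plot in trial.plots:
            true_hi = LATENT_MEANS["hi"] + truth.breeding_values.loc[plot.ril, "hi"]
            assert plot.seed_weight / plot.total_dm == pytest.approx(
                np.clip(true_hi, 0.05, 0.90), rel=1e-12
            )

    def test_weather_shorter_than_maturity_raises(self):
        snps = generate_genotypes(10, 1, 50, seed=0)
        truth = simulate_truth(snps, default_g_target(), default_r_target(),
                               seed=0, traits=LATENTS, envs=("E1",))
        layout = TrialLayout(envs=("E1",), n_blocks=2, drop_fraction=0.0)
        short = make_weather(("E1",), n_days=60, seed=0)
        with pytest.raises(CoverageError):
            simulate_trial(truth, layout, weather=short, seed=0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_plot_invariants_over_seeds(self, seed):
        cfg, snps, trial = _tiny_panel(seed=seed)
        for plot in trial.plots:
            plot.validate()  # raises on any type-invariant violation
            assert plot.phenology["r1"] < plot.phenology["r5"]
            assert plot.seed_weight <= plot.total_dm

    def test_same_seed_bit_identical_different_seeds_differ(self):
        _, _, a = _tiny_panel(seed=11)
        _, _, b = _tiny_panel(seed=11)
        _, _, c = _tiny_panel(seed=12)
        pd.testing.assert_frame_equal(a.plots_frame(), b.plots_frame())
        assert not a.plots_frame().equals(c.plots_frame())

    def test_flat_mu_max_yields_flat_agr40(self):
        # zero genetic + residual variance in mu_max (and all other latents),
        # zero noise: every plot's early growth rate is identical
        from yieldpath.pipeline import compute_plot_traits

        snps = generate_genotypes(24, 2, 60, seed=6)
        zero_g = pd.DataFrame(np.zeros((len(LATENTS),) * 2),
                              index=LATENTS, columns=LATENTS)
        truth = simulate_truth(snps, zero_g, zero_g.copy(), seed=6,
                               traits=LATENTS, envs=("E1",))
        layout = TrialLayout(envs=("E1",), n_blocks=4, drop_fraction=0.0,
                             rue_method={"E1": "slope"})
        trial = simulate_trial(truth, layout, seed=6, noise=NoiseConfig.zero())
        traits, _ = compute_plot_traits(
            trial.plots_frame(), trial.cc_frame(), trial.biomass_frame(),
            trial.weather, rue_method=layout.rue_method,
        )
        assert traits["AGR40"].std() < 1e-8
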