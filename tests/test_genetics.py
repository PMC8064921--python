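"""Kinship and multitrait genetic covariance estimation."""

import numpy as np
import pandas as pd
import pytest

from yieldpath.errors import DegenerateDataError
from yieldpath.genetics import (
    GeneticFit,
    KinshipMatrix,
    fit_multitrait,
    genetic_correlations,
    heritability,
    kinship_vanraden,
)
from yieldpath.synthetic import generate_genotypes
from yieldpath.utils import bend_psd


class TestKinship:
    def test_identical_lines_share_diagonal_value(self):
        geno = np.array([[0, 2, 0, 2], [0, 2, 0, 2], [2, 0, 2, 0]])
        kin = kinship_vanraden(geno)
        assert kin.values[0, 1] == pytest.approx(kin.values[0, 0])

    def test_hand_computed_toy(self):
        geno = np.array([[0, 2], [2, 0], [2, 2]], dtype=float)
        p = geno.mean(axis=0) / 2  # (2/3, 2/3)
        w = geno - 2 * p
        expected = w @ w.T / (2 * np.sum(p * (1 - p)))
        kin = kinship_vanraden(geno)
        assert np.allclose(kin.values, expected)

    def test_centering_removes_marker_means(self):
        snps = generate_genotypes(50, 5, 200, seed=1)
        m = snps.genotypes.astype(float)
        w = m - m.mean(axis=0)
        assert np.allclose(w.mean(axis=0), 0.0, atol=1e-12)

    def test_monomorphic_only_raises(self):
        with pytest.raises(DegenerateDataError):
            kinship_vanraden(np.array([[2, 2], [2, 2], [2, 2]]))

    def test_symmetric(self):
        snps = generate_genotypes(40, 4, 150, seed=2)
        kin = kinship_vanraden(snps)
        assert np.allclose(kin.values, kin.values.T)


def _simulated_fit(n_lines, rho_g, h2, seed, n_traits=2, kin=None, snps_n=800):
    """Direct observation-level simulation: y = u + e with known G, R."""
    rng = np.random.default_rng(seed)
    if kin is None:
        snps = generate_genotypes(n_lines, max(n_lines // 10, 2), snps_n,
                                  seed=seed)
        kin = kinship_vanraden(snps)
    k = kin.frame().to_numpy()
    g = np.full((n_traits, n_traits), rho_g) * h2
    np.fill_diagonal(g, h2)
    r = np.eye(n_traits) * (1 - h2)
    lk = np.linalg.cholesky(k + 1e-8 * np.eye(n_lines))
    lg = np.linalg.cholesky(g + 1e-10 * np.eye(n_traits))
    u = lk @ rng.standard_normal((n_lines, n_traits)) @ lg.T
    e = rng.standard_normal((n_lines, n_traits)) @ np.sqrt(r)
    y = pd.DataFrame(u + e, index=kin.lines,
                     columns=[f"t{i}" for i in range(n_traits)])
    return fit_multitrait(y, kin), g, r


class TestMultitrait:
    def test_genetic_correlation_recovery(self):
        # truth: rho_g = 0.8, h2 = 0.6 per trait
        estimates = []
        for seed in range(10):
            fit, _, _ = _simulated_fit(400, rho_g=0.8, h2=0.6, seed=seed)
            estimates.append(genetic_correlations(fit).iloc[0, 1])
        assert 0.65 < np.median(estimates) < 0.95

    def test_null_correlations_near_zero(self):
        snps = generate_genotypes(500, 25, 600, seed=99)
        kin = kinship_vanraden(snps)
        rng = np.random.default_rng(99)
        y = pd.DataFrame(rng.standard_normal((500, 3)), index=kin.lines,
                         columns=["a", "b", "c"])
        fit = fit_multitrait(y, kin)
        corr = genetic_correlations(fit)
        off = corr.to_numpy()[~np.eye(3, dtype=bool)]
        # boundary-zero genetic variances yield undefined correlations;
        # anything defined must be near zero
        assert np.all(np.isnan(off) | (np.abs(off) < 0.15))

    def test_null_with_identity_kinship(self):
        # G and R are only jointly identified when K = I; the estimated
        # total covariance must still be near zero for independent traits
        rng = np.random.default_rng(7)
        lines = [f"L{i}" for i in range(500)]
        kin = KinshipMatrix(lines, np.eye(500))
        y = pd.DataFrame(rng.standard_normal((500, 2)), index=lines,
                         columns=["a", "b"])
        fit = fit_multitrait(y, kin)
        total = fit.G.iloc[0, 1] + fit.R.iloc[0, 1]
        assert abs(total) < 0.15

    def test_duplicate_trait_has_unit_genetic_correlation(self):
        snps = generate_genotypes(300, 30, 600, seed=1)
        kin = kinship_vanraden(snps)
        rng = np.random.default_rng(1)
        k = kin.frame().to_numpy()
        u = np.linalg.cholesky(k + 1e-8 * np.eye(300)) @ rng.standard_normal(300)
        y = pd.DataFrame(
            {"a": np.sqrt(0.6) * u + rng.normal(0, np.sqrt(0.4), 300)},
            index=kin.lines,
        )
        y["a_copy"] = y["a"]
        dup_fit = fit_multitrait(y, kin)
        assert genetic_correlations(dup_fit).loc["a", "a_copy"] >= 0.98

    def test_h2_recovery(self):
        estimates = []
        for seed in range(10):
            fit, _, _ = _simulated_fit(400, rho_g=0.5, h2=0.8, seed=100 + seed)
            estimates.append(fit.h2.iloc[0])
        assert abs(np.median(estimates) - 0.8) <= 0.1

    def test_line_permutation_equivariance(self):
        # genetically structured data: away from the zero-variance boundary
        # the REML solution is unique, so relabeling must not change G or R
        n = 300
        snps = generate_genotypes(n, 30, 500, seed=4)
        kin = kinship_vanraden(snps)
        rng = np.random.default_rng(4)
        k = kin.frame().to_numpy()
        lk = np.linalg.cholesky(k + 1e-8 * np.eye(n))
        g = np.array([[0.5, 0.3], [0.3, 0.5]])
        u = lk @ rng.standard_normal((n, 2)) @ np.linalg.cholesky(g).T
        y = pd.DataFrame(u + rng.standard_normal((n, 2)) * np.sqrt(0.5),
                         index=kin.lines, columns=["a", "b"])
        fit1 = fit_multitrait(y, kin)
        perm = rng.permutation(n)
        kin_p = KinshipMatrix([kin.lines[i] for i in perm],
                              kin.values[np.ix_(perm, perm)])
        fit2 = fit_multitrait(y.iloc[perm], kin_p)
        # tolerance reflects optimizer precision on the flat REML ridge,
        # not statistical error
        assert np.allclose(fit1.G, fit2.G, atol=2e-3)
        assert np.allclose(fit1.R, fit2.R, atol=2e-3)

    def test_outputs_are_psd(self):
        fit, _, _ = _simulated_fit(200, rho_g=0.7, h2=0.5, seed=11, n_traits=3)
        assert np.linalg.eigvalsh(fit.G.to_numpy()).min() >= 0
        assert np.linalg.eigvalsh(fit.R.to_numpy()).min() >= 0
        assert fit.bending_norm_G < 0.05
        corr = genetic_correlations(fit)
        assert np.all(np.abs(corr.to_numpy()) <= 1.0 + 1e-12)
        assert np.allclose(corr, corr.T)


class TestDerived:
    def test_correlation_formula(self):
        fit = GeneticFit(
            traits=["a", "b"],
            G=pd.DataFrame([[4.0, 2.0], [2.0, 4.0]], index=["a", "b"],
                           columns=["a", "b"]),
            R=pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"]),
            h2=pd.Series([0.8, 0.8], index=["a", "b"]),
            n_lines_used=10,
        )
        corr = genetic_correlations(fit)
        assert corr.loc["a", "b"] == pytest.approx(0.5)
        assert np.allclose(np.diag(corr), 1.0)

    def test_zero_genetic_variance_flagged_missing(self):
        fit = GeneticFit(
            traits=["a", "b"],
            G=pd.DataFrame([[0.0, 0.0], [0.0, 4.0]], index=["a", "b"],
                           columns=["a", "b"]),
            R=pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"]),
            h2=pd.Series([0.0, 0.8], index=["a", "b"]),
            n_lines_used=10,
        )
        corr = genetic_correlations(fit)
        assert np.isnan(corr.loc["a", "b"])

    def test_heritability_boundary_cases(self):
        fit = GeneticFit(
            traits=["a", "b"],
            G=pd.DataFrame(np.diag([2.0, 1.0]), index=["a", "b"],
                           columns=["a", "b"]),
            R=pd.DataFrame(np.diag([0.0, 1.0]), index=["a", "b"],
                           columns=["a", "b"]),
            h2=pd.Series([1.0, 0.5], index=["a", "b"]),
            n_lines_used=10,
        )
        h2 = heritability(fit)
        assert h2["a"] == pytest.approx(1.0)
        assert h2["b"] == pytest.approx(0.5)

    def test_bending_preserves_diagonal(self):
        mat = np.array([[1.0, 0.99, -0.9], [0.99, 1.0, 0.3], [-0.9, 0.3, 1.0]])
        bent, norm = bend_psd(mat)
        assert np.linalg.eigvalsh(bent).min() >= 0
        assert np.allclose(np.diag(bent), 1.0)
        assert norm > 0
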