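import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr
from scipy.stats import chisquare

import coral
from coral.backbone import (
    BackboneConfig,
    BackbonePosterior,
    _sign_align_mean,
    coefficient_conditional_moments,
    extract_latent_point_estimates,
    fit_backbone,
)
from conftest import random_taxonomy
from coral.data import build_taxonomic_correlation


def dense_kronecker_conditional(Zb, X, C, V, M0, rho):
    """Oracle: brute-force dense Gaussian conditional of vec(B) | z."""
    p, n_s = M0.shape
    P = rho * np.asarray(C) + (1 - rho) * np.eye(n_s)
    prior_prec = np.kron(np.linalg.inv(P), np.linalg.inv(V))
    lik_prec = np.kron(np.eye(n_s), X.T @ X)
    Q = prior_prec + lik_prec
    rhs = prior_prec @ M0.flatten(order="F") + (X.T @ Zb).flatten(order="F")
    cov = np.linalg.inv(Q)
    return cov @ rhs, cov


class TestCoefficientConditional:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, n_s, p = 12, int(rng.integers(2, 5)), int(rng.integers(1, 4))
        tax = random_taxonomy(rng, n_s)
        C = build_taxonomic_correlation(tax).to_numpy()
        X = rng.normal(size=(n, p))
        Zb = rng.normal(size=(n, n_s))
        A = rng.normal(size=(p, p))
        V = A @ A.T + np.eye(p)
        M0 = rng.normal(size=(p, n_s))
        rho = float(rng.uniform(0, 0.95))
        mean, cov = coefficient_conditional_moments(Zb, X, C, V, M0, rho)
        mean_o, cov_o = dense_kronecker_conditional(Zb, X, C, V, M0, rho)
        assert np.allclose(mean, mean_o, atol=1e-8)
        assert np.allclose(cov, cov_o, atol=1e-8)


def _small_dataset(seed=0, n=120, n_s=8):
    rng = np.random.default_rng(seed)
    tax = random_taxonomy(rng, n_s)
    X = pd.DataFrame(
        np.column_stack([np.ones(n), rng.normal(size=(n, 2))]),
        columns=["intercept", "a", "b"],
    )
    B = rng.normal(size=(3, n_s)) * 0.8
    Y = pd.DataFrame(
        (rng.random((n, n_s)) < ndtr(X.to_numpy() @ B)).astype(int),
        columns=list(tax.species_ids),
    )
    C = build_taxonomic_correlation(tax)
    return Y, X, C, tax


class TestSampler:
    def test_identical_seed_identical_draws(self):
        Y, X, C, _ = _small_dataset()
        cfg = BackboneConfig(chains=2, iterations=60, burn_in=20, thin=4, seed=9,
                             n_factors_site=2, n_factors_sample=1)
        sites = pd.Series(["s%d" % (i % 5) for i in range(len(Y))])
        bp1 = fit_backbone(Y, X, C, cfg=cfg, latent=True, site_of_sample=sites)
        bp2 = fit_backbone(Y, X, C, cfg=cfg, latent=True, site_of_sample=sites)
        assert np.array_equal(bp1.B, bp2.B)
        assert np.array_equal(bp1.rho, bp2.rho)
        assert np.array_equal(bp1.eta_site, bp2.eta_site)

    def test_draw_count_and_shapes(self):
        Y, X, C, _ = _small_dataset()
        cfg = BackboneConfig(chains=2, iterations=50, burn_in=10, thin=5, seed=0,
                             n_factors_site=2, n_factors_sample=1)
        sites = pd.Series(["s%d" % (i % 4) for i in range(len(Y))])
        bp = fit_backbone(Y, X, C, cfg=cfg, latent=True, site_of_sample=sites)
        assert bp.n_draws == 2 * cfg.draws_per_chain
        assert bp.B.shape == (bp.n_draws, 3, 8)
        assert bp.eta_site.shape == (bp.n_draws, 4, 2)
        assert ((bp.rho >= 0) & (bp.rho <= 1)).all()
        # V draws are symmetric positive definite
        for Vd in bp.V[::7]:
            assert np.allclose(Vd, Vd.T)
            assert np.linalg.eigvalsh(Vd).min() > 0

    def test_too_few_sites_for_factors(self):
        Y, X, C, _ = _small_dataset()
        cfg = BackboneConfig(chains=1, iterations=10, burn_in=5, thin=1,
                             n_factors_site=10, n_factors_sample=1)
        sites = pd.Series(["s%d" % (i % 3) for i in range(len(Y))])
        with pytest.raises(ValueError, match="site"):
            fit_backbone(Y, X, C, cfg=cfg, latent=True, site_of_sample=sites)

    def test_prior_chain_recovers_uniform_rho(self):
        # likelihood off (zero samples): the chain must sample the prior,
        # whose rho marginal is uniform on the grid
        Y = pd.DataFrame(np.empty((0, 3), dtype=int), columns=["s1", "s2", "s3"])
        X = pd.DataFrame(np.empty((0, 2)), columns=["intercept", "a"])
        rng = np.random.default_rng(0)
        tax = random_taxonomy(rng, 3)
        C = build_taxonomic_correlation(tax)
        C.index = C.columns = ["s1", "s2", "s3"]
        cfg = BackboneConfig(chains=1, iterations=10_500, burn_in=500, thin=1,
                             rho_grid_size=21, seed=4)
        bp = fit_backbone(Y, X, C, cfg=cfg, latent=False)
        counts = np.bincount((bp.rho * 20).round().astype(int), minlength=21)
        assert chisquare(counts).pvalue > 0.01

    def test_identity_correlation_leaves_rho_at_prior(self):
        Y, X, _, _ = _small_dataset(n=80)
        cfg = BackboneConfig(chains=1, iterations=600, burn_in=100, thin=1, seed=2)
        bp = fit_backbone(Y, X, None, cfg=cfg, latent=False)
        # with C = I the conditional is flat: draws are iid uniform on the grid
        assert abs(bp.rho.mean() - 0.5) < 0.06
        assert abs(bp.rho.var() - 1 / 12) < 0.02

    def test_single_species_matches_independent_probit(self):
        # strong data: hyperpriors wash out and the backbone reduces to a
        # single-species probit regression
        rng = np.random.default_rng(1)
        n = 600
        X = pd.DataFrame(
            np.column_stack([np.ones(n), rng.normal(size=(n, 1))]), columns=["intercept", "a"]
        )
        beta = np.array([-0.4, 0.9])
        y = (rng.random(n) < ndtr(X.to_numpy() @ beta)).astype(int)
        Y = pd.DataFrame({"sp": y})
        cfg = BackboneConfig(chains=2, iterations=1500, burn_in=500, thin=2, seed=3)
        bp = fit_backbone(Y, X, None, cfg=cfg, latent=False)
        bb_mean = bp.B.mean(axis=0)[:, 0]
        draws = coral.probit_gibbs(
            y, X.to_numpy(), np.zeros(2), np.diag([10.0, 1.0]),
            coral.ProbitFitConfig(n_samples=4000, burn_in=1000, seed=5),
        )
        assert np.allclose(bb_mean, draws.mean(axis=0), atol=0.08)


class TestLatentPointEstimates:
    def _bp(self, eta_site, eta_sample=None):
        D, n_sites, q1 = eta_site.shape
        cfg = BackboneConfig(chains=1, iterations=2, burn_in=1, thin=1)
        return BackbonePosterior(
            B=np.zeros((D, 1, 1)), Gamma=np.zeros((D, 1, 1)), V=np.ones((D, 1, 1)),
            rho=np.zeros(D), species_ids=["sp"], design_columns=["intercept"],
            config=cfg, eta_site=eta_site,
            eta_sample=eta_sample,
            site_ids=[f"s{i}" for i in range(n_sites)],
        )

    def test_single_draw_is_identity(self, rng):
        eta = rng.normal(size=(1, 5, 2))
        site_est, _ = extract_latent_point_estimates(self._bp(eta))
        assert np.allclose(site_est.to_numpy(), eta[0])

    def test_sign_flip_does_not_cancel(self, rng):
        base = rng.normal(size=(5, 2))
        draws = np.stack([base, -base])
        est = _sign_align_mean(draws)
        assert np.allclose(np.abs(est), np.abs(base))

    def test_procrustes_undoes_rotation_drift(self, rng):
        from coral.backbone import _procrustes_align_mean
        from scipy.stats import ortho_group

        base = rng.normal(size=(20, 3))
        R = ortho_group.rvs(3, random_state=0)
        draws = np.stack([base, base @ R, base @ R.T])
        est = _procrustes_align_mean(draws)
        # a naive average would shrink; aligned average preserves the block
        assert np.linalg.norm(est) > 0.98 * np.linalg.norm(base)
        # and spans the same subspace as the reference draw
        proj = base @ np.linalg.lstsq(base, est, rcond=None)[0]
        assert np.allclose(proj, est, atol=1e-8)

    def test_zero_factor_stays_zero(self, rng):
        draws = rng.normal(size=(4, 6, 2))
        draws[:, :, 1] = 0.0
        est = _sign_align_mean(draws)
        assert np.allclose(est[:, 1], 0.0)

    def test_site_broadcast_to_samples(self, rng):
        eta = rng.normal(size=(3, 2, 1))
        bp = self._bp(eta)
        sites = pd.Series(["s0", "s1", "s0"], index=["a", "b", "c"])
        site_est, _ = extract_latent_point_estimates(bp, sites)
        assert len(site_est) == 3
        assert np.allclose(site_est.iloc[0], site_est.iloc[2])


class TestSerialization:
    def test_hdf5_round_trip(self, tmp_path):
        Y, X, C, _ = _small_dataset()
        cfg = BackboneConfig(chains=1, iterations=30, burn_in=10, thin=2, seed=0,
                             n_factors_site=2, n_factors_sample=1)
        sites = pd.Series(["s%d" % (i % 4) for i in range(len(Y))])
        bp = fit_backbone(Y, X, C, cfg=cfg, latent=True, site_of_sample=sites)
        path = tmp_path / "bp.h5"
        bp.to_hdf5(path)
        bp2 = BackbonePosterior.from_hdf5(path)
        assert np.array_equal(bp.B, bp2.B)
        assert np.array_equal(bp.eta_sample, bp2.eta_sample)
        assert bp2.species_ids == [str(s) for s in bp.species_ids]
        assert bp2.config == bp.config
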