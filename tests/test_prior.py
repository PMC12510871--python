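import numpy as np
import pandas as pd
import pytest

from coral.backbone import BackbonePosterior, BackboneConfig
from coral.prior import (
    CoralPrior,
    build_priors,
    conditional_prior_one_draw,
    moment_match,
)
from conftest import random_taxonomy
from coral.data import build_taxonomic_correlation


def brute_force_conditional(B, Gamma, V, rho, C, c_r, t_r, T):
    """Oracle: dense joint Gaussian over [beta_r; vec(B)], conditioned on vec(B).

    The joint prior covariance is P_full (x) V where P_full extends P with
    the rare species (unit self-correlation, cross-correlations rho*c_r);
    vec stacks per-species coefficient blocks.
    """
    p, n_s = B.shape
    P = rho * C + (1 - rho) * np.eye(n_s)
    P_full = np.block([[np.ones((1, 1)), rho * c_r[None, :]], [rho * c_r[:, None], P]])
    cov = np.kron(P_full, V)
    mu_r = Gamma @ t_r
    mu_B = (Gamma @ T.T).T.reshape(-1)  # species-blocks of Gamma t_j
    obs = B.T.reshape(-1)
    S11 = cov[:p, :p]
    S12 = cov[:p, p:]
    S22 = cov[p:, p:]
    sol = np.linalg.solve(S22, obs - mu_B)
    m = mu_r + S12 @ sol
    S = S11 - S12 @ np.linalg.solve(S22, S12.T)
    return m, S


def _random_instance(rng, n_s, p, n_t=1):
    tax = random_taxonomy(rng, n_s + 1)
    C_full = build_taxonomic_correlation(tax).to_numpy()
    C = C_full[1:, 1:]
    c_r = C_full[0, 1:]
    A = rng.normal(size=(p, p))
    V = A @ A.T + p * np.eye(p)
    Gamma = rng.normal(size=(p, n_t))
    T = np.ones((n_s, n_t)) if n_t == 1 else rng.normal(size=(n_s, n_t))
    B = rng.normal(size=(p, n_s))
    rho = rng.uniform(0, 1)
    t_r = np.ones(n_t)
    return dict(B=B, Gamma=Gamma, V=V, rho=rho), C, c_r, t_r, T


class TestConditionalPrior:
    def test_rho_zero_gives_trait_mean_and_k_one(self, rng):
        draw, C, c_r, t_r, T = _random_instance(rng, 3, 2)
        draw["rho"] = 0.0
        for mode in ("paper", "exact"):
            m, S = conditional_prior_one_draw(draw, c_r, t_r, C=C, T=T, mode=mode)
            assert np.allclose(m, draw["Gamma"] @ t_r)
            assert np.allclose(S, draw["V"])  # k = 1

    def test_single_species_hand_computation(self):
        # n_s=1, p=1, V=1, Gamma t_r = 0, rho=1, c=0.5, (beta - mu) = 2:
        # m = 1*0.5*1*2 = 1.0 and k = 1 - 0.25 = 0.75 in both modes
        draw = dict(B=np.array([[2.0]]), Gamma=np.array([[0.0]]), V=np.array([[1.0]]), rho=1.0)
        for mode in ("paper", "exact"):
            m, S = conditional_prior_one_draw(
                draw, np.array([0.5]), np.array([1.0]), C=np.eye(1), mode=mode
            )
            assert m[0] == pytest.approx(1.0)
            assert S[0, 0] == pytest.approx(0.75)

    def test_modes_differ_by_rho_power(self, rng):
        draw, C, c_r, t_r, T = _random_instance(rng, 4, 2)
        rho = draw["rho"]
        _, S_paper = conditional_prior_one_draw(draw, c_r, t_r, C=C, T=T, mode="paper")
        _, S_exact = conditional_prior_one_draw(draw, c_r, t_r, C=C, T=T, mode="exact")
        P = rho * C + (1 - rho) * np.eye(4)
        q = c_r @ np.linalg.solve(P, c_r)
        assert S_paper[0, 0] / draw["V"][0, 0] == pytest.approx(1 - rho * q)
        assert S_exact[0, 0] / draw["V"][0, 0] == pytest.approx(1 - rho**2 * q)

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_mode_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n_s = int(rng.integers(1, 5))
        p = int(rng.integers(1, 4))
        draw, C, c_r, t_r, T = _random_instance(rng, n_s, p)
        m, S = conditional_prior_one_draw(draw, c_r, t_r, C=C, T=T, mode="exact")
        m_o, S_o = brute_force_conditional(
            draw["B"], draw["Gamma"], draw["V"], draw["rho"], C, c_r, t_r, T
        )
        assert np.allclose(m, m_o, atol=1e-10)
        assert np.allclose(S, S_o, atol=1e-10)

    def test_k_in_unit_interval_for_valid_taxonomy(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            draw, C, c_r, t_r, T = _random_instance(rng, int(rng.integers(2, 6)), 1)
            for mode in ("paper", "exact"):
                _, S = conditional_prior_one_draw(draw, c_r, t_r, C=C, T=T, mode=mode)
                k = S[0, 0] / draw["V"][0, 0]
                assert 0.0 < k <= 1.0 + 1e-12


class TestMomentMatch:
    def test_single_draw_identity(self, rng):
        m = rng.normal(size=3)
        S = np.eye(3)
        mm, SS = moment_match([(m, S)])
        assert np.allclose(mm, m) and np.allclose(SS, S)

    def test_two_point_mixture_closed_form(self):
        a = np.array([1.0, -2.0])
        S = np.diag([0.5, 2.0])
        mm, SS = moment_match([(a, S), (-a, S)])
        assert np.allclose(mm, 0.0)
        assert np.allclose(SS, S + np.outer(a, a))

    def test_matches_monte_carlo_mixture(self):
        rng = np.random.default_rng(0)
        p = 3
        comps = []
        for _ in range(4):
            m = rng.normal(size=p)
            A = rng.normal(size=(p, p))
            comps.append((m, A @ A.T + np.eye(p)))
        mm, SS = moment_match(comps)
        n = 100_000
        samples = np.concatenate(
            [rng.multivariate_normal(m, S, size=n // 4) for m, S in comps]
        )
        mc_mean, mc_cov = samples.mean(axis=0), np.cov(samples.T, ddof=0)
        assert np.allclose(mm, mc_mean, atol=0.05)
        assert np.allclose(SS, mc_cov, rtol=0.05, atol=0.05)

    def test_dispersion_term_is_psd(self, rng):
        comps = [(rng.normal(size=4), np.eye(4)) for _ in range(20)]
        _, SS = moment_match(comps)
        gap = SS - np.mean([S for _, S in comps], axis=0)
        assert np.linalg.eigvalsh(gap).min() >= -1e-10


def _posterior_from_draws(draws, tax, species_ids, columns):
    cfg = BackboneConfig(chains=1, iterations=2, burn_in=1, thin=1)
    return BackbonePosterior(
        B=np.stack([d["B"] for d in draws]),
        Gamma=np.stack([d["Gamma"] for d in draws]),
        V=np.stack([d["V"] for d in draws]),
        rho=np.array([d["rho"] for d in draws]),
        species_ids=species_ids,
        design_columns=columns,
        config=cfg,
        trait_matrix=np.ones((len(species_ids), 1)),
    )


class TestBuildPriors:
    def _taxonomy_with_relatives(self):
        ranks = [
            "kingdom", "phylum", "class", "order", "family",
            "subfamily", "tribe", "genus", "species",
        ]
        rows = {
            "bb1": ["k1", "p1", "c1", "o1", "f1", "sf1", "t1", "g1", "s1"],
            "bb2": ["k1", "p1", "c2", "o2", "f2", "sf2", "t2", "g2", "s2"],
            "close": ["k1", "p1", "c1", "o1", "f1", "sf1", "t1", "g1", "sX"],
            "far": ["k1", "p9", "c9", "o9", "f9", "sf9", "t9", "g9", "sY"],
            "alien": ["k9", "p8", "c8", "o8", "f8", "sf8", "t8", "g8", "sZ"],
        }
        from coral.data import TaxonomyTable

        table = pd.DataFrame.from_dict(rows, orient="index", columns=ranks)
        return TaxonomyTable(table)

    def _backbone(self, rho=0.9, n_draws=5, seed=0):
        rng = np.random.default_rng(seed)
        draws = []
        for _ in range(n_draws):
            draws.append(
                dict(
                    B=rng.normal(size=(2, 2)),
                    Gamma=rng.normal(size=(2, 1)),
                    V=np.diag([1.0, 0.5]),
                    rho=rho,
                )
            )
        return _posterior_from_draws(draws, None, ["bb1", "bb2"], ["intercept", "x"])

    def test_k_smaller_for_closer_relatives(self):
        tax = self._taxonomy_with_relatives()
        priors = build_priors(self._backbone(), tax, ["close", "far"])
        assert priors["close"].k_mean < priors["far"].k_mean
        assert priors["close"].relatedness_rank == "genus"
        assert priors["far"].relatedness_rank == "kingdom"

    def test_unrelated_species_gets_marginal_prior(self):
        tax = self._taxonomy_with_relatives()
        bp = self._backbone(n_draws=8)
        priors = build_priors(bp, tax, ["alien"])
        pr = priors["alien"]
        assert pr.k_mean == pytest.approx(1.0)
        assert pr.relatedness_depth == 0
        gt = bp.Gamma[:, :, 0]  # (D, p) trait means per draw
        expect_m = gt.mean(axis=0)
        dev = gt - expect_m
        expect_S = bp.V.mean(axis=0) + dev.T @ dev / len(gt)
        assert np.allclose(pr.m, expect_m)
        assert np.allclose(pr.S, expect_S)

    def test_agrees_with_per_draw_reference(self):
        tax = self._taxonomy_with_relatives()
        bp = self._backbone(n_draws=6, rho=0.7)
        C = build_taxonomic_correlation(tax, ["bb1", "bb2"]).to_numpy()
        c_close = build_taxonomic_correlation(tax, ["close", "bb1", "bb2"]).to_numpy()[0, 1:]
        ref_draws = []
        for d in range(bp.n_draws):
            draw = dict(B=bp.B[d], Gamma=bp.Gamma[d], V=bp.V[d], rho=bp.rho[d])
            ref_draws.append(conditional_prior_one_draw(draw, c_close, C=C, mode="exact"))
        m_ref, S_ref = moment_match(ref_draws)
        pr = build_priors(bp, tax, ["close"])["close"]
        assert np.allclose(pr.m, m_ref, atol=1e-10)
        assert np.allclose(pr.S, S_ref, atol=1e-10)

    def test_missing_taxonomy_raises(self):
        tax = self._taxonomy_with_relatives()
        with pytest.raises(ValueError, match="ghost"):
            build_priors(self._backbone(), tax, ["ghost"])

    def test_prior_covariance_positive_definite(self):
        tax = self._taxonomy_with_relatives()
        priors = build_priors(self._backbone(n_draws=10), tax, ["close", "far", "alien"])
        for pr in priors.values():
            assert np.linalg.eigvalsh(pr.S).min() > 0
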