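"""Single-species Bayesian probit regression via data augmentation.

Each species is modeled as Pr(y_i = 1) = Phi(x_i' beta) with a Gaussian
prior beta ~ N(m0, S0).  The Gibbs sampler alternates truncated-normal
draws of the latent liabilities z_i with the conjugate multivariate-normal
draw of beta.  Three model kinds share this machinery: the transfer-learning
fit (expanded design, informative conditional prior), the baseline
(measured covariates, default diagonal prior) and the ablation (expanded
design, default prior).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import zlib

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.special import ndtr, ndtri
from sklearn.base import BaseEstimator, ClassifierMixin

_TINY = 1e-300


@dataclass
class ProbitFitConfig:
    """MCMC settings for the per-species probit fits."""

    n_samples: int = 5000
    burn_in: int = 2500
    seed: int = 0
    model_kind: str = "coral"

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.model_kind not in ("coral", "baseline", "ablation"):
            raise ValueError(f"unknown model_kind {self.model_kind!r}")


@dataclass
class SpeciesPosteriorSummary:
    """Gaussian summary N(mu, Sigma) of one species' coefficient posterior.

    For a q-column design this stores q + q(q+1)/2 numbers (Sigma is
    symmetric), e.g. 350 for the 25-column expanded design.
    """

    species_id: str
    mu: np.ndarray
    Sigma: np.ndarray
    model_kind: str
    columns: list[str] = field(default_factory=list)

    @property
    def n_parameters(self) -> int:
        q = len(self.mu)
        return q + q * (q + 1) // 2


def sample_truncnorm_liabilities(mean: np.ndarray, y: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Inverse-CDF draws of z ~ N(mean, 1) truncated to z>0 where y=1, z<0 where y=0.

    Uses the tail-stable forms z = mean - ndtri((1-u) * Phi(mean)) for the
    positive side and z = mean + ndtri(u * Phi(-mean)) for the negative
    side, which stay accurate for extreme linear predictors.
    """
    pos = y.astype(bool)
    z = np.empty_like(mean)
    arg_pos = np.maximum((1.0 - u[pos]) * ndtr(mean[pos]), _TINY)
    z[pos] = mean[pos] - ndtri(arg_pos)
    arg_neg = np.maximum(u[~pos] * ndtr(-mean[~pos]), _TINY)
    z[~pos] = mean[~pos] + ndtri(arg_neg)
    return z


def probit_gibbs(
    y: np.ndarray,
    X: np.ndarray,
    prior_mean: np.ndarray,
    prior_cov: np.ndarray,
    cfg: ProbitFitConfig | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Posterior draws of beta for one species; returns (n_samples, p).

    With zero data rows the sampler falls back to exact prior draws, so the
    no-data limit recovers the prior.
    """
    cfg = cfg or ProbitFitConfig()
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("rows of X must match y")
    if n and not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("y must be binary 0/1")
    prior_mean = np.asarray(prior_mean, dtype=float).reshape(p)
    prior_cov = np.asarray(prior_cov, dtype=float).reshape(p, p)
    try:
        S0_chol = cho_factor(prior_cov, lower=True)
    except np.linalg.LinAlgError as e:
        raise ValueError("prior covariance must be positive definite") from e
    S0_inv = cho_solve(S0_chol, np.eye(p))
    S0_inv_m0 = S0_inv @ prior_mean

    if n == 0:
        L0 = cholesky(prior_cov, lower=True)
        eps = rng.standard_normal((cfg.n_samples, p))
        return prior_mean + eps @ L0.T

    Q = S0_inv + X.T @ X
    A_chol = cho_factor(Q, lower=True)
    A = cho_solve(A_chol, np.eye(p))
    A = 0.5 * (A + A.T)
    L_A = cholesky(A, lower=True)

    beta = prior_mean.copy()
    total = cfg.burn_in + cfg.n_samples
    draws = np.empty((cfg.n_samples, p))
    for it in range(total):
        mean = X @ beta
        u = rng.random(n)
        z = sample_truncnorm_liabilities(mean, y, u)
        rhs = S0_inv_m0 + X.T @ z
        beta = A @ rhs + L_A @ rng.standard_normal(p)
        if it >= cfg.burn_in:
            draws[it - cfg.burn_in] = beta
    return draws


def default_prior(columns: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Default diagonal prior: N(0, 10) for the intercept, N(0, 1) otherwise.

    Variances, not standard deviations.
    """
    var = np.array([10.0 if c == "intercept" else 1.0 for c in columns])
    return np.zeros(len(columns)), np.diag(var)


def species_seed(global_seed: int, species_id: str) -> int:
    """Stable per-species seed (< 2^31), independent of scheduling order."""
    h = zlib.crc32(str(species_id).encode("utf-8"))
    return (int(global_seed) * 1000003 + h) % (2**31 - 1)


def summarize_draws(
    draws: np.ndarray, species_id: str, model_kind: str, columns: list[str]
) -> SpeciesPosteriorSummary:
    mu = draws.mean(axis=0)
    d = draws - mu
    Sigma = d.T @ d / draws.shape[0]
    Sigma = 0.5 * (Sigma + Sigma.T)
    return SpeciesPosteriorSummary(
        species_id=str(species_id), mu=mu, Sigma=Sigma, model_kind=model_kind, columns=list(columns)
    )


def fit_species(
    y: np.ndarray,
    X: pd.DataFrame | np.ndarray,
    cfg: ProbitFitConfig,
    prior_mean: np.ndarray | None = None,
    prior_cov: np.ndarray | None = None,
    species_id: str = "species",
    seed: int | None = None,
) -> SpeciesPosteriorSummary:
    """Fit one species and summarize the posterior as a Gaussian.

    For the transfer-learning model kind the informative prior must be
    supplied; baseline/ablation fall back to the default diagonal prior
    when none is given.
    """
    columns = list(X.columns) if isinstance(X, pd.DataFrame) else [f"x{k}" for k in range(X.shape[1])]
    if prior_mean is None or prior_cov is None:
        if cfg.model_kind == "coral":
            raise ValueError(f"missing informative prior for species {species_id!r}")
        prior_mean, prior_cov = default_prior(columns)
    Xv = X.to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    draws = probit_gibbs(y, Xv, prior_mean, prior_cov, cfg, rng)
    return summarize_draws(draws, species_id, cfg.model_kind, columns)


def fit_all_rare(
    Y: pd.DataFrame,
    X: pd.DataFrame,
    priors: dict | None,
    cfg: ProbitFitConfig,
    n_jobs: int = 1,
) -> dict[str, SpeciesPosteriorSummary]:
    """Independent per-species fits with schedule-independent reproducibility.

    Each species gets a deterministic seed derived from (cfg.seed, species
    id), so results are identical for any worker count.  Per-species
    failures are logged and skipped rather than aborting the batch.
    """
    import logging

    log = logging.getLogger(__name__)

    def _one(sp):
        try:
            pm, pc = (None, None)
            if priors is not None and sp in priors:
                pm, pc = priors[sp]
            return sp, fit_species(
                Y[sp].to_numpy(),
                X,
                cfg,
                prior_mean=pm,
                prior_cov=pc,
                species_id=sp,
                seed=species_seed(cfg.seed, sp),
            )
        except Exception as e:  # noqa: BLE001 - batch must survive bad species
            log.warning("species %r failed: %s", sp, e)
            return sp, None

    results = Parallel(n_jobs=n_jobs)(delayed(_one)(sp) for sp in Y.columns)
    return {sp: s for sp, s in results if s is not None}


class BayesianProbitClassifier(ClassifierMixin, BaseEstimator):
    """scikit-learn estimator interface to the Bayesian probit model.

    Parameters
    ----------
    prior_mean, prior_cov : optional arrays defining the Gaussian prior on
        the coefficients; defaults to N(0, 10) for the first column when
        ``first_column_is_intercept`` and N(0, 1) otherwise.
    n_samples, burn_in : Gibbs sampler length.
    random_state : seed.

    After ``fit`` the Gaussian posterior summary is available as
    ``posterior_mean_`` and ``posterior_cov_``; ``predict_proba`` uses the
    analytic probit-Gaussian identity
    Phi(x'mu / sqrt(1 + x'Sigma x)) rather than Monte Carlo.
    """

    def __init__(
        self,
        prior_mean=None,
        prior_cov=None,
        n_samples: int = 5000,
        burn_in: int = 2500,
        first_column_is_intercept: bool = True,
        random_state: int = 0,
    ):
        self.prior_mean = prior_mean
        self.prior_cov = prior_cov
        self.n_samples = n_samples
        self.burn_in = burn_in
        self.first_column_is_intercept = first_column_is_intercept
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        self.classes_ = np.unique(np.concatenate([y, [0, 1]])) if y.size else np.array([0, 1])
        if not np.isin(y, (0, 1)).all():
            raise ValueError("y must be binary 0/1")
        p = X.shape[1]
        if self.prior_mean is None or self.prior_cov is None:
            cols = ["intercept" if (k == 0 and self.first_column_is_intercept) else f"x{k}" for k in range(p)]
            m0, S0 = default_prior(cols)
        else:
            m0 = np.asarray(self.prior_mean, dtype=float)
            S0 = np.asarray(self.prior_cov, dtype=float)
        cfg = ProbitFitConfig(
            n_samples=self.n_samples, burn_in=self.burn_in, seed=self.random_state,
            model_kind="baseline",
        )
        draws = probit_gibbs(y, X, m0, S0, cfg, np.random.default_rng(self.random_state))
        summ = summarize_draws(draws, "estimator", "baseline", [f"x{k}" for k in range(p)])
        self.posterior_mean_ = summ.mu
        self.posterior_cov_ = summ.Sigma
        self.n_features_in_ = p
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        lin = X @ self.posterior_mean_
        s = 1.0 + np.einsum("ip,pq,iq->i", X, self.posterior_cov_, X)
        p1 = ndtr(lin / np.sqrt(s))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)
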