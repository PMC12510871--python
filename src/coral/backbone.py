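"""Latent-factor multivariate probit model for the common-species backbone.

The model is Pr(y_ij = 1) = Phi(L_ij) with linear predictor
L_ij = sum_k x_ik beta_kj + sum_k eta_ik lambda_kj, a coefficient prior
vec(B) ~ N(vec(Gamma T'), P (x) V) with P = rho C + (1 - rho) I, and
site- plus sample-level latent factors with multiplicative-gamma shrinkage
on the loadings.  Inference is blocked Gibbs:

* liabilities z_ij from truncated normals (sign tied to y_ij);
* B from its matrix-normal conditional — after rotating species into the
  eigenbasis of C the update factorizes into independent p x p solves,
  which is exactly the dense Kronecker-structured conditional (checked
  against a brute-force oracle in the tests);
* Gamma, V (inverse-Wishart) and rho (discrete grid) from their
  conjugate/exact conditionals;
* latent factors (site factors conditioned on all samples at the site) and
  loadings from conditional normals, with global multiplicative-gamma
  shrinkage updates.

Fitting with a zero-row Y runs the same chain with the likelihood absent,
i.e. samples the prior — useful for prior-predictive validation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, cho_factor, cho_solve, solve_triangular
from scipy.stats import invwishart
from sklearn.base import BaseEstimator

from .probit import sample_truncnorm_liabilities


@dataclass
class BackboneConfig:
    """Sampler settings; defaults are desk-scale (4 x 3,750, burn 1,250, thin 10)."""

    n_factors_site: int = 10
    n_factors_sample: int = 4
    rho_grid_size: int = 101
    chains: int = 4
    iterations: int = 3750
    burn_in: int = 1250
    thin: int = 10
    seed: int = 0
    gamma_prior_var: float = 10.0
    v0_df: int | None = None  # default p + 2 (prior mean of V = v0_scale)
    shrinkage_a1: float = 2.0
    shrinkage_a2: float = 3.0

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be < iterations")
        if self.rho_grid_size < 2:
            raise ValueError("rho grid must include 0 and 1")

    @property
    def rho_grid(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.rho_grid_size)

    @property
    def draws_per_chain(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


@dataclass
class BackbonePosterior:
    """MCMC draws from the backbone model, draw axis first."""

    B: np.ndarray  # (D, p, n_s)
    Gamma: np.ndarray  # (D, p, n_t)
    V: np.ndarray  # (D, p, p)
    rho: np.ndarray  # (D,)
    species_ids: list
    design_columns: list
    config: BackboneConfig
    eta_site: np.ndarray | None = None  # (D, n_sites, q1)
    eta_sample: np.ndarray | None = None  # (D, n_y, q2)
    lambda_site: np.ndarray | None = None  # (D, q1, n_s)
    lambda_sample: np.ndarray | None = None  # (D, q2, n_s)
    site_ids: list = field(default_factory=list)
    trait_matrix: np.ndarray | None = None  # (n_s, n_t)

    @property
    def n_draws(self) -> int:
        return self.B.shape[0]

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            for name in ("B", "Gamma", "V", "rho"):
                f.create_dataset(name, data=getattr(self, name))
            for name in ("eta_site", "eta_sample", "lambda_site", "lambda_sample", "trait_matrix"):
                arr = getattr(self, name)
                if arr is not None:
                    f.create_dataset(name, data=arr)
            f.attrs["species_ids"] = json.dumps([str(s) for s in self.species_ids])
            f.attrs["design_columns"] = json.dumps(list(self.design_columns))
            f.attrs["site_ids"] = json.dumps([str(s) for s in self.site_ids])
            f.attrs["config"] = json.dumps(asdict(self.config))

    @classmethod
    def from_hdf5(cls, path) -> "BackbonePosterior":
        import h5py

        with h5py.File(path, "r") as f:
            kw = {n: f[n][...] for n in ("B", "Gamma", "V", "rho")}
            for n in ("eta_site", "eta_sample", "lambda_site", "lambda_sample", "trait_matrix"):
                kw[n] = f[n][...] if n in f else None
            return cls(
                species_ids=json.loads(f.attrs["species_ids"]),
                design_columns=json.loads(f.attrs["design_columns"]),
                site_ids=json.loads(f.attrs["site_ids"]),
                config=BackboneConfig(**json.loads(f.attrs["config"])),
                **kw,
            )


def _prepare_correlation(C: np.ndarray, n_s: int):
    """Eigendecompose C, clipping tiny negative eigenvalues (jitter <= 1e-8)."""
    if C is None:
        return np.ones(n_s), np.eye(n_s)
    C = np.asarray(C, dtype=float)
    evals, evecs = np.linalg.eigh(0.5 * (C + C.T))
    if evals.min() < -1e-8:
        raise ValueError("taxonomic correlation matrix is not positive semi-definite")
    return np.clip(evals, 1e-10, None), evecs


def _b_update_terms(XtX, V_inv, d, M0t, XtZt):
    """Per-rotated-species precision and right-hand side of the B conditional."""
    Q = XtX[None, :, :] + V_inv[None, :, :] / d[:, None, None]
    rhs = (V_inv @ M0t) / d[None, :] + XtZt
    return Q, rhs


def coefficient_conditional_moments(Zb, X, C, V, M0, rho):
    """Exact conditional mean and covariance of vec(B) given liabilities.

    vec stacks per-species coefficient blocks (species as the Kronecker
    left factor).  This assembles the sampler's eigen-rotated update into
    dense form; the tests verify it against brute-force multivariate-normal
    conditioning.  Only sensible for small problems.
    """
    X = np.asarray(X, dtype=float)
    n_s = M0.shape[1]
    p = X.shape[1]
    evals, U = _prepare_correlation(None if C is None else np.asarray(C, dtype=float), n_s)
    d = rho * evals + (1.0 - rho)
    V_inv = np.linalg.inv(V)
    XtX = X.T @ X
    Q, rhs = _b_update_terms(XtX, V_inv, d, M0 @ U, X.T @ (np.asarray(Zb) @ U))
    mean_rot = np.linalg.solve(Q, rhs.T[:, :, None])[:, :, 0]  # (n_s, p)
    mean = (mean_rot.T @ U.T).flatten(order="F")
    cov_blocks = np.linalg.inv(Q)  # (n_s, p, p) in rotated basis
    K = np.kron(U, np.eye(p))
    cov = K @ (np.einsum("jk,jpq->jpkq", np.eye(n_s), cov_blocks).reshape(n_s * p, n_s * p)) @ K.T
    return mean, cov


def _mgp_taus(deltas: np.ndarray) -> np.ndarray:
    return np.cumprod(deltas)


def _update_mgp(deltas, Lam, a1, a2, rng):
    """Global multiplicative-gamma shrinkage update for one loading block."""
    q, n_s = Lam.shape
    ssq = (Lam**2).sum(axis=1)  # per factor
    for l in range(q):
        taus = _mgp_taus(deltas)
        shape = (a1 if l == 0 else a2) + 0.5 * n_s * (q - l)
        rate = 1.0 + 0.5 * np.sum(taus[l:] / deltas[l] * ssq[l:])
        deltas[l] = rng.gamma(shape, 1.0 / rate)
    return deltas


def _run_chain(
    Y, X, evals_C, evecs_C, T, cfg: BackboneConfig, latent: bool, site_idx, n_sites, rng
):
    n, p = X.shape
    n_s = T.shape[0]
    n_t = T.shape[1]
    q1 = cfg.n_factors_site if latent else 0
    q2 = cfg.n_factors_sample if latent else 0
    grid = cfg.rho_grid
    XtX = X.T @ X
    U = evecs_C
    v0_df = cfg.v0_df if cfg.v0_df is not None else p + 2
    v0_scale = np.eye(p)

    # state
    V = np.eye(p)
    Gamma = np.zeros((p, n_t))
    rho = 0.0
    B = Gamma @ T.T + 0.01 * rng.standard_normal((p, n_s))
    eta_site = 0.1 * rng.standard_normal((n_sites, q1)) if q1 else None
    eta_sample = 0.1 * rng.standard_normal((n, q2)) if q2 else None
    Lam_site = np.zeros((q1, n_s))
    Lam_sample = np.zeros((q2, n_s))
    d_site = np.ones(q1)
    d_sample = np.ones(q2)

    n_keep = cfg.draws_per_chain
    out = {
        "B": np.empty((n_keep, p, n_s)),
        "Gamma": np.empty((n_keep, p, n_t)),
        "V": np.empty((n_keep, p, p)),
        "rho": np.empty(n_keep),
    }
    if latent:
        out["eta_site"] = np.empty((n_keep, n_sites, q1))
        out["eta_sample"] = np.empty((n_keep, n, q2))
        out["lambda_site"] = np.empty((n_keep, q1, n_s))
        out["lambda_sample"] = np.empty((n_keep, q2, n_s))

    kept = 0
    for it in range(cfg.iterations):
        if n > 0:
            latent_part = 0.0
            if q1:
                latent_part = eta_site[site_idx] @ Lam_site
            if q2:
                latent_part = latent_part + eta_sample @ Lam_sample
            L_lin = X @ B + latent_part
            z = sample_truncnorm_liabilities(L_lin, Y, rng.random((n, n_s)))
            Zb = z - latent_part
        else:
            Zb = np.zeros((0, n_s))

        # --- B | rest: rotate species into eigenbasis of C
        V_chol = cho_factor(V, lower=True)
        V_inv = cho_solve(V_chol, np.eye(p))
        d = rho * evals_C + (1.0 - rho)
        M0 = Gamma @ T.T
        Zt = Zb @ U
        M0t = M0 @ U
        Q, rhs = _b_update_terms(XtX, V_inv, d, M0t, X.T @ Zt)  # (n_s,p,p), (p,n_s)
        Lq = np.linalg.cholesky(Q)
        mean = np.linalg.solve(Q, rhs.T[:, :, None])[:, :, 0]  # (n_s, p)
        eps = rng.standard_normal((n_s, p, 1))
        noise = np.linalg.solve(np.swapaxes(Lq, 1, 2), eps)[:, :, 0]
        Bt = (mean + noise).T  # (p, n_s)
        B = Bt @ U.T

        # --- Gamma | rest (prior N(0, gamma_prior_var I))
        Pinv_T = U @ ((U.T @ T) / d[:, None])  # P^-1 T, (n_s, n_t)
        A_g = T.T @ Pinv_T  # (n_t, n_t)
        Q_g = np.kron(A_g, V_inv) + np.eye(p * n_t) / cfg.gamma_prior_var
        rhs_g = (V_inv @ B @ Pinv_T).flatten(order="F")
        Lg = cholesky(Q_g, lower=True)
        mean_g = cho_solve((Lg, True), rhs_g)
        gdraw = mean_g + solve_triangular(Lg.T, rng.standard_normal(p * n_t), lower=False)
        Gamma = gdraw.reshape((p, n_t), order="F")

        # --- V | rest: inverse-Wishart
        E = B - Gamma @ T.T
        Et = E @ U
        S_E = (Et / d[None, :]) @ Et.T
        V = invwishart.rvs(df=v0_df + n_s, scale=v0_scale + S_E, random_state=rng)
        V = np.atleast_2d(V)
        V = 0.5 * (V + V.T)

        # --- rho | rest: exact discrete conditional on the grid
        V_inv = cho_solve(cho_factor(V, lower=True), np.eye(p))
        qs = np.einsum("pj,pq,qj->j", Et, V_inv, Et)
        D_grid = np.clip(grid[:, None] * evals_C[None, :] + (1.0 - grid[:, None]), 1e-12, None)
        logp = -0.5 * p * np.log(D_grid).sum(axis=1) - 0.5 * (qs[None, :] / D_grid).sum(axis=1)
        logp -= logp.max()
        prob = np.exp(logp)
        prob /= prob.sum()
        rho = grid[rng.choice(len(grid), p=prob)]

        # --- latent factors and loadings
        if latent and n > 0:
            R = z - X @ B
            # sample-level factors
            if q2:
                R2 = R - (eta_site[site_idx] @ Lam_site if q1 else 0.0)
                A2 = np.linalg.inv(np.eye(q2) + Lam_sample @ Lam_sample.T)
                A2 = 0.5 * (A2 + A2.T)
                mean2 = R2 @ Lam_sample.T @ A2
                eta_sample = mean2 + rng.standard_normal((n, q2)) @ cholesky(A2, lower=True).T
                eta_sample = eta_sample - eta_sample.mean(axis=0)
            # site-level factors (conditioned on all samples at the site)
            if q1:
                R1 = R - (eta_sample @ Lam_sample if q2 else 0.0)
                acc = np.zeros((n_sites, n_s))
                np.add.at(acc, site_idx, R1)
                counts = np.bincount(site_idx, minlength=n_sites).astype(float)
                LLT = Lam_site @ Lam_site.T
                Qs = np.eye(q1)[None, :, :] + counts[:, None, None] * LLT[None, :, :]
                rhs_s = acc @ Lam_site.T  # (n_sites, q1)
                mean_s = np.linalg.solve(Qs, rhs_s[:, :, None])[:, :, 0]
                Ls = np.linalg.cholesky(Qs)
                noise_s = np.linalg.solve(
                    np.swapaxes(Ls, 1, 2), rng.standard_normal((n_sites, q1, 1))
                )[:, :, 0]
                eta_site = mean_s + noise_s
                eta_site = eta_site - eta_site.mean(axis=0)
            # loadings, both blocks jointly per species (shared H across species)
            H_parts = []
            taus = []
            if q1:
                H_parts.append(eta_site[site_idx])
                taus.append(_mgp_taus(d_site))
            if q2:
                H_parts.append(eta_sample)
                taus.append(_mgp_taus(d_sample))
            H = np.hstack(H_parts)
            tau = np.concatenate(taus)
            Qh = np.diag(tau) + H.T @ H
            Lh = cholesky(Qh, lower=True)
            mean_h = cho_solve((Lh, True), H.T @ R)
            noise_h = solve_triangular(
                Lh.T, rng.standard_normal((q1 + q2, n_s)), lower=False
            )
            Lam_all = mean_h + noise_h
            Lam_site, Lam_sample = Lam_all[:q1], Lam_all[q1:]
            if q1:
                d_site = _update_mgp(d_site, Lam_site, cfg.shrinkage_a1, cfg.shrinkage_a2, rng)
            if q2:
                d_sample = _update_mgp(
                    d_sample, Lam_sample, cfg.shrinkage_a1, cfg.shrinkage_a2, rng
                )

        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0 and kept < n_keep:
            out["B"][kept] = B
            out["Gamma"][kept] = Gamma
            out["V"][kept] = V
            out["rho"][kept] = rho
            if latent:
                out["eta_site"][kept] = eta_site
                out["eta_sample"][kept] = eta_sample
                out["lambda_site"][kept] = Lam_site
                out["lambda_sample"][kept] = Lam_sample
            kept += 1
    return out


def fit_backbone(
    Y: pd.DataFrame | np.ndarray,
    X: pd.DataFrame | np.ndarray,
    C: pd.DataFrame | np.ndarray | None,
    T: np.ndarray | None = None,
    cfg: BackboneConfig | None = None,
    latent: bool = True,
    site_of_sample: pd.Series | np.ndarray | None = None,
) -> BackbonePosterior:
    """Fit the backbone model by Gibbs sampling; returns pooled chain draws.

    ``Y`` is the common-species occurrence block, ``X`` the design matrix,
    ``C`` the species correlation matrix (None = identity) and ``T`` the
    trait matrix (default intercept-only).  With ``latent`` the site- and
    sample-level factor blocks are sampled; site factors need
    ``site_of_sample`` and at least as many distinct sites as site factors.
    """
    cfg = cfg or BackboneConfig()
    species_ids = list(Y.columns) if isinstance(Y, pd.DataFrame) else [f"sp{j}" for j in range(np.asarray(Y).shape[1])]
    design_columns = list(X.columns) if isinstance(X, pd.DataFrame) else [f"x{k}" for k in range(np.asarray(X).shape[1])]
    Yv = np.asarray(Y, dtype=float)
    Xv = np.asarray(X, dtype=float)
    n, n_s = Yv.shape if Yv.ndim == 2 else (0, len(species_ids))
    Cv = None if C is None else (C.loc[species_ids, species_ids].to_numpy() if isinstance(C, pd.DataFrame) else np.asarray(C))
    evals_C, evecs_C = _prepare_correlation(Cv, n_s)
    Tm = np.ones((n_s, 1)) if T is None else np.asarray(T, dtype=float)

    site_ids: list = []
    site_idx = np.zeros(max(n, 0), dtype=int)
    n_sites = 1
    if latent:
        if site_of_sample is not None:
            codes, uniques = pd.factorize(np.asarray(site_of_sample))
            site_idx = codes
            site_ids = list(uniques)
            n_sites = len(uniques)
        else:
            n_sites = n
            site_idx = np.arange(n)
            site_ids = list(range(n))
        if cfg.n_factors_site > 0 and n_sites < cfg.n_factors_site:
            raise ValueError(
                f"{n_sites} distinct sites < {cfg.n_factors_site} site-level factors"
            )
    if n > 0 and np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        warnings.warn("design matrix is rank deficient; conditionals remain proper via the prior")

    ss = np.random.SeedSequence(cfg.seed)
    chains = [
        _run_chain(
            Yv, Xv, evals_C, evecs_C, Tm, cfg, latent and n > 0, site_idx, n_sites,
            np.random.default_rng(child),
        )
        for child in ss.spawn(cfg.chains)
    ]
    pooled = {k: np.concatenate([c[k] for c in chains], axis=0) for k in chains[0]}
    return BackbonePosterior(
        B=pooled["B"],
        Gamma=pooled["Gamma"],
        V=pooled["V"],
        rho=pooled["rho"],
        eta_site=pooled.get("eta_site"),
        eta_sample=pooled.get("eta_sample"),
        lambda_site=pooled.get("lambda_site"),
        lambda_sample=pooled.get("lambda_sample"),
        species_ids=species_ids,
        design_columns=design_columns,
        config=cfg,
        site_ids=site_ids,
        trait_matrix=Tm,
    )


def _sign_align_mean(draws: np.ndarray) -> np.ndarray:
    """Posterior mean of factor draws after per-draw sign alignment.

    draws: (D, units, q).  Each factor column of each draw is aligned (by
    sign of the inner product) to the draw in which that factor has maximal
    norm, so a factor that flips sign across draws does not average away.
    """
    D, n_units, q = draws.shape
    est = np.empty((n_units, q))
    for k in range(q):
        cols = draws[:, :, k]
        ref = cols[np.argmax(np.linalg.norm(cols, axis=1))]
        signs = np.sign(cols @ ref)
        signs[signs == 0] = 1.0
        est[:, k] = (cols * signs[:, None]).mean(axis=0)
    return est


def _procrustes_align_mean(draws: np.ndarray) -> np.ndarray:
    """Posterior mean of factor draws after per-draw orthogonal alignment.

    The factor block is identified only up to an orthogonal rotation (and
    the chains need not agree on a rotation), so each draw is rotated onto
    a reference draw — the one with the largest total norm — by the
    orthogonal Procrustes solution before averaging.  With a single factor
    this reduces to sign alignment.
    """
    D, n_units, q = draws.shape
    norms = np.linalg.norm(draws.reshape(D, -1), axis=1)
    ref = draws[int(np.argmax(norms))]
    est = np.zeros((n_units, q))
    for d in range(D):
        M = draws[d].T @ ref
        Uu, _, Vt = np.linalg.svd(M)
        est += draws[d] @ (Uu @ Vt)
    return est / D


def extract_latent_point_estimates(
    bp: BackbonePosterior,
    site_of_sample: pd.Series | np.ndarray | None = None,
    align: str = "procrustes",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Point estimates of the latent predictors, site factors broadcast to samples.

    Returns (eta_hat_site_by_sample, eta_hat_sample) as DataFrames with
    LF_site_k / LF_sample_k columns; concatenate onto the measured design
    to form the expanded covariate vector.  ``align`` chooses how draws are
    matched before averaging: "procrustes" (orthogonal rotation onto a
    reference draw; handles rotation drift across draws and chains) or
    "sign" (per-factor sign flips only).
    """
    if bp.eta_site is None and bp.eta_sample is None:
        raise ValueError("backbone posterior contains no latent factor draws")
    if align not in ("procrustes", "sign"):
        raise ValueError(f"unknown alignment {align!r}")
    _align = _procrustes_align_mean if align == "procrustes" else _sign_align_mean
    parts = []
    if bp.eta_site is not None and bp.eta_site.shape[2] > 0:
        est_site = _align(bp.eta_site)  # (n_sites, q1)
        site_df = pd.DataFrame(
            est_site,
            index=pd.Index([str(s) for s in bp.site_ids]),
            columns=[f"LF_site_{k+1}" for k in range(est_site.shape[1])],
        )
        if site_of_sample is not None:
            site_df = site_df.loc[[str(s) for s in np.asarray(site_of_sample)]]
            site_df.index = (
                site_of_sample.index
                if isinstance(site_of_sample, pd.Series)
                else pd.RangeIndex(len(site_df))
            )
        parts.append(site_df)
    if bp.eta_sample is not None and bp.eta_sample.shape[2] > 0:
        est_sample = _align(bp.eta_sample)
        parts.append(
            pd.DataFrame(
                est_sample,
                index=parts[0].index if parts else None,
                columns=[f"LF_sample_{k+1}" for k in range(est_sample.shape[1])],
            )
        )
    site_part = parts[0] if bp.eta_site is not None else pd.DataFrame()
    sample_part = parts[-1] if bp.eta_sample is not None else pd.DataFrame()
    return site_part, sample_part


def expand_design(
    X: pd.DataFrame, bp: BackbonePosterior, site_of_sample: pd.Series
) -> pd.DataFrame:
    """Concatenate the measured design with latent-factor point estimates."""
    site_part, sample_part = extract_latent_point_estimates(bp, site_of_sample)
    blocks = [X]
    if len(site_part):
        site_part.index = X.index
        blocks.append(site_part)
    if len(sample_part):
        sample_part.index = X.index
        blocks.append(sample_part)
    return pd.concat(blocks, axis=1)


def fit_stage2(
    Y: pd.DataFrame,
    Xt: pd.DataFrame,
    C,
    T=None,
    cfg: BackboneConfig | None = None,
) -> BackbonePosterior:
    """Refit the backbone with latent factors as fixed covariates (latent off).

    The resulting hyperparameter posterior over (B, Gamma, V, rho) on the
    expanded design is what the rare-species conditional priors condition
    on.
    """
    return fit_backbone(Y, Xt, C, T=T, cfg=cfg, latent=False)


class BackboneJSDM(BaseEstimator):
    """scikit-learn-style wrapper around the backbone Gibbs sampler.

    ``fit(X, Y, C=..., site_of_sample=...)`` stores the pooled posterior in
    ``posterior_``; ``transform(X)`` returns the expanded design (measured
    columns + latent point estimates) for downstream per-species models.
    """

    def __init__(
        self,
        n_factors_site: int = 10,
        n_factors_sample: int = 4,
        rho_grid_size: int = 101,
        chains: int = 4,
        iterations: int = 3750,
        burn_in: int = 1250,
        thin: int = 10,
        latent: bool = True,
        random_state: int = 0,
    ):
        self.n_factors_site = n_factors_site
        self.n_factors_sample = n_factors_sample
        self.rho_grid_size = rho_grid_size
        self.chains = chains
        self.iterations = iterations
        self.burn_in = burn_in
        self.thin = thin
        self.latent = latent
        self.random_state = random_state

    def _config(self) -> BackboneConfig:
        return BackboneConfig(
            n_factors_site=self.n_factors_site,
            n_factors_sample=self.n_factors_sample,
            rho_grid_size=self.rho_grid_size,
            chains=self.chains,
            iterations=self.iterations,
            burn_in=self.burn_in,
            thin=self.thin,
            seed=self.random_state,
        )

    def fit(self, X, Y, C=None, T=None, site_of_sample=None):
        self.site_of_sample_ = site_of_sample
        self.posterior_ = fit_backbone(
            Y, X, C, T=T, cfg=self._config(), latent=self.latent,
            site_of_sample=site_of_sample,
        )
        return self

    def transform(self, X):
        return expand_design(X, self.posterior_, self.site_of_sample_)
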