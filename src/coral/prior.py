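"""Conditional transfer priors for rare species.

Under the backbone prior vec(B) ~ N(vec(Gamma T'), P (x) V) with
P = rho C + (1 - rho) I, the coefficients of a species r outside the
backbone are jointly Gaussian with the backbone coefficients.  Conditioning
on a posterior draw of (B, Gamma, V, rho) gives

    m_r = Gamma t_r + E (rho P^-1 c_r),        E = B - Gamma T',
    S_r = k_r V,

where c_r holds the taxonomic correlations between species r and the
backbone species.  Two variance conventions are exposed: ``exact`` uses the
Schur complement of the joint prior covariance, k_r = 1 - rho^2 c'P^-1 c
(self-consistent with the conditional mean and verified against brute-force
Gaussian conditioning), while ``paper`` uses k_r = 1 - rho c'P^-1 c.

Averaging the per-draw Gaussians over the backbone posterior yields a
mixture; the transfer prior is its Gaussian moment match,
m' = E[m_r], S' = E[S_r] + Cov[m_r].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .backbone import BackbonePosterior
from .data import TaxonomyTable, cross_taxonomic_correlation, build_taxonomic_correlation, _shared_depth

K_EPS = 1e-6


@dataclass
class CoralPrior:
    """Gaussian transfer prior N(m, S) for one rare species."""

    species_id: str
    m: np.ndarray
    S: np.ndarray
    k_mean: float
    relatedness_depth: int  # deepest rank index shared with any backbone species
    relatedness_rank: str
    columns: list | None = None
    k_draws: np.ndarray | None = None


def conditional_prior_one_draw(
    draw: dict,
    c_r: np.ndarray,
    t_r: np.ndarray | None = None,
    C: np.ndarray | None = None,
    T: np.ndarray | None = None,
    mode: str = "exact",
) -> tuple[np.ndarray, np.ndarray]:
    """(m_r, S_r) from one posterior draw of {B, Gamma, V, rho}.

    ``C`` is the backbone species correlation matrix (identity if None) and
    ``T`` the backbone trait matrix (intercept-only default).  ``c_r`` holds
    entries in [0, 1]; ``t_r`` defaults to an intercept-only trait vector.
    """
    if mode not in ("exact", "paper"):
        raise ValueError(f"unknown mode {mode!r}")
    B = np.asarray(draw["B"], dtype=float)
    Gamma = np.atleast_2d(np.asarray(draw["Gamma"], dtype=float))
    if Gamma.shape[0] != B.shape[0]:
        Gamma = Gamma.reshape(B.shape[0], -1)
    V = np.atleast_2d(np.asarray(draw["V"], dtype=float))
    rho = float(draw["rho"])
    p, n_s = B.shape
    c_r = np.asarray(c_r, dtype=float).reshape(n_s)
    Tm = np.ones((n_s, 1)) if T is None else np.asarray(T, dtype=float)
    t_r = np.ones(Tm.shape[1]) if t_r is None else np.asarray(t_r, dtype=float)
    Cm = np.eye(n_s) if C is None else np.asarray(C, dtype=float)

    P = rho * Cm + (1.0 - rho) * np.eye(n_s)
    Pinv_c = np.linalg.solve(P, c_r)
    E = B - Gamma @ Tm.T
    m_r = Gamma @ t_r + E @ (rho * Pinv_c)
    q = float(c_r @ Pinv_c)
    k_r = 1.0 - (rho if mode == "paper" else rho**2) * q
    if k_r <= 0.0:
        warnings.warn(f"variance scaling factor k={k_r:.3g} <= 0; clipped to {K_EPS}")
        k_r = K_EPS
    return m_r, k_r * V


def moment_match(draws: list[tuple[np.ndarray, np.ndarray]]) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian moment match of a mixture of Gaussians given as (mean, cov) pairs.

    m' = mean of the means; S' = mean of the covariances plus the population
    covariance of the means (law of total variance).
    """
    if len(draws) == 0:
        raise ValueError("need at least one draw")
    means = np.stack([m for m, _ in draws])
    covs = np.stack([S for _, S in draws])
    m = means.mean(axis=0)
    dev = means - m
    S = covs.mean(axis=0) + dev.T @ dev / len(draws)
    return m, 0.5 * (S + S.T)


def build_priors(
    bp: BackbonePosterior,
    tax: TaxonomyTable,
    rare_ids,
    T_rare: np.ndarray | None = None,
    mode: str = "exact",
    level_heights: np.ndarray | None = None,
    max_draws: int | None = None,
) -> dict[str, CoralPrior]:
    """Moment-matched transfer priors for every rare species.

    Relatedness vectors c_r come from the taxonomy against the backbone
    species; all stored posterior draws are used unless ``max_draws``
    subsamples them.  Vectorized across species and draws.
    """
    rare_ids = pd.Index(rare_ids)
    if len(rare_ids) == 0:
        return {}
    missing = rare_ids.difference(tax.species_ids)
    if len(missing):
        raise ValueError(f"rare species missing from taxonomy: {list(missing[:10])}")
    common_ids = pd.Index([str(s) for s in bp.species_ids])

    C_common = build_taxonomic_correlation(tax, common_ids, level_heights).to_numpy()
    C_cross = cross_taxonomic_correlation(tax, common_ids, rare_ids, level_heights).to_numpy()
    depth = _shared_depth(tax.rank_codes(common_ids.append(rare_ids))[: len(common_ids)],
                          tax.rank_codes(common_ids.append(rare_ids))[len(common_ids):])
    deepest = depth.max(axis=0)  # (n_rare,)

    evals, U = np.linalg.eigh(0.5 * (C_common + C_common.T))
    evals = np.clip(evals, 1e-10, None)
    W = U.T @ C_cross  # (n_s, n_rare)

    D = bp.n_draws
    idx = np.arange(D) if max_draws is None or max_draws >= D else np.linspace(0, D - 1, max_draws).astype(int)
    p = bp.B.shape[1]
    n_rare = len(rare_ids)
    n_t = bp.Gamma.shape[2]
    Tm = bp.trait_matrix if bp.trait_matrix is not None else np.ones((len(common_ids), 1))
    Tr = np.ones((n_rare, n_t)) if T_rare is None else np.asarray(T_rare, dtype=float)

    sum_m = np.zeros((n_rare, p))
    sum_mm = np.zeros((n_rare, p, p))
    sum_S = np.zeros((n_rare, p, p))
    k_all = np.empty((len(idx), n_rare))
    rho_pow = 1 if mode == "paper" else 2
    if mode not in ("exact", "paper"):
        raise ValueError(f"unknown mode {mode!r}")

    n_clipped = 0
    for t, d in enumerate(idx):
        B = bp.B[d]
        Gamma = bp.Gamma[d]
        V = bp.V[d]
        rho = float(bp.rho[d])
        dv = rho * evals + (1.0 - rho)
        Wd = W / dv[:, None]
        PinvC = U @ Wd  # (n_s, n_rare)
        q = (W * Wd).sum(axis=0)  # c' P^-1 c per rare species
        k = 1.0 - rho**rho_pow * q
        bad = k <= 0
        n_clipped += int(bad.sum())
        k = np.where(bad, K_EPS, k)
        k_all[t] = k
        E = B - Gamma @ Tm.T
        M = Gamma @ Tr.T + E @ (rho * PinvC)  # (p, n_rare)
        sum_m += M.T
        sum_mm += np.einsum("rp,rq->rpq", M.T, M.T)
        sum_S += np.einsum("r,pq->rpq", k, V)
    if n_clipped:
        warnings.warn(f"clipped {n_clipped} non-positive variance scaling factors to {K_EPS}")

    nd = len(idx)
    mean_m = sum_m / nd
    cov_m = sum_mm / nd - np.einsum("rp,rq->rpq", mean_m, mean_m)
    S_prime = sum_S / nd + cov_m
    S_prime = 0.5 * (S_prime + np.swapaxes(S_prime, 1, 2))
    k_mean = k_all.mean(axis=0)

    ranks = tax.ranks
    out = {}
    for r, sp in enumerate(rare_ids):
        out[str(sp)] = CoralPrior(
            species_id=str(sp),
            m=mean_m[r],
            S=S_prime[r],
            k_mean=float(k_mean[r]),
            relatedness_depth=int(deepest[r]),
            relatedness_rank=ranks[deepest[r] - 1] if deepest[r] > 0 else "none",
            columns=list(bp.design_columns),
            k_draws=k_all[:, r].copy(),
        )
    return out


def priors_to_hdf5(priors: dict[str, CoralPrior], path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        for sp, pr in priors.items():
            g = f.create_group(sp)
            g.create_dataset("m", data=pr.m)
            iu = np.triu_indices(len(pr.m))
            g.create_dataset("S_upper", data=pr.S[iu])
            g.attrs["k_mean"] = pr.k_mean
            g.attrs["relatedness_depth"] = pr.relatedness_depth
            g.attrs["relatedness_rank"] = pr.relatedness_rank


def priors_from_hdf5(path) -> dict[str, CoralPrior]:
    import h5py

    out = {}
    with h5py.File(path, "r") as f:
        for sp in f:
            g = f[sp]
            m = g["m"][...]
            p = len(m)
            S = np.zeros((p, p))
            iu = np.triu_indices(p)
            S[iu] = g["S_upper"][...]
            S = S + np.triu(S, 1).T
            out[sp] = CoralPrior(
                species_id=sp,
                m=m,
                S=S,
                k_mean=float(g.attrs["k_mean"]),
                relatedness_depth=int(g.attrs["relatedness_depth"]),
                relatedness_rank=str(g.attrs["relatedness_rank"]),
            )
    return out


def priors_to_tsv(priors: dict[str, CoralPrior], path) -> None:
    """Flat text export: per species the mean vector and upper-triangular S'."""
    rows = []
    for sp, pr in priors.items():
        p = len(pr.m)
        iu = np.triu_indices(p)
        row = {"species_id": sp, "k_mean": pr.k_mean, "relatedness_rank": pr.relatedness_rank}
        row.update({f"m_{k}": v for k, v in enumerate(pr.m)})
        row.update({f"S_{i}_{j}": pr.S[i, j] for i, j in zip(*iu)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
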