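"""Prediction and evaluation for Gaussian-summarized probit posteriors.

Because every per-species posterior is stored as a Gaussian N(mu, Sigma),
the posterior-mean occurrence probability has the closed form
Phi(x'mu / sqrt(1 + x'Sigma x)) — no Monte Carlo needed.  On top of that
this module implements the presence-absence metric suite (AUC, Tjur R2,
PRAUC, Brier, negative log-likelihood, log-determinant of the posterior
covariance), species-wise twofold cross-validation with a minimum
per-fold occurrence share, paired one-sided model comparison tests and
posterior predictive checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import ttest_rel
from sklearn.metrics import average_precision_score, roc_auc_score

from .probit import (
    ProbitFitConfig,
    SpeciesPosteriorSummary,
    default_prior,
    fit_species,
    species_seed,
    summarize_draws,
)

_P_CLIP = 1e-12


def predict_prob(
    summary: SpeciesPosteriorSummary, X_new: pd.DataFrame | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior-mean occurrence probabilities and linear-predictor means.

    p_i = Phi(x_i'mu / sqrt(1 + x_i'Sigma x_i)) — the exact Gaussian
    integral of the probit link over the coefficient posterior.
    """
    if isinstance(X_new, pd.DataFrame):
        if summary.columns and list(X_new.columns) != list(summary.columns):
            raise ValueError("design columns do not match posterior summary")
        X_new = X_new.to_numpy()
    X_new = np.asarray(X_new, dtype=float)
    if X_new.shape[1] != len(summary.mu):
        raise ValueError(
            f"design has {X_new.shape[1]} columns, summary has {len(summary.mu)}"
        )
    lin = X_new @ summary.mu
    s = 1.0 + np.einsum("ip,pq,iq->i", X_new, summary.Sigma, X_new)
    return ndtr(lin / np.sqrt(s)), lin


def environmental_column_mask(columns: list[str]) -> np.ndarray:
    """Fixed-effect (environmental) columns: everything measured except the
    intercept and the latent-factor columns."""
    return np.array(
        [c != "intercept" and not c.startswith("LF_") for c in columns], dtype=bool
    )


def compute_metrics(
    y: np.ndarray,
    p: np.ndarray,
    summary: SpeciesPosteriorSummary | None = None,
    logdet_environment_only: bool = True,
) -> dict:
    """One species' metric row; AUC/PRAUC/Tjur are NaN without both classes."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("probabilities outside [0, 1]")
    pos, neg = y == 1, y == 0
    out: dict = {"prevalence": int(y.sum())}
    if pos.any() and neg.any():
        out["auc"] = float(roc_auc_score(y, p))
        out["tjur_r2"] = float(p[pos].mean() - p[neg].mean())
        out["prauc"] = float(average_precision_score(y, p))
    else:
        out["auc"] = out["tjur_r2"] = out["prauc"] = np.nan
    out["brier"] = float(np.mean((p - y) ** 2))
    pc = np.clip(p, _P_CLIP, 1.0 - _P_CLIP)
    out["nll"] = float(-np.mean(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc)))
    if summary is not None:
        Sigma = summary.Sigma
        if logdet_environment_only and summary.columns:
            mask = environmental_column_mask(summary.columns)
            Sigma = Sigma[np.ix_(mask, mask)]
        sign, logdet = np.linalg.slogdet(Sigma)
        out["logdet"] = float(logdet) if sign > 0 else np.nan
    return out


@dataclass
class CVFolds:
    """Twofold assignment for one species (0/1 per sample)."""

    assignment: np.ndarray
    resamples: int
    accepted: bool


def make_cv_folds(
    y: np.ndarray, seed: int, max_resamples: int = 1000
) -> CVFolds:
    """Random balanced twofold split, redrawn until each fold holds at least
    40% of the occurrences (exact rational comparison, boundary accepted)."""
    y = np.asarray(y)
    n = len(y)
    prev = int(y.sum())
    rng = np.random.default_rng(seed)
    assignment = np.zeros(n, dtype=int)
    for attempt in range(1, max_resamples + 1):
        perm = rng.permutation(n)
        assignment = np.zeros(n, dtype=int)
        assignment[perm[n // 2 :]] = 1
        c0 = int(y[assignment == 0].sum())
        c1 = prev - c0
        if 5 * c0 >= 2 * prev and 5 * c1 >= 2 * prev:
            return CVFolds(assignment=assignment, resamples=attempt, accepted=True)
    return CVFolds(assignment=assignment, resamples=max_resamples, accepted=False)


def _design_and_prior(kind, X_measured, X_expanded, coral_prior):
    if kind == "baseline":
        X = X_measured
        m0, S0 = default_prior(list(X.columns))
    elif kind == "ablation":
        X = X_expanded
        m0, S0 = default_prior(list(X.columns))
    elif kind == "coral":
        if coral_prior is None:
            raise ValueError("coral fit requires a transfer prior")
        X = X_expanded
        m0, S0 = coral_prior.m, coral_prior.S
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    return X, m0, S0


def run_cv(
    Y: pd.DataFrame,
    X_measured: pd.DataFrame,
    X_expanded: pd.DataFrame,
    priors: dict,
    eval_ids,
    cfg: ProbitFitConfig,
    model_kinds: tuple[str, ...] = ("coral", "baseline", "ablation"),
    min_prevalence: int = 5,
    max_resamples: int = 1000,
    logdet_environment_only: bool = True,
) -> pd.DataFrame:
    """Species-wise twofold CV of the per-species models.

    For each evaluation species (prevalence >= ``min_prevalence``): draw the
    folds, fit each model kind on one fold, predict the held-out fold, and
    score the concatenated held-out predictions.  The backbone posterior,
    latent-factor point estimates and transfer priors are fixed inputs
    (they never see the focal species' data).  Returns the long-format
    metrics table with one row per species x model kind.
    """
    rows = []
    for sp in eval_ids:
        y = Y[sp].to_numpy()
        prev = int(y.sum())
        if prev < min_prevalence:
            continue
        folds = make_cv_folds(y, seed=species_seed(cfg.seed, f"folds:{sp}"), max_resamples=max_resamples)
        if not folds.accepted:
            continue
        preds = {kind: np.empty(len(y)) for kind in model_kinds}
        logdets = {kind: [] for kind in model_kinds}
        for f in (0, 1):
            train = folds.assignment != f
            test = ~train
            for kind in model_kinds:
                X, m0, S0 = _design_and_prior(
                    kind, X_measured, X_expanded, priors.get(str(sp))
                )
                fit_cfg = ProbitFitConfig(
                    n_samples=cfg.n_samples, burn_in=cfg.burn_in,
                    seed=cfg.seed, model_kind=kind,
                )
                summ = fit_species(
                    y[train],
                    X.iloc[train.nonzero()[0]],
                    fit_cfg,
                    prior_mean=m0,
                    prior_cov=S0,
                    species_id=str(sp),
                    seed=species_seed(cfg.seed, f"{kind}:{f}:{sp}"),
                )
                p_test, _ = predict_prob(summ, X.iloc[test.nonzero()[0]])
                preds[kind][test] = p_test
                met = compute_metrics(
                    y[test], p_test, summ, logdet_environment_only=logdet_environment_only
                )
                if np.isfinite(met.get("logdet", np.nan)):
                    logdets[kind].append(met["logdet"])
        for kind in model_kinds:
            met = compute_metrics(y, preds[kind])
            met.update(
                species_id=str(sp),
                model_kind=kind,
                resamples=folds.resamples,
                logdet=float(np.mean(logdets[kind])) if logdets[kind] else np.nan,
            )
            pr = priors.get(str(sp))
            met["relatedness_rank"] = pr.relatedness_rank if pr is not None else ""
            rows.append(met)
    return pd.DataFrame(rows)


def compare_models(
    metric_a: np.ndarray, metric_b: np.ndarray, side: str = "greater"
) -> tuple[float, float]:
    """Paired one-sided t-test on per-species metric differences (A vs B)."""
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    if len(a) < 2:
        raise ValueError("need at least two paired finite values")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return 0.0, 0.5
        raise ValueError("exact tie: zero variance of nonzero differences")
    res = ttest_rel(a, b, alternative=side)
    return float(res.statistic), float(res.pvalue)


def posterior_predictive_checks(
    Y: pd.DataFrame,
    P: pd.DataFrame,
    covariate: pd.Series | None = None,
    min_prevalence: int = 10,
) -> dict[str, pd.DataFrame]:
    """Three calibration checks of the analytic posterior predictions.

    (i) per species: expected number of occurrences vs observed prevalence;
    (ii) per sample: expected vs observed species richness;
    (iii) for species with >= ``min_prevalence`` occurrences: observed vs
    expected proportion of occurrences in samples below the median of the
    named covariate.
    """
    out = {}
    out["species_prevalence"] = pd.DataFrame(
        {"observed": Y.sum(axis=0), "expected": P.sum(axis=0)}
    )
    out["sample_richness"] = pd.DataFrame(
        {"observed": Y.sum(axis=1), "expected": P.sum(axis=1)}
    )
    if covariate is not None:
        below = (covariate < covariate.median()).to_numpy()
        prev = Y.sum(axis=0)
        keep = prev[prev >= min_prevalence].index
        obs = Y.loc[:, keep].iloc[below].sum(axis=0) / prev[keep]
        expected_total = P.loc[:, keep].sum(axis=0)
        exp = P.loc[:, keep].iloc[below].sum(axis=0) / expected_total
        out["below_median"] = pd.DataFrame({"observed": obs, "expected": exp})
    return out
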