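"""Pre-registered desk-scale validation experiments.

These functions wire the full workflow onto synthetic communities of fixed
size so the method's headline claims can be re-measured end to end on a
single CPU: transfer-learning benefit in held-out prediction, variance
scaling with relatedness, posterior-variance reduction, coefficient
recovery by the backbone, and rarefaction recovery.  Problem sizes and
sampler lengths are package choices documented in the methods note; all
randomness flows from the single ``seed`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .backbone import BackboneConfig, expand_design, fit_backbone, fit_stage2
from .data import build_design_matrix, build_taxonomic_correlation, split_by_prevalence
from .evaluate import compare_models, run_cv
from .prior import build_priors
from .probit import ProbitFitConfig
from .simulate import recovery_experiment, simulate_community

# community at the scaled study size: ~400 samples, ~60 common / ~300 rare
COMMUNITY_KW = dict(
    n_samples=400, n_sites=30, n_species=360, rho=0.7,
    n_factors_site=5, n_factors_sample=3,
)
PREVALENCE_THRESHOLD = 50
EVAL_MIN_PREVALENCE = 5

BACKBONE_CFG_KW = dict(
    n_factors_site=5, n_factors_sample=3, chains=2, iterations=1500,
    burn_in=500, thin=5,
)
PROBIT_KW = dict(n_samples=1500, burn_in=750)


@dataclass
class TransferExperiment:
    """Everything the downstream checks need from one synthetic run."""

    cd: object
    tax: object
    truth: object
    partition: object
    X: pd.DataFrame
    Xt: pd.DataFrame
    bp1: object
    bp2: object
    priors: dict
    cv_metrics: pd.DataFrame
    probit_cfg: ProbitFitConfig
    seed: int
    means: dict = field(default_factory=dict)


def run_transfer_experiment(
    seed: int = 0, model_kinds=("coral", "baseline", "ablation")
) -> TransferExperiment:
    """Simulate a community, run the two-stage workflow and twofold CV."""
    cd, tax, truth = simulate_community(seed=seed, **COMMUNITY_KW)
    partition = split_by_prevalence(cd, PREVALENCE_THRESHOLD)
    if len(partition.common_ids) < BACKBONE_CFG_KW["n_factors_site"]:
        raise RuntimeError("degenerate community: too few common species")
    X, _ = build_design_matrix(cd)
    C = build_taxonomic_correlation(tax, partition.common_ids)
    Y_common = cd.Y[partition.common_ids]
    cfg1 = BackboneConfig(seed=seed + 1, **BACKBONE_CFG_KW)
    bp1 = fit_backbone(Y_common, X, C, cfg=cfg1, latent=True, site_of_sample=cd.site_of_sample)
    Xt = expand_design(X, bp1, cd.site_of_sample)
    cfg2 = BackboneConfig(seed=seed + 2, **BACKBONE_CFG_KW)
    bp2 = fit_stage2(Y_common, Xt, C, cfg=cfg2)
    priors = build_priors(bp2, tax, partition.rare_ids)
    probit_cfg = ProbitFitConfig(seed=seed + 3, **PROBIT_KW)
    prev = partition.prevalence
    eval_ids = [sp for sp in partition.rare_ids if prev[sp] >= EVAL_MIN_PREVALENCE]
    cv = run_cv(
        cd.Y, X, Xt, priors, eval_ids, probit_cfg,
        model_kinds=model_kinds, min_prevalence=EVAL_MIN_PREVALENCE,
    )
    means = {
        f"{metric}_{kind}": float(cv.loc[cv.model_kind == kind, metric].mean())
        for kind in model_kinds
        for metric in ("auc", "tjur_r2", "prauc", "brier", "nll", "logdet")
    }
    return TransferExperiment(
        cd=cd, tax=tax, truth=truth, partition=partition, X=X, Xt=Xt,
        bp1=bp1, bp2=bp2, priors=priors, cv_metrics=cv, probit_cfg=probit_cfg,
        seed=seed, means=means,
    )


def auc_comparison(exp: TransferExperiment, kind_a="coral", kind_b="baseline"):
    wide = exp.cv_metrics.pivot(index="species_id", columns="model_kind", values="auc")
    return compare_models(wide[kind_a], wide[kind_b])


def backbone_recovery(
    seed: int = 0, rho_true: float = 0.7, n_samples: int = 400, n_species: int = 40,
    cfg: BackboneConfig | None = None,
):
    """Fit the backbone (no latent factors) to data simulated from it.

    Returns (correlation of posterior-mean coefficients with truth,
    rho posterior draws).
    """
    cd, tax, truth = simulate_community(
        n_samples=n_samples, n_sites=10, n_species=n_species, rho=rho_true,
        n_factors_site=0, n_factors_sample=0, intercept_loc=-1.0,
        intercept_scale=1.0, seed=seed,
    )
    X, _ = build_design_matrix(cd)
    C = build_taxonomic_correlation(tax)
    cfg = cfg or BackboneConfig(seed=seed + 1)
    bp = fit_backbone(cd.Y, X, C, cfg=cfg, latent=False)
    B_hat = bp.B.mean(axis=0)
    corr = float(np.corrcoef(B_hat.ravel(), truth.B.ravel())[0, 1])
    return corr, bp.rho


def variance_comparison(exp: TransferExperiment, max_prevalence: int = 10) -> pd.DataFrame:
    """Full-data posterior variance over environmental coefficients,
    transfer fit vs baseline, for the very rare species."""
    from .evaluate import environmental_column_mask
    from .probit import default_prior, fit_species, species_seed

    prev = exp.partition.prevalence
    ids = [
        sp for sp in exp.partition.rare_ids
        if 1 <= prev[sp] <= max_prevalence and str(sp) in exp.priors
    ]
    mask_e = environmental_column_mask(list(exp.Xt.columns))
    mask_b = environmental_column_mask(list(exp.X.columns))
    rows = []
    for sp in ids:
        y = exp.cd.Y[sp].to_numpy()
        pr = exp.priors[str(sp)]
        cfg_c = ProbitFitConfig(seed=exp.seed + 4, model_kind="coral", **PROBIT_KW)
        s_c = fit_species(
            y, exp.Xt, cfg_c, prior_mean=pr.m, prior_cov=pr.S, species_id=str(sp),
            seed=species_seed(exp.seed + 4, f"var_c:{sp}"),
        )
        cfg_b = ProbitFitConfig(seed=exp.seed + 4, model_kind="baseline", **PROBIT_KW)
        s_b = fit_species(
            y, exp.X, cfg_b, species_id=str(sp),
            seed=species_seed(exp.seed + 4, f"var_b:{sp}"),
        )
        rows.append(
            {
                "species_id": str(sp),
                "prevalence": int(prev[sp]),
                "var_coral": float(np.diag(s_c.Sigma)[mask_e].mean()),
                "var_baseline": float(np.diag(s_b.Sigma)[mask_b].mean()),
            }
        )
    return pd.DataFrame(rows)


def k_by_relatedness(exp: TransferExperiment) -> pd.Series:
    """Mean variance scaling factor k grouped by the deepest rank shared
    with any backbone species (index = shared depth, ascending)."""
    rows = [
        {"depth": pr.relatedness_depth, "k": pr.k_mean} for pr in exp.priors.values()
    ]
    df = pd.DataFrame(rows)
    return df.groupby("depth")["k"].mean().sort_index()


def rarefaction_recovery(exp: TransferExperiment, fraction: float = 0.9):
    """Mask the common species and measure coefficient recovery by transfer."""
    report, per_species = recovery_experiment(
        exp.cd.Y[exp.partition.common_ids], exp.Xt, exp.bp2, exp.tax,
        exp.probit_cfg, fraction=fraction, seed=exp.seed + 5,
    )
    return report, per_species
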