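"""End-to-end orchestration of the two-stage transfer-learning workflow.

Stage order: load/validate -> common/rare split -> stage-1 backbone with
latent factors -> latent point estimates -> stage-2 backbone on the
expanded design -> transfer priors for rare species -> independent rare
fits -> analytic predictions, posterior predictive checks and optional
cross-validation.  Every stage writes its artifact into the output
directory and is skipped on rerun when the artifact already exists, so a
pipeline can be resumed; a manifest records the config hash, seed and
library versions needed to reproduce any output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .backbone import BackboneConfig, BackbonePosterior, expand_design, fit_backbone, fit_stage2
from .data import build_design_matrix, build_taxonomic_correlation, load_community, split_by_prevalence
from .evaluate import compare_models, posterior_predictive_checks, predict_prob, run_cv
from .prior import build_priors, priors_from_hdf5, priors_to_hdf5, priors_to_tsv
from .probit import ProbitFitConfig, SpeciesPosteriorSummary, fit_all_rare, summarize_draws

log = logging.getLogger(__name__)

ALL_STAGES = ("split", "backbone", "priors", "fit", "predict", "cv")


@dataclass
class RunConfig:
    occurrence: str = ""
    covariates: str = ""
    taxonomy: str = ""
    outdir: str = "coral_out"
    seed: int = 0
    prevalence_threshold: int = 50
    eval_min_prevalence: int = 5
    prior_mode: str = "exact"
    model_kinds: tuple[str, ...] = ("coral", "baseline", "ablation")
    backbone: dict = field(default_factory=dict)
    probit: dict = field(default_factory=dict)
    cv_enabled: bool = True
    cv_max_resamples: int = 1000
    n_jobs: int = 1

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "model_kinds" in raw:
            raw["model_kinds"] = tuple(raw["model_kinds"])
        return cls(**raw)

    def backbone_config(self, latent: bool) -> BackboneConfig:
        kw = dict(self.backbone)
        kw.setdefault("seed", self.seed)
        if not latent:
            kw["seed"] = kw["seed"] + 1  # independent chain seeding per stage
        return BackboneConfig(**kw)

    def probit_config(self, kind: str) -> ProbitFitConfig:
        kw = dict(self.probit)
        kw.setdefault("seed", self.seed)
        return ProbitFitConfig(model_kind=kind, **kw)


def summaries_to_hdf5(summaries: dict[str, SpeciesPosteriorSummary], path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        for sp, s in summaries.items():
            g = f.create_group(sp)
            g.create_dataset("mu", data=s.mu)
            iu = np.triu_indices(len(s.mu))
            g.create_dataset("Sigma_upper", data=s.Sigma[iu])
            g.attrs["model_kind"] = s.model_kind
            g.attrs["columns"] = json.dumps(s.columns)


def summaries_from_hdf5(path) -> dict[str, SpeciesPosteriorSummary]:
    import h5py

    out = {}
    with h5py.File(path, "r") as f:
        for sp in f:
            g = f[sp]
            mu = g["mu"][...]
            p = len(mu)
            S = np.zeros((p, p))
            iu = np.triu_indices(p)
            S[iu] = g["Sigma_upper"][...]
            S = S + np.triu(S, 1).T
            out[sp] = SpeciesPosteriorSummary(
                species_id=sp, mu=mu, Sigma=S,
                model_kind=str(g.attrs["model_kind"]),
                columns=json.loads(g.attrs["columns"]),
            )
    return out


def summarize_backbone_species(bp: BackbonePosterior) -> dict[str, SpeciesPosteriorSummary]:
    """Gaussian posterior summaries of the backbone (common) species from
    the stage-2 coefficient draws."""
    out = {}
    for j, sp in enumerate(bp.species_ids):
        draws = bp.B[:, :, j]
        out[str(sp)] = summarize_draws(draws, str(sp), "coral", list(bp.design_columns))
    return out


def run_pipeline(cfg: RunConfig, stages: tuple[str, ...] = ALL_STAGES) -> dict:
    """Execute (or resume) the pipeline; returns paths of written artifacts."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}

    cd, tax = load_community(cfg.occurrence, cfg.covariates, cfg.taxonomy)
    partition = split_by_prevalence(cd, cfg.prevalence_threshold)
    X, builder = build_design_matrix(cd)
    sites = cd.site_of_sample

    if "split" in stages:
        path = out / "partition.json"
        path.write_text(
            json.dumps(
                {
                    "threshold": partition.threshold,
                    "n_common": len(partition.common_ids),
                    "n_rare": len(partition.rare_ids),
                    "common_ids": [str(s) for s in partition.common_ids],
                    "zero_occurrence": [str(s) for s in partition.zero_occurrence_ids],
                },
                indent=1,
            )
        )
        artifacts["partition"] = path

    Y_common = cd.Y[partition.common_ids]
    C_common = build_taxonomic_correlation(tax, partition.common_ids)

    s1_path, s2_path = out / "backbone_stage1.h5", out / "backbone_stage2.h5"
    if "backbone" in stages or not s2_path.exists():
        if s1_path.exists():
            bp1 = BackbonePosterior.from_hdf5(s1_path)
            log.info("stage 1 cached: %s", s1_path)
        else:
            log.info("fitting stage-1 backbone (%d common species)", Y_common.shape[1])
            bp1 = fit_backbone(
                Y_common, X, C_common, cfg=cfg.backbone_config(latent=True),
                latent=True, site_of_sample=sites,
            )
            bp1.to_hdf5(s1_path)
        Xt = expand_design(X, bp1, sites)
        Xt.to_csv(out / "expanded_design.tsv", sep="\t")
        if s2_path.exists():
            bp2 = BackbonePosterior.from_hdf5(s2_path)
            log.info("stage 2 cached: %s", s2_path)
        else:
            log.info("fitting stage-2 backbone on expanded design")
            bp2 = fit_stage2(Y_common, Xt, C_common, cfg=cfg.backbone_config(latent=False))
            bp2.to_hdf5(s2_path)
        artifacts["backbone_stage1"], artifacts["backbone_stage2"] = s1_path, s2_path
    else:
        bp2 = BackbonePosterior.from_hdf5(s2_path)
        Xt = pd.read_csv(out / "expanded_design.tsv", sep="\t", index_col=0)

    priors_path = out / "priors.h5"
    if priors_path.exists():
        priors = priors_from_hdf5(priors_path)
    else:
        log.info("building transfer priors for %d rare species", len(partition.rare_ids))
        priors = build_priors(bp2, tax, partition.rare_ids, mode=cfg.prior_mode)
        priors_to_hdf5(priors, priors_path)
        priors_to_tsv(priors, out / "priors.tsv")
    artifacts["priors"] = priors_path

    fits_path = out / "species_fits.h5"
    if "fit" in stages or "predict" in stages:
        if fits_path.exists():
            summaries = summaries_from_hdf5(fits_path)
        else:
            log.info("fitting %d rare species", len(partition.rare_ids))
            pri = {sp: (p.m, p.S) for sp, p in priors.items()}
            summaries = fit_all_rare(
                cd.Y[partition.rare_ids], Xt, pri,
                cfg.probit_config("coral"), n_jobs=cfg.n_jobs,
            )
            summaries.update(summarize_backbone_species(bp2))
            summaries_to_hdf5(summaries, fits_path)
        artifacts["species_fits"] = fits_path

    if "predict" in stages:
        P = pd.DataFrame(
            {sp: predict_prob(s, Xt)[0] for sp, s in summaries.items()},
            index=cd.sample_ids,
        )[[sp for sp in cd.species_ids if sp in summaries]]
        P.to_csv(out / "predictions.tsv", sep="\t")
        checks = posterior_predictive_checks(
            cd.Y[P.columns], P, covariate=cd.covariates["temperature"]
        )
        for name, tab in checks.items():
            tab.to_csv(out / f"ppc_{name}.tsv", sep="\t")
        artifacts["predictions"] = out / "predictions.tsv"

    if "cv" in stages and cfg.cv_enabled:
        prev = partition.prevalence
        eval_ids = [
            sp for sp in partition.rare_ids if prev[sp] >= cfg.eval_min_prevalence
        ]
        log.info("twofold CV on %d evaluation species", len(eval_ids))
        metrics = run_cv(
            cd.Y, X, Xt, priors, eval_ids, cfg.probit_config("coral"),
            model_kinds=cfg.model_kinds,
            min_prevalence=cfg.eval_min_prevalence,
            max_resamples=cfg.cv_max_resamples,
        )
        metrics.to_csv(out / "cv_metrics.tsv", sep="\t", index=False)
        artifacts["cv_metrics"] = out / "cv_metrics.tsv"
        if {"coral", "baseline"} <= set(cfg.model_kinds) and len(metrics):
            wide = metrics.pivot(index="species_id", columns="model_kind", values="auc")
            try:
                t, pval = compare_models(wide["coral"], wide["baseline"])
                (out / "comparison.json").write_text(
                    json.dumps({"auc_t": t, "auc_one_sided_p": pval})
                )
            except ValueError:
                pass

    manifest = {
        "config": cfg.__dict__ | {"model_kinds": list(cfg.model_kinds)},
        "config_hash": hashlib.sha256(
            yaml.safe_dump(cfg.__dict__ | {"model_kinds": list(cfg.model_kinds)}).encode()
        ).hexdigest(),
        "seed": cfg.seed,
        "versions": {
            "coral": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "artifacts": {k: str(v) for k, v in artifacts.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return artifacts
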