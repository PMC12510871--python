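# coral-jsdm

Common-to-rare Bayesian transfer learning for joint species distribution
models.

DNA-based biodiversity surveys routinely detect tens of thousands to
hundreds of thousands of species in a few thousand samples — and almost
all of those species are rare. Classical joint species distribution models
(JSDMs) cannot carry that many species, so rare species are usually cut
from the analysis altogether. This package implements the alternative:
fit a latent-factor multivariate probit JSDM to the *common* species only
(the "backbone"), then transfer what it learned — latent environmental
factors, average responses, cross-predictor covariance, and taxonomic
structure in the responses — to every rare species as an informative
Gaussian prior, under which each rare species is fitted independently (and
so trivially in parallel).

It is aimed at community ecologists and biostatisticians working with
sample × species occurrence matrices from metabarcoding or other
novel-community data, with a ranked taxonomy (or ultrametric phylogeny)
and simple per-sample covariates.

## The model in brief

Occurrences follow a probit regression
Pr(y_ij = 1) = Φ(Σ_k x_ik β_kj + Σ_k η_ik λ_kj) with measured predictors
x and latent factors η, and a taxonomically structured coefficient prior

    vec(B) ~ N(vec(Γ Tᵀ), P ⊗ V),    P = ρC + (1 − ρ) I,

where C holds taxonomic correlations between species and ρ ∈ [0, 1] is the
strength of phylogenetic signal. After fitting the backbone and refitting
it with the latent-factor point estimates as fixed covariates
x̃ = (x, η̂), each rare species r gets the conditional prior

    β_r | draw ~ N( Γt_r + E ρP⁻¹c_r ,  k_r V ),    E = B − ΓTᵀ,

with k_r = 1 − ρ²c_rᵀP⁻¹c_r (Schur complement; the printed-formula variant
1 − ρc_rᵀP⁻¹c_r is available as `mode="paper"`), averaged over the
backbone posterior by Gaussian moment matching. Rare species are fitted by
probit data augmentation under that prior and summarized as N(μ, Σ), from
which occurrence probabilities are analytic:
p_i = Φ(x̃_iᵀμ / √(1 + x̃_iᵀΣx̃_i)). Evaluation compares the transfer
model against a no-transfer baseline (measured covariates, default prior)
and an ablation (latent factors, default prior) by species-wise twofold
cross-validation on AUC, Tjur R², PRAUC, Brier score, negative
log-likelihood and posterior log-determinant. See `docs/methods.md` for
the full account.

## Worked example

```python
import numpy as np
import coral

# simulate a small community from the model's own generative process
cd, tax, truth = coral.simulate_community(
    n_samples=200, n_sites=15, n_species=150,
    n_factors_site=3, n_factors_sample=2, seed=7,
)
part = coral.split_by_prevalence(cd, threshold=25)
print(f"{len(part.common_ids)} common / {len(part.rare_ids)} rare species")

X, _ = coral.build_design_matrix(cd)
C = coral.build_taxonomic_correlation(tax, part.common_ids)

cfg = coral.BackboneConfig(n_factors_site=3, n_factors_sample=2,
                           chains=2, iterations=1000, burn_in=400, thin=5, seed=1)
bp1 = coral.fit_backbone(cd.Y[part.common_ids], X, C, cfg=cfg,
                         latent=True, site_of_sample=cd.site_of_sample)
Xt = coral.expand_design(X, bp1, cd.site_of_sample)
bp2 = coral.fit_stage2(cd.Y[part.common_ids], Xt, C, cfg=cfg)
print(f"phylogenetic signal rho (stage 2 posterior mean): {bp2.rho.mean():.2f}")

priors = coral.build_priors(bp2, tax, part.rare_ids)
ks = [p.k_mean for p in priors.values()]
print(f"variance scaling factor k: mean {np.mean(ks):.2f}, range [{min(ks):.2f}, {max(ks):.2f}]")

sp = max(part.rare_ids, key=lambda s: part.prevalence[s])
pr = priors[str(sp)]
fit = coral.fit_species(cd.Y[sp].to_numpy(), Xt,
                        coral.ProbitFitConfig(n_samples=2000, burn_in=1000, model_kind="coral"),
                        prior_mean=pr.m, prior_cov=pr.S, species_id=str(sp))
p_hat, _ = coral.predict_prob(fit, Xt)
m = coral.compute_metrics(cd.Y[sp].to_numpy(), p_hat, fit)
print(f"{sp}: prevalence {part.prevalence[sp]}, closest backbone relative at "
      f"{pr.relatedness_rank} level, in-sample AUC {m['auc']:.2f}, Tjur R2 {m['tjur_r2']:.2f}")
```

Output:

```
25 common / 125 rare species
phylogenetic signal rho (stage 2 posterior mean): 0.21
variance scaling factor k: mean 0.92, range [0.89, 0.94]
sp_0014: prevalence 24, closest backbone relative at genus level, in-sample AUC 0.97, Tjur R2 0.54
```

Reading this: the stage-2 fit finds modest taxonomic signal (ρ ≈ 0.21 —
at this tiny scale the latent-loading rows, which carry no taxonomic
structure, dilute it), so the rare-species priors shrink variance only
mildly (k close to 1; smaller k means a more informative prior, and k
drops for species with close backbone relatives). The focal rare species,
sharing a genus with a backbone species, is then fitted under its
transfer prior and predicted analytically.

A scikit-learn-style surface is available for the per-species model
(`coral.BayesianProbitClassifier`, with `fit`/`predict_proba`/
`get_params`) and the design expansion (`coral.DesignMatrixBuilder`, a
`TransformerMixin` that replays the training standardization on new
samples).

## Command line

```bash
coral simulate --outdir data/ --n-samples 400 --n-species 360 --seed 1
coral run --config config.yaml        # split -> backbone -> priors -> fits -> predictions -> CV
coral rarefy --config config.yaml     # mask common species, test coefficient recovery
```

One YAML config drives everything (paths, prevalence threshold, MCMC
lengths, prior mode, model kinds); stages cache their artifacts in the
output directory and reruns resume from the cache. A manifest records the
config hash, seed and library versions behind every output.

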