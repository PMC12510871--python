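# Methods

## The model

The package targets sample × species presence–absence matrices of the kind
produced by metabarcoding surveys: a few hundred to a few thousand samples,
and a species pool dominated by rarity, so that a joint model of every
species at once is both statistically fragile and computationally out of
reach. The strategy is Bayesian transfer learning in three stages.

**Stage 1 — backbone.** The common species (prevalence ≥ a threshold,
default 50 samples) are fitted jointly with a latent-factor multivariate
probit model:

    Pr(y_ij = 1) = Φ(L_ij),
    L_ij = Σ_k x_ik β_kj + Σ_k η_ik λ_kj,

where x_i are measured predictors (climate polynomials, seasonal harmonics,
log sequencing depth), η_i are site- and sample-level latent factors, and
the coefficient matrix B carries a taxonomically structured prior

    vec(B) ~ N(vec(Γ Tᵀ), P ⊗ V),   P = ρC + (1 − ρ) I,

with C the taxonomic correlation matrix, ρ ∈ [0, 1] the strength of
phylogenetic signal, V the cross-predictor covariance of species-specific
deviations and Γ the trait-level mean response (intercept-only by default:
the matrix T is a column of ones). Inference is blocked Gibbs: truncated
normal liabilities; a matrix-normal B update that, after rotating species
into the eigenbasis of C, factorizes into independent p × p solves; a
conjugate normal for Γ; inverse-Wishart for V; an exact discrete
conditional for ρ on a grid (default 101 points, uniform prior); and
conditional normals for factors and loadings with a global
multiplicative-gamma shrinkage prior on the loadings.

**Latent point estimates and stage 2.** Factor draws are identified only
up to orthogonal rotation, so before averaging, each draw's factor block is
rotated onto a reference draw (the draw of maximal norm) by the orthogonal
Procrustes solution; with one factor this reduces to sign alignment, which
is also available as a config option. The per-unit means form point
estimates η̂ (site factors broadcast to samples), and the design is
expanded to x̃_i = (x_i, η̂_i). The backbone is then refitted with x̃ as
fixed covariates and no residual factors; this second fit supplies the
hyperparameter posterior over (B, Γ, V, ρ) on the expanded design.

**Transfer priors and rare-species fits.** Under the joint coefficient
prior, a species r outside the backbone has conditional moments given a
draw of the backbone parameters

    m_r = Γ t_r + E (ρ P⁻¹ c_r),   E = B − Γ Tᵀ,
    S_r = k_r V,

where c_r holds the taxonomic correlations between r and the backbone
species. Two variance conventions are implemented: `exact`,
k_r = 1 − ρ² c_rᵀ P⁻¹ c_r, the Schur complement of the joint prior
covariance and therefore self-consistent with the conditional mean (it is
verified against brute-force dense Gaussian conditioning in the tests);
and `paper`, k_r = 1 − ρ c_rᵀ P⁻¹ c_r, the convention printed in the
literature this family of models comes from. `exact` is the default; the
two coincide at ρ ∈ {0, 1}. Averaging (m_r, S_r) over the posterior draws
gives a Gaussian mixture, which is moment-matched to a single Gaussian
N(m′, S′) with m′ = E[m_r] and S′ = E[S_r] + Cov[m_r] (law of total
variance). Each rare species is then fitted independently by
data-augmentation probit Gibbs under N(m′, S′) on the expanded design, and
its posterior is summarized by the sample mean and covariance of the
draws — 350 numbers for a 25-column design. Occurrence probabilities are
analytic: Φ(xᵀμ / √(1 + xᵀΣx)).

The comparison models share all machinery: the **baseline** uses the
measured design only with independent N(0, 10) (intercept) / N(0, 1)
priors — variances, not standard deviations — and the **ablation** uses
the expanded design with the same default prior, isolating the value of
the latent factors from the value of the informative prior.

## Parameters that matter

| parameter | default | role |
|---|---|---|
| prevalence threshold | 50 samples | common/rare split |
| evaluation minimum prevalence | 5 | CV eligibility |
| ρ grid | 101 points on [0, 1] | discrete conditional for ρ |
| site / sample factors | 10 / 4 | latent dimensionality (fixed, no adaptation) |
| backbone MCMC | 4 chains × 3750, burn 1250, thin 10 | 1000 pooled draws |
| per-species MCMC | 5000 kept after 2500 burn-in | rare-species fits |
| Γ prior variance | 10 | weakly informative trait-mean prior |
| V prior | IW(p + 2, I) | prior mean I |
| shrinkage a1, a2 | 2, 3 | multiplicative-gamma loading prior |
| k clipping | 1e-6 | guards positive-definite S_r |
| prior mode | `exact` | see above |

Taxonomic correlations use equal-height levels: C_jj′ = s/R for s shared
consecutive top ranks of R (default 9, kingdom…species) — the tip
correlations of a unit-depth ultrametric taxonomy tree; per-level heights
are configurable, and an ultrametric Newick tree is accepted as an
alternative source. Climate covariates are centered/scaled before
polynomial expansion and log depth is centered (both optional): the
expansion is recorded so held-out samples replay the training
standardization exactly.

## Synthetic data

`simulate_community` draws from the model's own generative process: a
random nested taxonomy (bottom-up grouping, ~2 children per node) gives C;
vec(B) is drawn exactly from N(vec(ΓTᵀ), P ⊗ V) with ρ = 0.7 by default;
sites sit on a smooth environmental gradient (temperature rising,
precipitation falling along it); latent factors are standard normal with
loadings shrinking geometrically by factor index; species intercepts get
their spread from Γ's intercept row (−3.0) and V's intercept variance
(1.3²), which skews the community so most species are rare (~17% of
species reach prevalence 50/400 and ~45% prevalence 5). What the generator
deliberately does **not** emulate: sequencing error and chimeras, OTU
clustering artifacts, abundance information, spatially autocorrelated
residuals beyond the site effects, and — important for interpreting the
validation — any taxonomic structure in the latent-factor loadings, which
the model itself assumes iid across species. Passing tests therefore show
the machinery is correct under the model's own assumptions, not that the
model is well specified for any particular survey.

## Validation experiments and their scale

The desk-scale experiments (in `coral.experiments`, re-run by
`scripts/acceptance.py`) use a community of 400 samples at 30 sites with
360 species (~60 common, ~300 rare), 5 site + 3 sample factors, backbone
chains of 2 × 1500 (burn 500, thin 5) and per-species chains of 1500 kept
after 750 burn-in; these sizes were chosen once as realistic for the
hardware the package targets. On these conditions the package reproduces,
qualitatively, the behaviors the method is designed for: held-out AUC
ordering transfer > ablation > baseline with a decisive paired t-test; k
falling monotonically with the depth of the closest backbone relative;
transfer posteriors several-fold tighter than baseline posteriors for
species with ≤ 10 occurrences; and recovery of masked common species'
coefficients (group correlations ≈ 0.6–0.8 at 90% masking, ≈ 1 at 0%).

One behavior does **not** reproduce at this scale: mean held-out Tjur R²
of the transfer model falls slightly below the ablation (the ordering
against the baseline is preserved). Two properties of the synthetic
conditions explain it. First, the generator's latent loadings are iid
across species, so the informative prior's taxonomic borrowing on the
latent-factor coefficients contributes no signal, only shrinkage — and the
single ρ of the stage-2 fit is diluted (posterior mean ≈ 0.36 here) by
those unstructured rows, weakening k. Second, conditioning the backbone on
common species truncates the intercept distribution, so the prior centers
rare-species intercepts too high — visible as mild overprediction for the
rarest species in the posterior predictive checks, a known behavior of
this model family. Both effects are faithful to the construction, so the
discrepancy is reported rather than tuned away.

## Numerical choices

Truncated normals are drawn by inverse CDF in tail-stable form
(z = μ − Φ⁻¹((1−u)Φ(μ)) on the positive side), finite out to |μ| ≈ 38.
Correlation matrices are eigendecomposed with eigenvalues clipped at
1e-10 (a matrix needing more than 1e-8 of jitter is rejected). Posterior
covariance summaries are symmetrized as (Σ + Σᵀ)/2. k is clipped at 1e-6
with a warning if a draw goes non-positive. Negative log-likelihood clips
probabilities to [1e-12, 1 − 1e-12]. Factors are recentered to mean zero
each sweep to keep them identified against the intercept. CV folds are
balanced halves redrawn (up to 1000 times) until each fold holds ≥ 40% of
the species' occurrences, compared exactly as 5·count ≥ 2·prevalence;
species for which no split qualifies are flagged and excluded. Masking
rounds the masked count to nearest with ties toward fewer masked. Per-
species seeds are derived by CRC32 from (global seed, species id), so
batch results are identical under any parallel schedule. PRAUC is average
precision (step interpolation). The log-determinant metric uses the
posterior covariance over environmental coefficients only (excluding
intercept and latent columns); a full-matrix option exists.

## Known limitations

Rotation of the latent factor space is handled only at the point-estimate
step (Procrustes), not inside the chains; the stage-2 model conditions on
η̂ as fixed covariates and so understates latent-factor uncertainty, by
design. The transfer prior ignores the selection event that made a rare
species rare, biasing its intercept component upward. Species with zero
occurrences are retained (flagged) and their posterior essentially returns
the prior. The sampler targets hundreds to low thousands of backbone
species on one CPU; it does not attempt GPU-scale communities.
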