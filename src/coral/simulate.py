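"""Synthetic communities drawn from the model's own generative process.

The generator produces everything the pipeline ingests — occurrence matrix,
covariates, nested taxonomy — plus the underlying truth (coefficients,
latent factors, loadings), so parameter recovery and the transfer-learning
benefit can be measured without any real data.  Species coefficients are
drawn exactly from the backbone prior vec(B) ~ N(vec(Gamma T'), P (x) V),
with the prevalence skew ("most species are rare") controlled by the
intercept row of Gamma and its variance in V.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cholesky
from scipy.special import ndtr

from .data import (
    DEFAULT_RANKS,
    CommunityData,
    TaxonomyTable,
    build_design_matrix,
    build_taxonomic_correlation,
)


@dataclass
class SyntheticTruth:
    """Ground truth behind a simulated community."""

    B: np.ndarray  # (p, n_species) measured-covariate coefficients
    Gamma: np.ndarray  # (p, 1)
    V: np.ndarray  # (p, p)
    rho: float
    eta_site: np.ndarray  # (n_sites, q1)
    eta_sample: np.ndarray  # (n_samples, q2)
    lambda_site: np.ndarray  # (q1, n_species)
    lambda_sample: np.ndarray  # (q2, n_species)
    design_columns: list[str] = field(default_factory=list)
    species_ids: list[str] = field(default_factory=list)
    site_ids: list[str] = field(default_factory=list)
    seed: int = 0

    def expanded_coefficients(self) -> np.ndarray:
        """True coefficients on the expanded design [X, eta_site, eta_sample]."""
        return np.vstack([self.B, self.lambda_site, self.lambda_sample])


def _random_nested_taxonomy(
    n_species: int, rng: np.random.Generator, children_per_node: float = 2.0,
    ranks=DEFAULT_RANKS,
) -> TaxonomyTable:
    """Random nested taxonomy: species grouped into genera, genera into
    tribes, and so on up to a single kingdom."""
    R = len(ranks)
    species_ids = [f"sp_{j:04d}" for j in range(n_species)]
    # bottom-up group assignment; level r has ~ n_{r+1} / children groups
    assignments = np.empty((n_species, R), dtype=int)
    assignments[:, R - 1] = np.arange(n_species)
    n_groups = n_species
    for lvl in range(R - 2, -1, -1):
        n_parent = max(1, int(round(n_groups / children_per_node)))
        if lvl == 0:
            n_parent = 1
        parent_of = rng.integers(0, n_parent, size=n_groups)
        assignments[:, lvl] = parent_of[assignments[:, lvl + 1]]
        n_groups = n_parent
    table = pd.DataFrame(
        {
            rank: [f"{rank[:2]}_{assignments[j, l]}" for j in range(n_species)]
            for l, rank in enumerate(ranks)
        },
        index=pd.Index(species_ids, name="species_id"),
    )
    return TaxonomyTable(table, ranks=tuple(ranks))


def _default_gamma(columns: list[str], intercept_loc: float) -> np.ndarray:
    base = {
        "intercept": intercept_loc,
        "temperature": 0.4,
        "temperature_sq": -0.25,
        "precipitation": 0.3,
        "precipitation_sq": -0.15,
        "temp_x_precip": 0.1,
        "sin_annual": 0.2,
        "cos_annual": 0.2,
        "sin_semiannual": 0.1,
        "cos_semiannual": 0.1,
        "log_depth": 0.15,
    }
    return np.array([[base.get(c, 0.0)] for c in columns])


def simulate_community(
    n_samples: int = 400,
    n_sites: int = 30,
    n_species: int = 360,
    rho: float = 0.7,
    v_scale: float = 0.15,
    intercept_loc: float = -3.0,
    intercept_scale: float = 1.3,
    gamma: np.ndarray | None = None,
    n_factors_site: int = 5,
    n_factors_sample: int = 3,
    loading_scale: float = 0.6,
    loading_shrink: float = 0.6,
    children_per_node: float = 2.0,
    seed: int = 0,
) -> tuple[CommunityData, TaxonomyTable, SyntheticTruth]:
    """Simulate a community from the latent-factor probit model.

    Sites sit on a smooth environmental gradient (temperature increasing,
    precipitation decreasing along it); samples get uniform day-of-year and
    lognormal sequencing depth.  Coefficients follow the phylogenetically
    structured prior built on a random nested taxonomy; ``intercept_loc``
    shifts species intercepts so that most species are rare.
    """
    if n_sites < n_factors_site:
        raise ValueError("need at least as many sites as site-level factors")
    rng = np.random.default_rng(seed)
    tax = _random_nested_taxonomy(n_species, rng, children_per_node)
    species_ids = list(tax.species_ids)
    C = build_taxonomic_correlation(tax).to_numpy()

    # covariates: smooth site gradient
    site_ids = [f"site_{s:03d}" for s in range(n_sites)]
    u = rng.uniform(0.0, 1.0, size=n_sites)
    site_temp = 14.0 + 12.0 * u + rng.normal(0.0, 0.8, n_sites)
    site_prec = 500.0 + 1500.0 * (1.0 - u) + rng.normal(0.0, 120.0, n_sites)
    site_of_sample = rng.integers(0, n_sites, size=n_samples)
    covariates = pd.DataFrame(
        {
            "site": [site_ids[s] for s in site_of_sample],
            "day": rng.uniform(0.0, 365.0, n_samples),
            "temperature": site_temp[site_of_sample],
            "precipitation": site_prec[site_of_sample],
            "seq_depth": np.maximum(
                1, np.round(np.exp(rng.normal(np.log(2e4), 0.5, n_samples)))
            ).astype(int),
        },
        index=pd.Index([f"sample_{i:04d}" for i in range(n_samples)], name="sample_id"),
    )

    # design matrix exactly as the pipeline will build it
    from .data import DesignMatrixBuilder

    builder = DesignMatrixBuilder().fit(covariates)
    X_df = builder.transform(covariates)
    X = X_df.to_numpy()
    p = X.shape[1]

    # coefficients from the structured prior
    Gamma = _default_gamma(list(X_df.columns), intercept_loc) if gamma is None else np.asarray(gamma, dtype=float).reshape(p, 1)
    V = v_scale * np.eye(p)
    V[0, 0] = intercept_scale**2
    P = rho * C + (1.0 - rho) * np.eye(n_species)
    Lv = cholesky(V + 1e-12 * np.eye(p), lower=True)
    Lp = cholesky(P + 1e-10 * np.eye(n_species), lower=True)
    B = Gamma @ np.ones((1, n_species)) + Lv @ rng.standard_normal((p, n_species)) @ Lp.T

    # latent factors and shrinking loadings
    q1, q2 = n_factors_site, n_factors_sample
    eta_site = rng.standard_normal((n_sites, q1))
    eta_sample = rng.standard_normal((n_samples, q2))
    lam_sd_site = loading_scale * loading_shrink ** np.arange(q1)
    lam_sd_sample = loading_scale * loading_shrink ** np.arange(q2)
    lambda_site = rng.standard_normal((q1, n_species)) * lam_sd_site[:, None]
    lambda_sample = rng.standard_normal((q2, n_species)) * lam_sd_sample[:, None]

    L_lin = (
        X @ B
        + eta_site[site_of_sample] @ lambda_site
        + eta_sample @ lambda_sample
    )
    Y = (rng.random((n_samples, n_species)) < ndtr(L_lin)).astype(int)
    Y_df = pd.DataFrame(Y, index=covariates.index, columns=species_ids)

    cd = CommunityData(Y_df, covariates)
    truth = SyntheticTruth(
        B=B,
        Gamma=Gamma,
        V=V,
        rho=rho,
        eta_site=eta_site,
        eta_sample=eta_sample,
        lambda_site=lambda_site,
        lambda_sample=lambda_sample,
        design_columns=list(X_df.columns),
        species_ids=species_ids,
        site_ids=site_ids,
        seed=seed,
    )
    return cd, tax, truth


def mask_occurrences(
    cd: CommunityData, species_ids, fraction: float, seed: int = 0
) -> CommunityData:
    """Set a random ``fraction`` of each listed species' presences to absence.

    The count masked is rounded to nearest with ties toward fewer masked;
    absences are untouched.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    Y = cd.Y.copy()
    for sp in species_ids:
        presences = np.flatnonzero(Y[sp].to_numpy())
        n_mask = int(np.ceil(fraction * len(presences) - 0.5))
        if n_mask > 0:
            drop = rng.choice(presences, size=n_mask, replace=False)
            Y.iloc[drop, Y.columns.get_loc(sp)] = 0
    return CommunityData(Y, cd.covariates.copy())


def recovery_experiment(
    Y_common: pd.DataFrame,
    X_expanded: pd.DataFrame,
    bp_stage2,
    tax: TaxonomyTable,
    probit_cfg,
    fraction: float = 0.9,
    seed: int = 0,
    mode: str = "exact",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rarefaction check: mask the common species, refit them by transfer.

    Masks ``fraction`` of each common species' occurrences, rebuilds their
    transfer priors from the (full-data) stage-2 backbone posterior,
    refits each masked species independently, and correlates the refit
    posterior-mean coefficients with the backbone posterior means within
    three predictor groups: climatic+seasonal, sample-level latent factors
    and site-level latent factors.  Returns (per-group summary, per-species
    correlations).
    """
    from .data import CLIMATE_SEASON_COLUMNS
    from .prior import build_priors
    from .probit import ProbitFitConfig, fit_species, species_seed

    cols = list(X_expanded.columns)
    groups = {
        "climatic_seasonal": [c for c in cols if c in CLIMATE_SEASON_COLUMNS],
        "sample_latent": [c for c in cols if c.startswith("LF_sample_")],
        "site_latent": [c for c in cols if c.startswith("LF_site_")],
    }
    common_ids = [str(s) for s in bp_stage2.species_ids]
    B_hat = bp_stage2.B.mean(axis=0)  # (p, n_s) backbone posterior means

    rng = np.random.default_rng(seed)
    priors = build_priors(bp_stage2, tax, common_ids, mode=mode)

    records = []
    for j, sp in enumerate(common_ids):
        y = Y_common[sp].to_numpy().copy()
        presences = np.flatnonzero(y)
        n_mask = int(np.ceil(fraction * len(presences) - 0.5))
        if n_mask > 0:
            y[rng.choice(presences, size=n_mask, replace=False)] = 0
        cfg = ProbitFitConfig(
            n_samples=probit_cfg.n_samples, burn_in=probit_cfg.burn_in,
            seed=probit_cfg.seed, model_kind="coral",
        )
        summ = fit_species(
            y, X_expanded, cfg,
            prior_mean=priors[sp].m, prior_cov=priors[sp].S,
            species_id=sp, seed=species_seed(probit_cfg.seed, f"recovery:{sp}"),
        )
        row = {"species_id": sp}
        for gname, gcols in groups.items():
            idx = [cols.index(c) for c in gcols]
            if len(idx) < 2:
                row[gname] = np.nan
                continue
            a, b = summ.mu[idx], B_hat[idx, j]
            if np.std(a) == 0 or np.std(b) == 0:
                row[gname] = np.nan
            else:
                row[gname] = float(np.corrcoef(a, b)[0, 1])
        records.append(row)
    per_species = pd.DataFrame(records).set_index("species_id")
    report = pd.DataFrame(
        {
            "mean_correlation": per_species.mean(),
            "sd_correlation": per_species.std(),
            "n_species": per_species.notna().sum(),
        }
    )
    report.index.name = "predictor_group"
    return report, per_species
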