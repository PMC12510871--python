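"""Community data ingestion, taxonomic correlations and the design matrix.

The raw inputs are three aligned tables: a sample x species presence-absence
matrix, a per-sample covariate table (site, day of year, temperature,
precipitation, sequencing depth) and a per-species ranked taxonomy.  This
module validates them, turns the taxonomy into the correlation matrix C used
by the phylogenetically structured coefficient prior, expands the covariates
into the model design matrix, and partitions species into common and rare
sets by prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

DEFAULT_RANKS = (
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "subfamily",
    "tribe",
    "genus",
    "species",
)

REQUIRED_COVARIATES = ("site", "day", "temperature", "precipitation", "seq_depth")


@dataclass
class TaxonomyTable:
    """Ranked taxonomic assignments, one row per species.

    Pseudotaxon labels (placeholders for unclassifiable sequences) are
    ordinary values; every species must carry a non-empty label at every
    rank.
    """

    table: pd.DataFrame
    ranks: tuple[str, ...] = DEFAULT_RANKS

    def __post_init__(self) -> None:
        missing = [r for r in self.ranks if r not in self.table.columns]
        if missing:
            raise ValueError(f"taxonomy missing rank columns: {missing}")
        tab = self.table[list(self.ranks)]
        bad = tab.isna().any(axis=1) | (tab.astype(str) == "").any(axis=1)
        if bad.any():
            raise ValueError(
                "taxonomy has empty rank values for species: "
                f"{list(tab.index[bad][:10])}"
            )
        if self.table.index.duplicated().any():
            raise ValueError("duplicated species ids in taxonomy")

    @property
    def species_ids(self) -> pd.Index:
        return self.table.index

    @property
    def n_ranks(self) -> int:
        return len(self.ranks)

    def rank_codes(self, species: pd.Index | list | None = None) -> np.ndarray:
        """Integer-coded labels, shape (n_species, R); equal codes iff equal labels."""
        tab = self.table if species is None else self.table.loc[species]
        return np.column_stack(
            [pd.factorize(tab[r].astype(str))[0] for r in self.ranks]
        )


@dataclass
class CommunityData:
    """Aligned occurrence matrix, covariates and site map.

    Y is a sample x species DataFrame of 0/1 detections; ``covariates``
    carries one row per sample with the columns in REQUIRED_COVARIATES.
    """

    Y: pd.DataFrame
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.Y.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            bad = np.argwhere(~np.isin(vals, (0, 1)))[0]
            raise ValueError(
                f"occurrence matrix must be 0/1; offending cell "
                f"(sample={self.Y.index[bad[0]]!r}, species={self.Y.columns[bad[1]]!r}, "
                f"value={vals[bad[0], bad[1]]!r})"
            )
        if self.Y.index.duplicated().any():
            raise ValueError("duplicated sample ids")
        if self.Y.columns.duplicated().any():
            raise ValueError("duplicated species ids")
        missing_cov = [c for c in REQUIRED_COVARIATES if c not in self.covariates.columns]
        if missing_cov:
            raise ValueError(f"covariate table missing columns: {missing_cov}")
        if not self.Y.index.equals(self.covariates.index):
            missing = self.Y.index.difference(self.covariates.index)
            if len(missing):
                raise ValueError(f"samples without covariates: {list(missing[:10])}")
            self.covariates = self.covariates.loc[self.Y.index]
        if (self.covariates["seq_depth"] <= 0).any():
            bad = self.covariates.index[self.covariates["seq_depth"] <= 0]
            raise ValueError(f"non-positive sequencing depth for samples: {list(bad[:10])}")

    @property
    def n_samples(self) -> int:
        return self.Y.shape[0]

    @property
    def n_species(self) -> int:
        return self.Y.shape[1]

    @property
    def sample_ids(self) -> pd.Index:
        return self.Y.index

    @property
    def species_ids(self) -> pd.Index:
        return self.Y.columns

    @property
    def site_of_sample(self) -> pd.Series:
        return self.covariates["site"]

    def prevalence(self) -> pd.Series:
        return self.Y.sum(axis=0)

    def subset_samples(self, sample_ids) -> "CommunityData":
        return CommunityData(
            self.Y.loc[sample_ids].copy(), self.covariates.loc[sample_ids].copy()
        )


def load_community(
    occurrence_path,
    covariate_path,
    taxonomy_path,
    ranks: tuple[str, ...] = DEFAULT_RANKS,
    sep: str = "\t",
) -> tuple[CommunityData, TaxonomyTable]:
    """Read and cross-validate the three input tables.

    The occurrence table is samples-as-rows with a species-id header; a
    three-column (sample_id, species_id, value) triplet table is also
    accepted and pivoted to dense.  Species present in Y but absent from the
    taxonomy raise an error naming the offenders.
    """
    occ = pd.read_csv(occurrence_path, sep=sep, index_col=0)
    if list(occ.columns[:2]) == ["species_id", "value"] or occ.shape[1] == 2:
        triplets = pd.read_csv(occurrence_path, sep=sep)
        occ = (
            triplets.pivot_table(
                index=triplets.columns[0],
                columns=triplets.columns[1],
                values=triplets.columns[2],
                fill_value=0,
            )
            .astype(int)
        )
    cov = pd.read_csv(covariate_path, sep=sep, index_col=0)
    tax = pd.read_csv(taxonomy_path, sep=sep, index_col=0)
    taxonomy = TaxonomyTable(tax, ranks=ranks)
    missing = occ.columns.difference(taxonomy.species_ids)
    if len(missing):
        raise ValueError(f"species in occurrence matrix missing from taxonomy: {list(missing)}")
    cd = CommunityData(occ, cov)
    return cd, taxonomy


# ---------------------------------------------------------------------------
# Taxonomic correlation


def _shared_depth(codes_a: np.ndarray, codes_b: np.ndarray) -> np.ndarray:
    """Number of consecutive top ranks (from kingdom down) with equal labels.

    codes_a: (n, R), codes_b: (m, R) integer codes from a *shared* coding.
    Returns (n, m) counts in 0..R.
    """
    eq = codes_a[:, None, :] == codes_b[None, :, :]
    # stop counting at the first mismatch: cumulative product along ranks
    return np.cumprod(eq, axis=2).sum(axis=2)


def build_taxonomic_correlation(
    tax: TaxonomyTable,
    species_subset=None,
    level_heights: np.ndarray | None = None,
) -> pd.DataFrame:
    """Correlation matrix C over a species set from shared taxonomy.

    C[j, j'] = s / R where s is the number of consecutive top ranks at which
    the two species carry identical labels — the tip correlations of an
    ultrametric taxonomy tree of unit depth with R equal-height levels.
    ``level_heights`` (length R, summing to 1) overrides the equal-height
    convention.
    """
    species = tax.species_ids if species_subset is None else pd.Index(species_subset)
    if len(species) == 0:
        raise ValueError("empty species subset")
    codes = tax.rank_codes(species)
    C = _correlation_from_codes(codes, codes, tax.n_ranks, level_heights)
    np.fill_diagonal(C, 1.0)
    return pd.DataFrame(C, index=species, columns=species)


def cross_taxonomic_correlation(
    tax: TaxonomyTable,
    rows,
    cols,
    level_heights: np.ndarray | None = None,
) -> pd.DataFrame:
    """Rectangular block of the taxonomy correlation: rows x cols species."""
    rows = pd.Index(rows)
    cols = pd.Index(cols)
    both = rows.append(cols)
    codes = tax.rank_codes(both)
    ca, cb = codes[: len(rows)], codes[len(rows):]
    C = _correlation_from_codes(ca, cb, tax.n_ranks, level_heights)
    return pd.DataFrame(C, index=rows, columns=cols)


def _correlation_from_codes(ca, cb, n_ranks, level_heights):
    depth = _shared_depth(ca, cb)
    if level_heights is None:
        return depth / n_ranks
    h = np.asarray(level_heights, dtype=float)
    if h.shape != (n_ranks,) or not np.isclose(h.sum(), 1.0):
        raise ValueError("level_heights must have one entry per rank and sum to 1")
    cum = np.concatenate([[0.0], np.cumsum(h)])
    return cum[depth]


def correlation_from_newick(newick_path_or_str, species_subset=None) -> pd.DataFrame:
    """Tip correlations from an (assumed ultrametric) Newick phylogeny.

    C[a, b] = depth of the most recent common ancestor of tips a and b
    divided by total tree depth — shared branch length as a fraction of the
    root-to-tip distance.
    """
    import dendropy

    src = str(newick_path_or_str)
    if src.lstrip().startswith("("):
        tree = dendropy.Tree.get(data=src, schema="newick")
    else:
        tree = dendropy.Tree.get(path=src, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = list(tree.taxon_namespace)
    labels = [t.label for t in taxa]
    # root-to-tip depth via distance from seed node
    depths = {}
    for leaf in tree.leaf_node_iter():
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths[leaf.taxon.label] = d
    depth = max(depths.values())
    n = len(taxa)
    C = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            patristic = pdm.patristic_distance(taxa[i], taxa[j])
            # MRCA depth = tip depth - half patristic distance (ultrametric)
            C[i, j] = C[j, i] = max(0.0, (depth - patristic / 2.0) / depth)
    out = pd.DataFrame(C, index=labels, columns=labels)
    if species_subset is not None:
        out = out.loc[species_subset, species_subset]
    return out


# ---------------------------------------------------------------------------
# Design matrix

DESIGN_COLUMNS = (
    "intercept",
    "temperature",
    "temperature_sq",
    "precipitation",
    "precipitation_sq",
    "temp_x_precip",
    "sin_annual",
    "cos_annual",
    "sin_semiannual",
    "cos_semiannual",
    "log_depth",
)

ENVIRONMENTAL_COLUMNS = DESIGN_COLUMNS[1:]  # everything measured except intercept
CLIMATE_SEASON_COLUMNS = DESIGN_COLUMNS[1:10]  # climate polynomials + harmonics


class DesignMatrixBuilder(TransformerMixin, BaseEstimator):
    """Expand raw covariates into the model design matrix.

    Columns: intercept; centered/scaled temperature and precipitation with
    their squares and interaction; annual and semiannual harmonics of the
    day of year d (sin/cos of 2*pi*d/365 and 4*pi*d/365); log sequencing
    depth (centered by default).  Standardization parameters are learned in
    ``fit`` and replayed exactly in ``transform`` so held-out samples are
    mapped onto the training scale.
    """

    def __init__(self, standardize_climate: bool = True, center_log_depth: bool = True):
        self.standardize_climate = standardize_climate
        self.center_log_depth = center_log_depth

    def fit(self, covariates: pd.DataFrame, y=None):
        for c in ("day", "temperature", "precipitation", "seq_depth"):
            if c not in covariates.columns:
                raise ValueError(f"covariates missing column {c!r}")
        if (covariates["seq_depth"] <= 0).any():
            raise ValueError("sequencing depth must be strictly positive")
        if self.standardize_climate:
            self.center_ = {
                "temperature": float(covariates["temperature"].mean()),
                "precipitation": float(covariates["precipitation"].mean()),
            }
            self.scale_ = {
                "temperature": float(covariates["temperature"].std(ddof=0)) or 1.0,
                "precipitation": float(covariates["precipitation"].std(ddof=0)) or 1.0,
            }
        else:
            self.center_ = {"temperature": 0.0, "precipitation": 0.0}
            self.scale_ = {"temperature": 1.0, "precipitation": 1.0}
        self.log_depth_center_ = (
            float(np.log(covariates["seq_depth"]).mean()) if self.center_log_depth else 0.0
        )
        self.columns_ = list(DESIGN_COLUMNS)
        return self

    def transform(self, covariates: pd.DataFrame) -> pd.DataFrame:
        if (covariates["seq_depth"] <= 0).any():
            raise ValueError("sequencing depth must be strictly positive")
        t = (covariates["temperature"] - self.center_["temperature"]) / self.scale_["temperature"]
        p = (covariates["precipitation"] - self.center_["precipitation"]) / self.scale_["precipitation"]
        d = np.mod(covariates["day"].to_numpy(dtype=float), 365.0)
        w = 2.0 * np.pi * d / 365.0
        X = pd.DataFrame(
            {
                "intercept": np.ones(len(covariates)),
                "temperature": t,
                "temperature_sq": t**2,
                "precipitation": p,
                "precipitation_sq": p**2,
                "temp_x_precip": t * p,
                "sin_annual": np.sin(w),
                "cos_annual": np.cos(w),
                "sin_semiannual": np.sin(2 * w),
                "cos_semiannual": np.cos(2 * w),
                "log_depth": np.log(covariates["seq_depth"]) - self.log_depth_center_,
            },
            index=covariates.index,
        )
        return X


def build_design_matrix(
    cd: CommunityData,
    standardize_climate: bool = True,
    center_log_depth: bool = True,
) -> tuple[pd.DataFrame, DesignMatrixBuilder]:
    """Fit a DesignMatrixBuilder on the community's covariates and transform them."""
    builder = DesignMatrixBuilder(
        standardize_climate=standardize_climate, center_log_depth=center_log_depth
    ).fit(cd.covariates)
    return builder.transform(cd.covariates), builder


# ---------------------------------------------------------------------------
# Prevalence partition


@dataclass
class SpeciesPartition:
    """Common/rare split by prevalence (number of samples with a detection)."""

    common_ids: pd.Index
    rare_ids: pd.Index
    prevalence: pd.Series
    threshold: int
    zero_occurrence_ids: pd.Index = field(default_factory=lambda: pd.Index([]))


def split_by_prevalence(cd: CommunityData, threshold: int = 50) -> SpeciesPartition:
    """Partition species into common (prevalence >= threshold) and rare sets."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    prev = cd.prevalence()
    common = prev.index[prev >= threshold]
    rare = prev.index[prev < threshold]
    return SpeciesPartition(
        common_ids=common,
        rare_ids=rare,
        prevalence=prev,
        threshold=threshold,
        zero_occurrence_ids=prev.index[prev == 0],
    )
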