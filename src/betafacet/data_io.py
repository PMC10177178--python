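"""Input tables, validation, and run configuration.

The pipeline consumes four plain-text inputs:

* a sites x species incidence (presence/absence) CSV — sites are
  elevational bands, species are the regional pool;
* a rooted Newick tree with branch lengths on every edge;
* a species x trait CSV (body mass in grams, diet fractions, foraging
  stratum fractions);
* a sites x environment CSV (Bio1, Bio15, NDVI, PET, HFP and the band
  midpoint elevation).

All delimited files are comma-separated UTF-8 with a header row and the
site/species label in the first column.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger("betafacet")

DIET_COLUMNS = (
    "diet_invertebrates",
    "diet_vertebrates",
    "diet_fruits",
    "diet_nectar",
    "diet_seeds",
    "diet_other_plants",
)
STRATUM_COLUMNS = (
    "stratum_ground",
    "stratum_lower_canopy",
    "stratum_middle_canopy",
    "stratum_upper_canopy",
    "stratum_shrub",
)
ENV_COLUMNS = ("Bio1", "Bio15", "NDVI", "PET", "HFP")


class ValidationError(ValueError):
    """An input table violates a structural invariant."""


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Seeds and replicate counts for a full analysis run.

    Parameters
    ----------
    rng_seed
        Master seed; every stochastic stage derives its stream from it.
    n_null
        Randomized communities per null distribution (default 999).
    n_mantel_perm
        Permutations for Mantel tests (default 9999).
    n_trait_axes
        Principal axes retained for the functional trait space.
    ses_threshold
        |z| beyond which a standardized effect size is read as
        non-stochastic (default 1.96, the two-sided 5% normal bound).
    """

    rng_seed: int = 0
    n_null: int = 999
    n_mantel_perm: int = 9999
    n_trait_axes: int = 2
    ses_threshold: float = 1.96

    def __post_init__(self) -> None:
        if self.n_null < 1 or self.n_mantel_perm < 1 or self.n_trait_axes < 1:
            raise ValidationError("all replicate/axis counts must be >= 1")
        if self.ses_threshold <= 0:
            raise ValidationError("ses_threshold must be > 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Read a ``key = value`` plain-text config file."""
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs: dict = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in fields:
                raise ValidationError(f"unknown config key {key!r}")
            kwargs[key] = float(value) if key == "ses_threshold" else int(value)
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        lines = [
            f"{f.name} = {getattr(self, f.name)}" for f in dataclasses.fields(self)
        ]
        Path(path).write_text("\n".join(lines) + "\n")


class IncidenceMatrix:
    """Binary sites x species occupancy table.

    Wraps a pandas DataFrame with sites as rows and species as columns,
    all cells in {0, 1}.  This is the source of the shared/unique counts
    a, b, c from which every dissimilarity in the pipeline derives.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dupes = data.index[data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate site labels: {dupes}")
        if data.columns.has_duplicates:
            dupes = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate species labels: {dupes}")
        values = data.to_numpy()
        if not np.isfinite(values).all():
            raise ValidationError("incidence matrix contains non-numeric cells")
        if (values < 0).any():
            raise ValidationError("incidence matrix contains negative cells")
        if (values > 1).any():
            logger.warning(
                "incidence matrix contains abundances; coercing %d cells > 1 "
                "to presence",
                int((values > 1).sum()),
            )
        binary = (values > 0).astype(np.int8)
        empty_sites = np.flatnonzero(binary.sum(axis=1) == 0)
        if empty_sites.size:
            names = [str(data.index[i]) for i in empty_sites]
            raise ValidationError(f"site(s) with zero richness: {names}")
        empty_species = np.flatnonzero(binary.sum(axis=0) == 0)
        if empty_species.size:
            names = [str(data.columns[j]) for j in empty_species]
            raise ValidationError(f"species occurring nowhere: {names}")
        self._df = pd.DataFrame(
            binary, index=data.index.astype(str), columns=data.columns.astype(str)
        )

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def site_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self._df.columns)

    @property
    def matrix(self) -> np.ndarray:
        """Boolean occupancy array, shape (n_sites, n_species)."""
        return self._df.to_numpy(dtype=bool)

    @property
    def n_sites(self) -> int:
        return self._df.shape[0]

    @property
    def n_species(self) -> int:
        return self._df.shape[1]

    @property
    def richness(self) -> np.ndarray:
        return self._df.to_numpy().sum(axis=1)

    def site_species(self, site_id: str) -> set[str]:
        if site_id not in self._df.index:
            raise KeyError(f"unknown site {site_id!r}")
        row = self._df.loc[site_id]
        return set(row.index[row > 0])

    def subset_species(self, species: Sequence[str]) -> "IncidenceMatrix":
        return IncidenceMatrix(self._df.loc[:, list(species)])

    def __eq__(self, other: object) -> bool:
        return isinstance(other, IncidenceMatrix) and self._df.equals(other._df)

    def __repr__(self) -> str:
        return f"IncidenceMatrix({self.n_sites} sites x {self.n_species} species)"


def read_incidence(path: str | Path) -> IncidenceMatrix:
    """Read and validate a sites x species incidence CSV.

    Cells greater than 1 (abundances) are coerced to presence with a
    logged note; the analysis is incidence-based throughout.
    """
    df = pd.read_csv(path, index_col=0)
    return IncidenceMatrix(df)


def write_incidence(inc: IncidenceMatrix, path: str | Path) -> None:
    inc.df.to_csv(path)


def read_site_metadata(path: str | Path) -> pd.DataFrame:
    """Site metadata: one row per site, column ``elevation_mid`` (m)."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    if "elevation_mid" not in df.columns:
        raise ValidationError("site metadata needs an 'elevation_mid' column")
    if (df["elevation_mid"] <= 0).any():
        raise ValidationError("elevations must be strictly positive")
    return df


def read_environment(path: str | Path) -> pd.DataFrame:
    """Sites x environment table (Bio1, Bio15, NDVI, PET, HFP)."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    missing = [c for c in ENV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"environment table missing columns: {missing}")
    if df[list(ENV_COLUMNS)].isna().any().any():
        raise ValidationError("environment table contains missing values")
    return df


def read_traits(path: str | Path) -> pd.DataFrame:
    """Species x trait table: body mass plus diet and stratum fractions.

    Each fraction group is renormalized to sum to 1 when its raw sum is
    within [0.9, 1.1] (tolerating percentage-vs-fraction encodings);
    sums outside that band are rejected.
    """
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    return validate_traits(df)


def validate_traits(df: pd.DataFrame) -> pd.DataFrame:
    if df.index.has_duplicates:
        raise ValidationError("duplicate species labels in trait table")
    required = ["body_mass", *DIET_COLUMNS, *STRATUM_COLUMNS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"trait table missing columns: {missing}")
    if (df["body_mass"] <= 0).any():
        bad = df.index[df["body_mass"] <= 0].tolist()
        raise ValidationError(f"non-positive body mass for: {bad}")
    df = df.copy()
    for group in (list(DIET_COLUMNS), list(STRATUM_COLUMNS)):
        sums = df[group].sum(axis=1)
        # accept percentages (sum ~100) by rescaling first
        pct = (sums > 90) & (sums < 110)
        df.loc[pct, group] = df.loc[pct, group] / 100.0
        sums = df[group].sum(axis=1)
        bad = (sums < 0.9) | (sums > 1.1)
        if bad.any():
            raise ValidationError(
                f"fraction group {group[0].split('_')[0]} sums outside [0.9, 1.1] "
                f"for: {df.index[bad].tolist()}"
            )
        df[group] = df[group].div(sums, axis=0)
    return df


def write_traits(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index_label="species_id")


def read_tree(path: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree, requiring branch lengths on all edges."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValidationError(f"cannot parse Newick file {path}: {exc}") from exc
    return validate_tree(tree)


def validate_tree(tree: dendropy.Tree) -> dendropy.Tree:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValidationError(f"duplicate tip label {lab!r}")
        seen.add(lab)
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue  # root stem may legitimately lack a length
        if edge.length is None:
            head = edge.head_node
            name = (
                head.taxon.label
                if head.taxon is not None
                else f"internal node subtending {sorted(l.taxon.label for l in head.leaf_iter())}"
            )
            raise ValidationError(f"missing branch length on edge to {name}")
        if edge.length < 0:
            raise ValidationError("negative branch length")
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def prune_tree(tree: dendropy.Tree, keep: Sequence[str]) -> dendropy.Tree:
    """Prune to a species subset, preserving path lengths among kept tips."""
    keep = set(keep)
    pruned = tree.extract_tree_with_taxa_labels(
        keep, suppress_unifurcations=True
    )
    pruned_tips = {leaf.taxon.label for leaf in pruned.leaf_node_iter()}
    if pruned_tips != keep:
        raise ValidationError(
            f"species not on tree: {sorted(keep - pruned_tips)}"
        )
    return pruned


def align_inputs(
    inc: IncidenceMatrix,
    tree: dendropy.Tree,
    traits: pd.DataFrame | None = None,
) -> tuple[IncidenceMatrix, dendropy.Tree, pd.DataFrame | None]:
    """Intersect the species sets of the incidence matrix, tree and traits.

    Species present in the incidence matrix but missing from the tree or
    trait table are dropped everywhere (with a warning naming them),
    mirroring the usual practice of pruning a global tree to a regional
    species list.  Idempotent: aligning aligned inputs is a no-op.
    """
    inc_species = set(inc.species_ids)
    tip_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    surviving = inc_species & tip_labels
    if traits is not None:
        surviving &= set(traits.index)
    dropped = sorted(inc_species - surviving)
    if dropped:
        msg = f"dropping {len(dropped)} species absent from tree/traits: {dropped}"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    if len(surviving) < 2:
        raise ValidationError(
            "fewer than 2 species survive alignment of incidence/tree/traits"
        )
    keep = [s for s in inc.species_ids if s in surviving]
    inc_out = inc.subset_species(keep)
    tree_out = prune_tree(tree, keep) if tip_labels != surviving else tree
    traits_out = traits.loc[keep] if traits is not None else None
    return inc_out, tree_out, traits_out
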