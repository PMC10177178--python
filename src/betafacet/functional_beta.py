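"""Functional beta diversity from convex hulls in a reduced trait space.

Species are placed in a low-dimensional morpho-ecological space by PCA
of their traits (log10 body mass, diet fractions, foraging-stratum
fractions; all columns standardized).  Each community is the convex
hull of its species' coordinates, and the Sørensen partition is applied
to hull volumes: ``a`` the intersection volume of the two hulls, ``b``
and ``c`` the volumes each hull has outside the other.

The default (and only exactly-supported) dimensionality is 2, where
hulls are convex polygons and the intersection is computed by polygon
clipping.  Communities with fewer than dim+1 species, or whose points
are (near-)collinear, have no hull of positive volume; such sites are
flagged and their pairs reported as missing rather than imputed.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Polygon

from .data_io import DIET_COLUMNS, STRATUM_COLUMNS, IncidenceMatrix
from .taxonomic_beta import (
    PairCounts,
    PairwiseBetaSet,
    _as_beta_set,
    partition_from_counts,
)

logger = logging.getLogger("betafacet")

_COLLINEAR_TOL = 1e-9


@dataclasses.dataclass
class TraitSpace:
    """Species coordinates on the retained principal axes."""

    coordinates: pd.DataFrame  # species x axes
    variance_explained: np.ndarray  # fraction per retained axis
    loadings: pd.DataFrame  # trait x axes

    @property
    def species_ids(self) -> list[str]:
        return list(self.coordinates.index)

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


@dataclasses.dataclass
class HullGeometry:
    """Convex hull of one community in trait space (2D: a polygon)."""

    site_id: str
    vertices: np.ndarray | None  # hull vertices in order, or None if excluded
    volume: float
    excluded: bool
    reason: str = ""

    @property
    def polygon(self) -> Polygon:
        if self.excluded:
            raise ValueError(f"site {self.site_id!r} has no valid hull: {self.reason}")
        return Polygon(self.vertices)


def encode_traits(traits: pd.DataFrame) -> pd.DataFrame:
    """Numeric trait block: log10 body mass + raw fraction columns."""
    cols = {"log10_body_mass": np.log10(traits["body_mass"].to_numpy(dtype=float))}
    for c in (*DIET_COLUMNS, *STRATUM_COLUMNS):
        cols[c] = traits[c].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=traits.index)


def build_trait_space(traits: pd.DataFrame, n_axes: int = 2) -> TraitSpace:
    """PCA of the standardized trait block, keeping ``n_axes`` axes.

    Constant columns carry no information and are dropped with a
    warning before standardization.  Computed by singular value
    decomposition of the centered, unit-variance matrix.
    """
    x = encode_traits(traits)
    sd = x.std(axis=0, ddof=1)
    # tolerance absorbs float dust in nominally identical columns
    tol = 1e-10 * np.maximum(1.0, x.abs().max(axis=0))
    constant = sd[sd <= tol].index.tolist()
    if constant:
        logger.warning("dropping constant trait columns: %s", constant)
        x = x.drop(columns=constant)
        sd = sd.drop(index=constant)
    if x.shape[1] < n_axes:
        raise ValueError(
            f"only {x.shape[1]} informative trait columns for {n_axes} axes"
        )
    if x.shape[0] < n_axes + 1:
        raise ValueError("need at least n_axes + 1 species for a PCA")
    z = (x - x.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
    scores = u * s
    var = s**2 / (z.shape[0] - 1)
    frac = var / var.sum()
    axes = [f"PC{k + 1}" for k in range(n_axes)]
    return TraitSpace(
        coordinates=pd.DataFrame(scores[:, :n_axes], index=x.index, columns=axes),
        variance_explained=frac[:n_axes],
        loadings=pd.DataFrame(vt[:n_axes].T, index=x.columns, columns=axes),
    )


def site_hull(space: TraitSpace, species: set[str], site_id: str = "") -> HullGeometry:
    """Convex hull of one community's species in the trait space.

    Communities below dim+1 species or degenerate (collinear) point
    configurations are flagged ``excluded`` rather than erroring: the
    functional facet simply has no hull volume for them.
    """
    species = sorted(species)
    missing = [s for s in species if s not in space.coordinates.index]
    if missing:
        raise KeyError(f"species not in trait space: {missing}")
    pts = space.coordinates.loc[species].to_numpy()
    need = space.n_axes + 1
    if len(species) < need:
        return HullGeometry(site_id, None, 0.0, True, f"fewer than {need} species")
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return HullGeometry(site_id, None, 0.0, True, "degenerate point configuration")
    if hull.volume <= _COLLINEAR_TOL:
        return HullGeometry(site_id, None, 0.0, True, "degenerate point configuration")
    return HullGeometry(site_id, pts[hull.vertices], float(hull.volume), False)


def hull_pair_counts(h1: HullGeometry, h2: HullGeometry) -> PairCounts:
    """Volume analogs of a/b/c: intersection and one-sided remainders."""
    if h1.excluded or h2.excluded:
        raise ValueError("cannot intersect an excluded hull")
    p1, p2 = h1.polygon, h2.polygon
    inter = p1.intersection(p2).area
    # snap float dust so true containment yields an exact zero remainder
    tol = 1e-12 * max(p1.area, p2.area)
    b = p1.area - inter
    c = p2.area - inter
    return PairCounts(
        a=inter, b=b if b > tol else 0.0, c=c if c > tol else 0.0
    )


def pairwise_functional(
    inc: IncidenceMatrix,
    space: TraitSpace,
    hulls: dict[str, HullGeometry] | None = None,
) -> PairwiseBetaSet:
    """Functional Sørensen partition over all usable site pairs.

    Pairs involving an excluded site are NaN in every component and are
    propagated as missing downstream, never imputed.
    """
    if hulls is None:
        hulls = {s: site_hull(space, inc.site_species(s), s) for s in inc.site_ids}
    usable = [s for s in inc.site_ids if not hulls[s].excluded]
    if len(usable) < 2:
        raise ValueError("fewer than 2 sites have a valid trait hull")
    n = inc.n_sites
    total = np.full((n, n), np.nan)
    turnover = np.full((n, n), np.nan)
    nestedness = np.full((n, n), np.nan)
    idx = {s: k for k, s in enumerate(inc.site_ids)}
    for i_pos in range(len(usable)):
        for j_pos in range(i_pos + 1, len(usable)):
            si, sj = usable[i_pos], usable[j_pos]
            part = partition_from_counts(
                hull_pair_counts(hulls[si], hulls[sj]), facet="functional"
            )
            i, j = idx[si], idx[sj]
            total[i, j] = total[j, i] = part.total
            turnover[i, j] = turnover[j, i] = part.turnover
            nestedness[i, j] = nestedness[j, i] = part.nestedness
    return _as_beta_set("functional", inc.site_ids, total, turnover, nestedness)


def excluded_sites(hulls: dict[str, HullGeometry]) -> pd.DataFrame:
    """Exclusion report: flagged sites and why."""
    rows = [
        {"site_id": s, "reason": h.reason}
        for s, h in hulls.items()
        if h.excluded
    ]
    return pd.DataFrame(rows, columns=["site_id", "reason"])


def pooled_hull_volume(space: TraitSpace, species: set[str]) -> float:
    """Hull volume of a pooled species set (the functional 'gamma')."""
    h = site_hull(space, species, "pooled")
    return h.volume
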