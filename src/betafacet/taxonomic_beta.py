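"""Pairwise Sørensen-family partition of taxonomic beta diversity.

For two sites with ``a`` shared species, ``b`` unique to the first and
``c`` unique to the second, total dissimilarity (Sørensen) decomposes
additively into a turnover component (Simpson dissimilarity, replacement
of species between sites) and a nestedness-resultant component (richness
difference of otherwise nested biotas):

    beta_sor = (b + c) / (2a + b + c)
    beta_sim = min(b, c) / (a + min(b, c))
    beta_sne = [(max - min) / (2a + min + max)] * [a / (a + min)]

with beta_sim + beta_sne = beta_sor exactly.  The same partition is
applied verbatim to branch lengths (phylogenetic facet) and convex-hull
volumes (functional facet), so the counts here are floats.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd

from .data_io import IncidenceMatrix

FACETS = ("taxonomic", "phylogenetic", "functional")
COMPONENTS = ("turnover", "nestedness", "total")


@dataclasses.dataclass(frozen=True)
class PairCounts:
    """Shared/unique counts for one unordered site pair.

    ``a`` species common to both sites, ``b`` unique to the first,
    ``c`` unique to the second.  Values may be branch lengths or hull
    volumes for the non-taxonomic facets.
    """

    a: float
    b: float
    c: float


@dataclasses.dataclass(frozen=True)
class BetaPartition:
    total: float
    turnover: float
    nestedness: float
    facet: str = "taxonomic"


@dataclasses.dataclass
class PairwiseBetaSet:
    """Symmetric dissimilarity matrices for one facet.

    ``total``, ``turnover`` and ``nestedness`` are site x site
    DataFrames with zero diagonals; NaN marks pairs that could not be
    computed (e.g. functional exclusions).
    """

    facet: str
    total: pd.DataFrame
    turnover: pd.DataFrame
    nestedness: pd.DataFrame

    @property
    def site_ids(self) -> list[str]:
        return list(self.total.index)

    def component(self, name: str) -> pd.DataFrame:
        if name not in COMPONENTS:
            raise KeyError(f"unknown component {name!r}")
        return getattr(self, name)

    def condensed(self, name: str) -> np.ndarray:
        """Lower-triangle (pair-level) vector of one component."""
        m = self.component(name).to_numpy()
        i, j = np.tril_indices(m.shape[0], k=-1)
        return m[i, j]

    def pair_frame(self) -> pd.DataFrame:
        """Long-format table: site_i, site_j, facet, component, value."""
        rows = []
        sites = self.site_ids
        for j, i in itertools.combinations(range(len(sites)), 2):
            for comp in COMPONENTS:
                rows.append(
                    {
                        "site_i": sites[i],
                        "site_j": sites[j],
                        "facet": self.facet,
                        "component": comp,
                        "observed": self.component(comp).iat[i, j],
                    }
                )
        return pd.DataFrame(rows)

    def mean_components(self) -> dict[str, float]:
        """Mean of pairwise values per component (NaN pairs dropped)."""
        return {c: float(np.nanmean(self.condensed(c))) for c in COMPONENTS}


def pair_counts(inc: IncidenceMatrix, site1: str, site2: str) -> PairCounts:
    """Exact set-arithmetic a/b/c for two sites of an incidence matrix."""
    s1 = inc.site_species(site1)
    s2 = inc.site_species(site2)
    return PairCounts(
        a=len(s1 & s2), b=len(s1 - s2), c=len(s2 - s1)
    )


def partition_from_counts(pc: PairCounts, facet: str = "taxonomic") -> BetaPartition:
    """Additive Sørensen partition of a/b/c into turnover + nestedness."""
    a, b, c = float(pc.a), float(pc.b), float(pc.c)
    if min(a, b, c) < 0:
        raise ValueError("counts must be nonnegative")
    if a + b <= 0 or a + c <= 0:
        raise ValueError("partition undefined when a site is empty")
    lo, hi = min(b, c), max(b, c)
    total = (b + c) / (2 * a + b + c)
    turnover = lo / (a + lo) if (a + lo) > 0 else 0.0
    nestedness = (
        ((hi - lo) / (2 * a + lo + hi)) * (a / (a + lo)) if (a + lo) > 0 else 0.0
    )
    return BetaPartition(total=total, turnover=turnover, nestedness=nestedness, facet=facet)


def _partition_arrays(
    a: np.ndarray, b: np.ndarray, c: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized partition; returns (total, turnover, nestedness)."""
    a = np.asarray(a, dtype=float)
    lo = np.minimum(b, c).astype(float)
    hi = np.maximum(b, c).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        total = np.where(lo + hi > 0, (lo + hi) / (2 * a + lo + hi), 0.0)
        turnover = np.where(a + lo > 0, lo / (a + lo), 0.0)
        nestedness = np.where(
            a + lo > 0, ((hi - lo) / (2 * a + lo + hi)) * (a / (a + lo)), 0.0
        )
    return total, turnover, nestedness


def _as_beta_set(
    facet: str,
    site_ids: list[str],
    total: np.ndarray,
    turnover: np.ndarray,
    nestedness: np.ndarray,
) -> PairwiseBetaSet:
    frames = []
    for m in (total, turnover, nestedness):
        m = np.asarray(m, dtype=float)
        np.fill_diagonal(m, 0.0)
        frames.append(pd.DataFrame(m, index=site_ids, columns=site_ids))
    return PairwiseBetaSet(facet, *frames)


def pairwise_taxonomic(inc: IncidenceMatrix) -> PairwiseBetaSet:
    """Sørensen partition for all unordered site pairs."""
    if inc.n_sites < 2:
        raise ValueError("need at least 2 sites")
    m = inc.matrix.astype(np.int64)
    shared = m @ m.T
    rich = m.sum(axis=1)
    b = rich[:, None] - shared
    c = rich[None, :] - shared
    total, turnover, nestedness = _partition_arrays(shared, b, c)
    return _as_beta_set("taxonomic", inc.site_ids, total, turnover, nestedness)


def multiple_site_taxonomic(inc: IncidenceMatrix) -> dict[str, float]:
    """Baselga's multiple-site Sørensen partition over all sites at once.

    Provided as an alternative summary to the mean of pairwise values;
    the two are related but not identical.
    """
    m = inc.matrix.astype(np.int64)
    rich = m.sum(axis=1)
    shared = m @ m.T
    i, j = np.tril_indices(inc.n_sites, k=-1)
    b = rich[i] - shared[i, j]  # unique to site i within the pair
    c = rich[j] - shared[i, j]
    sum_min = float(np.minimum(b, c).sum())
    sum_max = float(np.maximum(b, c).sum())
    s_total = float(rich.sum())
    s_gamma = float(inc.n_species)  # every species occurs somewhere
    core = s_total - s_gamma  # sum of pairwise-shared richness surplus
    beta_sim = sum_min / (core + sum_min) if core + sum_min > 0 else 0.0
    beta_sor = (
        (sum_min + sum_max) / (2 * core + sum_min + sum_max)
        if (2 * core + sum_min + sum_max) > 0
        else 0.0
    )
    return {
        "turnover": beta_sim,
        "nestedness": beta_sor - beta_sim,
        "total": beta_sor,
    }


def gamma_contribution(alpha_values: np.ndarray, gamma: float) -> float:
    """Flagged interpretation: share of regional diversity attributable
    to among-site variation, computed as 1 - mean(alpha)/gamma.

    This is a proportional (multiplicative) beta reading and is NOT one
    of the Sørensen-family partitions; it is reported separately.
    """
    alpha_values = np.asarray(alpha_values, dtype=float)
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return float(1.0 - alpha_values.mean() / gamma)
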