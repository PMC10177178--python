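"""Richness-preserving null model and standardized effect sizes.

The null randomizes community membership while keeping each site's
observed species richness: every site independently receives a uniform
draw (without replacement) of its richness from the full species pool.
Species occurrence frequencies are deliberately NOT preserved — the
null asks what dissimilarity richness alone would produce.

For each site pair and each partition component, the observed value is
standardized against the null distribution:

    SES = (observed - mean(null)) / sd(null)

SES > 1.96 is read as overdispersion (limiting similarity), SES < -1.96
as clustering (environmental filtering), and values in between as
stochastic assembly (strict inequalities; an SES of exactly 1.96 is
stochastic).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .data_io import IncidenceMatrix
from .taxonomic_beta import COMPONENTS, PairwiseBetaSet

BetaFunction = Callable[[IncidenceMatrix], PairwiseBetaSet]


@dataclasses.dataclass
class SESRecord:
    site_i: str
    site_j: str
    facet: str
    component: str
    observed: float
    null_mean: float
    null_sd: float
    ses: float  # NaN when undefined (sd == 0 or missing observation)
    classification: str  # overdispersed / clustered / stochastic / undefined
    n_null_effective: int


def classify_ses(ses: float, threshold: float = 1.96) -> str:
    """Assembly-process reading of one standardized effect size."""
    if not np.isfinite(ses):
        return "undefined"
    if ses > threshold:
        return "overdispersed"
    if ses < -threshold:
        return "clustered"
    return "stochastic"


def randomize_community(
    inc: IncidenceMatrix, seed: int | np.random.Generator
) -> IncidenceMatrix:
    """One richness-preserving randomization of the incidence matrix."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    occ = _randomize_array(inc.matrix, inc.richness, rng)
    df = pd.DataFrame(
        occ.astype(np.int8), index=inc.df.index, columns=inc.df.columns
    )
    # a species may vanish from every site; IncidenceMatrix would reject
    # that, so bypass validation — richness rows are guaranteed non-empty.
    out = object.__new__(IncidenceMatrix)
    out._df = df
    return out


def _randomize_array(
    occ: np.ndarray, richness: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    n, p = occ.shape
    out = np.zeros((n, p), dtype=bool)
    for site in range(n):
        out[site, rng.choice(p, size=int(richness[site]), replace=False)] = True
    return out


def frequency_weighted_randomize(
    inc: IncidenceMatrix, seed: int | np.random.Generator
) -> IncidenceMatrix:
    """Sensitivity variant: draw species with probability proportional
    to their observed occurrence frequency (richness still fixed)."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    occ = inc.matrix
    freq = occ.sum(axis=0).astype(float)
    prob = freq / freq.sum()
    out = np.zeros_like(occ)
    for site in range(occ.shape[0]):
        out[site, rng.choice(occ.shape[1], size=int(inc.richness[site]), replace=False, p=prob)] = True
    df = pd.DataFrame(
        out.astype(np.int8), index=inc.df.index, columns=inc.df.columns
    )
    res = object.__new__(IncidenceMatrix)
    res._df = df
    return res


def null_matrices(
    inc: IncidenceMatrix,
    n_null: int,
    seed: int,
    randomizer: Callable[[IncidenceMatrix, np.random.Generator], IncidenceMatrix]
    | None = None,
) -> list[IncidenceMatrix]:
    """The shared randomization stream: one list of ``n_null`` matrices,
    reused across facets within a run so facet SES values are
    comparable."""
    rng = np.random.default_rng(seed)
    randomizer = randomizer or randomize_community
    return [randomizer(inc, rng) for _ in range(n_null)]


def ses_pairwise(
    inc: IncidenceMatrix,
    beta_fn: BetaFunction,
    facet: str,
    n_null: int = 999,
    seed: int = 0,
    threshold: float = 1.96,
    nulls: Sequence[IncidenceMatrix] | None = None,
) -> list[SESRecord]:
    """Standardized effect sizes for every pair and component.

    ``beta_fn`` is the facet machinery (e.g. ``pairwise_taxonomic`` or
    a closure over a tree / trait space); it is applied unchanged to
    the observed and to each randomized matrix.  Pairs that a replicate
    cannot evaluate (functional exclusions) are skipped for that
    replicate, and the effective null size is reported per pair.
    """
    if n_null < 2 and nulls is None:
        raise ValueError("need at least 2 null replicates")
    observed = beta_fn(inc)
    sites = observed.site_ids
    n = len(sites)
    if nulls is None:
        nulls = null_matrices(inc, n_null, seed)
    stacks = {
        comp: np.full((len(nulls), n, n), np.nan) for comp in COMPONENTS
    }
    for r, null_inc in enumerate(nulls):
        try:
            nb = beta_fn(null_inc)
        except ValueError:
            continue  # replicate unusable for this facet (e.g. <2 hulls)
        for comp in COMPONENTS:
            stacks[comp][r] = nb.component(comp).to_numpy()
    records: list[SESRecord] = []
    tri = [(i, j) for i in range(n) for j in range(i + 1, n)]
    for comp in COMPONENTS:
        obs_m = observed.component(comp).to_numpy()
        arr = stacks[comp]
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pairs
            mean = np.nanmean(arr, axis=0)
            sd = np.nanstd(arr, axis=0, ddof=1)
        eff = np.sum(~np.isnan(arr), axis=0)
        for i, j in tri:
            obs = obs_m[i, j]
            m, s, k = mean[i, j], sd[i, j], int(eff[i, j])
            if not np.isfinite(obs) or k < 2 or not np.isfinite(s) or s == 0:
                ses = np.nan
            else:
                ses = (obs - m) / s
            records.append(
                SESRecord(
                    site_i=sites[i],
                    site_j=sites[j],
                    facet=facet,
                    component=comp,
                    observed=float(obs),
                    null_mean=float(m) if np.isfinite(m) else np.nan,
                    null_sd=float(s) if np.isfinite(s) else np.nan,
                    ses=float(ses) if np.isfinite(ses) else np.nan,
                    classification=classify_ses(ses, threshold),
                    n_null_effective=k,
                )
            )
    return records


def ses_frame(records: Sequence[SESRecord]) -> pd.DataFrame:
    """Long-format SES table (one row per pair x facet x component)."""
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def ses_summary(
    records: Sequence[SESRecord], threshold: float = 1.96
) -> pd.DataFrame:
    """Per facet/component: fractions of pairs below -threshold, within
    [-threshold, threshold], and above threshold.  Components with no
    defined SES are reported as missing (NaN), not as zero."""
    if not records:
        raise ValueError("no SES records")
    df = ses_frame(list(records))
    rows = []
    for (facet, comp), grp in df.groupby(["facet", "component"], sort=False):
        ses = grp["ses"].to_numpy()
        ok = np.isfinite(ses)
        n_ok = int(ok.sum())
        if n_ok == 0:
            frac = (np.nan, np.nan, np.nan)
        else:
            s = ses[ok]
            frac = (
                float((s < -threshold).mean()),
                float(((s >= -threshold) & (s <= threshold)).mean()),
                float((s > threshold).mean()),
            )
        rows.append(
            {
                "facet": facet,
                "component": comp,
                "frac_clustered": frac[0],
                "frac_stochastic": frac[1],
                "frac_overdispersed": frac[2],
                "n_pairs": n_ok,
            }
        )
    return pd.DataFrame(rows)
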