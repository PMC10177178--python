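"""End-to-end orchestration: partitions, nulls, gradient statistics.

``run_all`` executes the full analysis — the three facet partitions,
the richness null with standardized effect sizes, Mantel tests against
elevational and environmental distance, hierarchical partitioning of
the environmental predictors, distance–decay regressions of observed
and standardized dissimilarities, cross-component rank-sum comparisons,
and per-trait phylogenetic signal — and collects every table in an
:class:`AnalysisReport`.  One master seed drives the whole run through
fixed substreams, so reports regenerate identically.
"""

from __future__ import annotations

import dataclasses
import itertools
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import functional_beta, gradient_stats, null_models, phylo_beta, phylo_signal
from .data_io import ENV_COLUMNS, IncidenceMatrix, RunConfig, align_inputs
from .synthetic_data import SimulationSpec, SyntheticDataset, simulate_dataset
from .taxonomic_beta import (
    COMPONENTS,
    PairwiseBetaSet,
    gamma_contribution,
    multiple_site_taxonomic,
    pairwise_taxonomic,
)


@dataclasses.dataclass
class AnalysisReport:
    """Every table the pipeline produces, plus provenance."""

    config: RunConfig
    beta_sets: dict[str, PairwiseBetaSet]
    summary: pd.DataFrame  # facet x component means (+ multi-site, gamma share)
    ses_records: pd.DataFrame  # long-format SES table
    ses_fractions: pd.DataFrame
    comparisons: pd.DataFrame  # rank-sum table across components/facets
    mantel_elevation: pd.DataFrame
    mantel_environment: pd.DataFrame
    hier_partition: pd.DataFrame
    decay_observed: pd.DataFrame
    decay_ses: pd.DataFrame
    lambda_signal: pd.DataFrame
    excluded_sites: pd.DataFrame
    provenance: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pairwise = pd.concat(
            [bs.pair_frame() for bs in self.beta_sets.values()], ignore_index=True
        )
        merged = pairwise.merge(
            self.ses_records,
            on=["site_i", "site_j", "facet", "component"],
            how="left",
            suffixes=("", "_ses"),
        )
        cols = [
            "site_i", "site_j", "facet", "component", "observed",
            "ses", "null_mean", "null_sd", "classification",
        ]
        merged[cols].to_csv(outdir / "pairwise_dissimilarity.csv", index=False)
        self.summary.to_csv(outdir / "summary.csv", index=False)
        self.ses_fractions.to_csv(outdir / "ses_fractions.csv", index=False)
        self.comparisons.to_csv(outdir / "comparisons.csv", index=False)
        self.mantel_elevation.to_csv(outdir / "mantel_elevation.csv", index=False)
        self.mantel_environment.to_csv(outdir / "mantel_environment.csv", index=False)
        self.hier_partition.to_csv(outdir / "hierarchical_partitioning.csv", index=False)
        self.decay_observed.to_csv(outdir / "decay_observed.csv", index=False)
        self.decay_ses.to_csv(outdir / "decay_ses.csv", index=False)
        self.lambda_signal.to_csv(outdir / "phylogenetic_signal.csv", index=False)
        self.excluded_sites.to_csv(outdir / "excluded_sites.csv", index=False)
        prov = pd.DataFrame([self.provenance])
        prov.to_csv(outdir / "provenance.csv", index=False)


def _substreams(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _ses_matrix(
    ses: pd.DataFrame, facet: str, component: str, site_ids: list[str]
) -> pd.DataFrame:
    m = pd.DataFrame(np.nan, index=site_ids, columns=site_ids)
    sub = ses[(ses["facet"] == facet) & (ses["component"] == component)]
    for _, row in sub.iterrows():
        m.loc[row["site_i"], row["site_j"]] = row["ses"]
        m.loc[row["site_j"], row["site_i"]] = row["ses"]
    np.fill_diagonal(m.values, 0.0)
    return m


def run_all(
    config: RunConfig,
    dataset: SyntheticDataset | None = None,
    sim_spec: SimulationSpec | None = None,
    incidence: IncidenceMatrix | None = None,
    metadata: pd.DataFrame | None = None,
    tree: dendropy.Tree | None = None,
    traits: pd.DataFrame | None = None,
    environment: pd.DataFrame | None = None,
    outdir: str | Path | None = None,
) -> AnalysisReport:
    """Run the full analysis from a dataset, a simulation spec, or the
    four input tables.  Traits (and hence the functional facet) are
    optional; without them a two-facet report is produced."""
    if dataset is None and sim_spec is not None:
        dataset = simulate_dataset(sim_spec)
    if dataset is not None:
        incidence, metadata = dataset.incidence, dataset.metadata
        tree, traits, environment = dataset.tree, dataset.traits, dataset.environment
    if incidence is None or metadata is None or tree is None or environment is None:
        raise ValueError("need a dataset, a simulation spec, or explicit inputs")
    incidence, tree, traits = align_inputs(incidence, tree, traits)
    seeds = _substreams(config.rng_seed, 4)

    # ---- observed partitions ------------------------------------------
    beta_sets: dict[str, PairwiseBetaSet] = {}
    beta_sets["taxonomic"] = pairwise_taxonomic(incidence)
    beta_sets["phylogenetic"] = phylo_beta.pairwise_phylogenetic(incidence, tree)
    hulls = None
    space = None
    excluded = pd.DataFrame(columns=["site_id", "reason"])
    if traits is not None:
        space = functional_beta.build_trait_space(traits, config.n_trait_axes)
        hulls = {
            s: functional_beta.site_hull(space, incidence.site_species(s), s)
            for s in incidence.site_ids
        }
        beta_sets["functional"] = functional_beta.pairwise_functional(
            incidence, space, hulls
        )
        excluded = functional_beta.excluded_sites(hulls)

    # ---- headline summary ---------------------------------------------
    rows = []
    for facet, bs in beta_sets.items():
        means = bs.mean_components()
        for comp in COMPONENTS:
            rows.append(
                {
                    "facet": facet,
                    "component": comp,
                    "mean_pairwise": means[comp],
                    "statistic": "mean_pairwise",
                }
            )
    for comp, value in multiple_site_taxonomic(incidence).items():
        rows.append(
            {
                "facet": "taxonomic",
                "component": comp,
                "mean_pairwise": value,
                "statistic": "multiple_site",
            }
        )
    # flagged interpretation: share of regional (gamma) diversity among sites
    rows.append(
        {
            "facet": "taxonomic",
            "component": "total",
            "mean_pairwise": gamma_contribution(
                incidence.richness, incidence.n_species
            ),
            "statistic": "gamma_share_1_minus_alpha_over_gamma",
        }
    )
    pd_sites = np.array(
        [phylo_beta.faith_pd(tree, incidence.site_species(s)) for s in incidence.site_ids]
    )
    pd_gamma = phylo_beta.faith_pd(tree, set(incidence.species_ids))
    rows.append(
        {
            "facet": "phylogenetic",
            "component": "total",
            "mean_pairwise": gamma_contribution(pd_sites, pd_gamma),
            "statistic": "gamma_share_1_minus_alpha_over_gamma",
        }
    )
    if space is not None:
        vols = np.array(
            [
                hulls[s].volume
                for s in incidence.site_ids
                if not hulls[s].excluded
            ]
        )
        vol_gamma = functional_beta.pooled_hull_volume(
            space, set(incidence.species_ids)
        )
        if vols.size and vol_gamma > 0:
            rows.append(
                {
                    "facet": "functional",
                    "component": "total",
                    "mean_pairwise": gamma_contribution(vols, vol_gamma),
                    "statistic": "gamma_share_1_minus_alpha_over_gamma",
                }
            )
    summary = pd.DataFrame(rows)

    # ---- null model / SES ---------------------------------------------
    nulls = null_models.null_matrices(incidence, config.n_null, seeds[0])
    all_records = []
    facet_fns = {"taxonomic": pairwise_taxonomic}
    edge_table = phylo_beta.EdgeTable(tree, incidence.species_ids)
    facet_fns["phylogenetic"] = lambda m: phylo_beta.pairwise_phylogenetic(
        m, tree, table=edge_table
    )
    if space is not None:
        facet_fns["functional"] = lambda m: functional_beta.pairwise_functional(m, space)
    for facet, fn in facet_fns.items():
        all_records.extend(
            null_models.ses_pairwise(
                incidence,
                fn,
                facet,
                nulls=nulls,
                threshold=config.ses_threshold,
            )
        )
    ses_records = null_models.ses_frame(all_records)
    ses_fractions = null_models.ses_summary(all_records, config.ses_threshold)

    # ---- component / facet comparisons (rank-sum) ---------------------
    comp_rows = []
    facets = list(beta_sets)
    for facet in facets:
        bs = beta_sets[facet]
        res = gradient_stats.ranksum_compare(
            bs.condensed("turnover"), bs.condensed("nestedness")
        )
        comp_rows.append(
            {
                "comparison": f"{facet}: turnover vs nestedness",
                "z": res.z,
                "abs_z": abs(res.z),
                "p": res.p,
                "direction": res.direction,
            }
        )
    for comp in COMPONENTS:
        for f1, f2 in itertools.combinations(facets, 2):
            res = gradient_stats.ranksum_compare(
                beta_sets[f1].condensed(comp), beta_sets[f2].condensed(comp)
            )
            comp_rows.append(
                {
                    "comparison": f"{comp}: {f1} vs {f2}",
                    "z": res.z,
                    "abs_z": abs(res.z),
                    "p": res.p,
                    "direction": res.direction,
                }
            )
    comparisons = pd.DataFrame(comp_rows)

    # ---- gradient statistics ------------------------------------------
    meta = metadata.loc[incidence.site_ids]
    env = environment.loc[incidence.site_ids]
    d_elev = gradient_stats.elevational_distance(meta)
    d_env = gradient_stats.environmental_distance(env, ENV_COLUMNS)
    mantel_elev = gradient_stats.mantel_table(
        list(beta_sets.values()), d_elev, n_perm=config.n_mantel_perm, seed=seeds[1]
    )
    mantel_env = gradient_stats.mantel_table(
        list(beta_sets.values()), d_env, n_perm=config.n_mantel_perm, seed=seeds[2]
    )
    per_var = gradient_stats.per_variable_distances(env, ENV_COLUMNS)
    hp_rows = []
    for facet, bs in beta_sets.items():
        for comp in COMPONENTS:
            try:
                hp = gradient_stats.hierarchical_partition(bs.component(comp), per_var)
            except ValueError:
                continue  # e.g. constant component
            for var in per_var:
                hp_rows.append(
                    {
                        "facet": facet,
                        "component": comp,
                        "predictor": var,
                        "independent_effect": hp.independent[var],
                        "joint_effect": hp.joint[var],
                        "r_squared_full": hp.r_squared_full,
                    }
                )
    hier_part = pd.DataFrame(
        hp_rows,
        columns=[
            "facet", "component", "predictor",
            "independent_effect", "joint_effect", "r_squared_full",
        ],
    )

    decay_obs_rows, decay_ses_rows = [], []
    for facet, bs in beta_sets.items():
        for comp in COMPONENTS:
            try:
                reg = gradient_stats.decay_regression(bs.component(comp), d_elev)
            except ValueError:
                continue
            decay_obs_rows.append(
                {"facet": facet, "component": comp, **dataclasses.asdict(reg)}
            )
            ses_m = _ses_matrix(ses_records, facet, comp, incidence.site_ids)
            try:
                reg_s = gradient_stats.decay_regression(ses_m, d_elev)
            except ValueError:
                continue
            decay_ses_rows.append(
                {"facet": facet, "component": comp, **dataclasses.asdict(reg_s)}
            )
    decay_observed = pd.DataFrame(decay_obs_rows)
    decay_ses = pd.DataFrame(decay_ses_rows)

    # ---- phylogenetic signal ------------------------------------------
    if traits is not None:
        encoded = functional_beta.encode_traits(traits)
        lam = phylo_signal.lambda_table(tree, encoded)
    else:
        lam = pd.DataFrame()

    provenance = {
        "rng_seed": config.rng_seed,
        "n_null": config.n_null,
        "n_mantel_perm": config.n_mantel_perm,
        "n_trait_axes": config.n_trait_axes,
        "ses_threshold": config.ses_threshold,
        "n_sites": incidence.n_sites,
        "n_species": incidence.n_species,
        "n_excluded_sites": len(excluded),
    }
    report = AnalysisReport(
        config=config,
        beta_sets=beta_sets,
        summary=summary,
        ses_records=ses_records,
        ses_fractions=ses_fractions,
        comparisons=comparisons,
        mantel_elevation=mantel_elev,
        mantel_environment=mantel_env,
        hier_partition=hier_part,
        decay_observed=decay_observed,
        decay_ses=decay_ses,
        lambda_signal=lam,
        excluded_sites=excluded,
        provenance=provenance,
    )
    if outdir is not None:
        report.write(outdir)
    return report
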