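# Methods

This note documents the models, conventions and numerical choices
behind `betafacet`, and what the synthetic-data tests do and do not
establish about real survey data.

## Dissimilarity partition

All three facets use the additive Sørensen decomposition on a triple
`(a, b, c)` of shared / unique quantities:

* total `β_sor = (b+c)/(2a+b+c)`;
* turnover `β_sim = min(b,c)/(a+min(b,c))` — replacement, insensitive
  to richness difference;
* nestedness-resultant `β_sne = β_sor − β_sim`, computed from its own
  closed form `[(max−min)/(2a+min+max)]·[a/(a+min)]` and verified
  against the difference to machine precision.

The counts are floats so the identical code serves species counts,
branch lengths and hull areas. Degenerate conventions: `0/0` turnover
is 0; if `b = c = 0` the pair is identical and the partition is
`(0,0,0)` regardless of `a`; a pair in which one community is empty is
rejected (taxonomic facet; upstream validation guarantees richness ≥ 1)
or propagated as missing (functional exclusions).

## Phylogenetic facet

`a`, `b`, `c` are summed branch lengths classified per site pair in a
single post-order pass: a branch whose subtended tips occur in both
communities is shared; in exactly one, unique to it; in neither,
ignored. Classification is confined to the **minimal spanning subtree
of the pair**: the root stem and every branch subtending the entire
union of the two communities (the root-to-MRCA(union) path) are
excluded. Those branches are unavoidably "shared" in any comparison,
and excluding them makes the computation exactly invariant under
pruning the tree to the union of the pair — a property the test suite
asserts. The worked three-tip examples are unaffected because their
unions span all tips. Zero-length branches are legal and contribute
nothing. Faith's PD, used for the per-site alpha diversity analogue,
keeps the conventional rooted definition (all branches from the
community's tips to the root, stem excluded).

Tree uncertainty is handled by `average_over_trees`, which reports the
elementwise mean and SD of the partition across a supplied tree sample;
with a single tree the SD is zero. The pipeline default is a single
tree because no principled reduction of a posterior sample to one tree
is assumed.

## Functional facet

Traits are encoded as log₁₀ body mass (the conventional transform for
body size) plus the raw diet and foraging-stratum fractions; every
column is standardized to mean 0, SD 1 and the space reduced by PCA
(SVD of the standardized matrix), keeping 2 axes by default. Columns
whose standard deviation is below `1e-10 × max(1, |x|max)` are dropped
as constant (the tolerance absorbs float dust in nominally identical
columns). Communities are convex hulls of their species' scores;
intersections are exact 2-D polygon clippings (shapely), with unique
volumes below `1e-12 × max(hull areas)` snapped to zero so that true
containment yields turnover exactly 0. Two dimensions is the only
exactly supported case; the partition is defined for general d but no
exact d > 2 clipping is provided. Communities with fewer than 3
species, or with (near-)collinear points (hull area ≤ 1e-9), are
flagged `excluded`; their pairs are missing, never imputed, and the
exclusion list is reported. Within the null model, a replicate in which
a community fails the rule is skipped for that replicate and the
per-pair effective null size reported.

## Null model and SES

The null redraws each site independently and uniformly (without
replacement) from the full aligned species pool at the site's observed
richness. Occurrence frequencies are deliberately not preserved — the
model asks what richness alone would produce; a frequency-weighted
variant exists for sensitivity analysis. One stream of randomized
matrices (default 999) is shared by all facets within a run so their
SES values are comparable. SD uses the sample (n−1) denominator;
`SES = (obs − mean)/SD`, undefined (and excluded from regressions,
flagged) when the null SD is zero. Classification uses strict
inequalities at ±1.96: a value of exactly 1.96 is stochastic.

Calibration: datasets generated by the null process itself must score
mean SES ≈ 0. The calibration tests generate replicates with
`randomize_community` on a fixed-richness scaffold, keeping the pool
identical between generation and standardization. Generating "random"
communities and then dropping species that happened to occur nowhere
would shrink the pool the null redraws from and bias SES upward —
a real hazard when the empirical pool is defined from the observed
occurrences themselves.

## Gradient statistics

* **Distances.** Elevational distance is |band-midpoint difference|;
  environmental distance is Euclidean on variables standardized to
  mean 0, SD 1 (together or per variable).
* **Mantel.** r is the Pearson correlation of lower-triangle entries;
  p is upper-tailed, `(1 + #{r_perm ≥ r_obs})/(n_perm + 1)` over joint
  row/column permutations (9999 by default). One tail is the
  convention for distance–decay; r itself is reported signed. Missing
  pairs are dropped identically in every permutation.
* **Distance–decay OLS.** Pair-level ordinary least squares; the
  non-independence of pairs is a documented caveat, not "corrected",
  and the permutation-based Mantel test is reported alongside.
* **Rank-sum.** Wilcoxon rank-sum z with tie-corrected variance and
  **no continuity correction** (so {1,2,3} vs {4,5,6} gives
  |z| = 4.5/√5.25 ≈ 1.964); two-sided normal p. Cross-facet
  comparisons are unpaired even though the pair sets coincide — a
  paired test would be the natural alternative, but the unpaired form
  is what the comparison tables conventionally report.
* **ANOSIM.** Rank-based R with label-permutation p; included for
  season-pooling checks on grouped data (the synthetic generator is
  season-free, so tests exercise it on simulated groups).
* **Hierarchical partitioning.** Chevan–Sutherland: OLS R² fitted for
  all 2^k predictor subsets (k ≤ 12 enforced), the independent effect
  of a predictor is its R² increment averaged over all entry orderings,
  the joint effect its marginal R² minus that. ΣI equals the
  full-model R² to 1e-10 by construction; negative joint effects are
  allowed. Collinear-to-singular designs are rejected by a rank check.

## Pagel's λ

Under Brownian motion, tip covariance equals shared root-to-MRCA path
length; λ multiplies the off-diagonal part. The root state and BM rate
are profiled out analytically (GLS), leaving a bounded 1-D likelihood
in λ maximized on [0, 1] (tolerance 1e-8), with the endpoints checked
explicitly since the bounded optimizer never evaluates them. The LRT
against λ = 0 uses the 50:50 mixture of a point mass and χ²₁ because
λ = 0 sits on the parameter boundary; a plain χ²₁ option matches
common implementations. Ultrametric trees make λ_max = 1. On a star
tree the likelihood is flat in λ; λ̂ is reported as 0 with an
`identifiable = False` flag. Fraction-valued traits are tested
per-column as supplied (a logit transform is the user's choice).

## Synthetic data

The generator emulates a single-mountain survey: 8 bands at 250-m
intervals from 2027 m, a 132-species pool, richness varying by band,
environmental variables monotone in elevation (temperature and PET
strictly decreasing before noise) plus Gaussian noise scaled to each
variable's gradient range (default SD 0.25 of the range). Assembly
modes:

* `turnover` — uniform species optima on the band axis; each species
  occupies the `niche_breadth` (default 3) nearest bands. Occupancy is
  deterministic given the optima so that constructed β values are
  exact oracles (breadth 1 with disjoint optima gives β_sim = 1;
  adjacent bands share species, distant bands do not).
* `nestedness` — ordered species loss from the richest site; every
  pairwise turnover is exactly 0 and β_sor = β_sne.
* `random` — uniform draws at fixed richness; the neutral reference.
  Species that occur nowhere are dropped from the output (the matrix
  invariant requires every species somewhere), which is why null
  *calibration* uses `randomize_community` directly (above).
* `filtered` / `limiting` — site assembly by nearest-optimum selection
  or greedy maximin spacing on a latent niche trait; these produce
  filtering-like and spacing-like structure for end-to-end smoke tests
  but no exact oracle values are claimed for them.

Trees are coalescent-style: uniform random joins with exponential
waiting times, ultrametric by construction (λ's assumptions hold).
Traits are multivariate normal with the λ-scaled BM covariance
(tip-variance normalized); body mass is 10^latent (≈ 30 g median), and
diet/stratum blocks are softmax transforms of latent BM traits, which
keeps simplex constraints while inheriting the signal. The dataset
generator derives independent substreams for communities, tree, traits
and environment from one master seed, so adding a stage never shifts
another stage's draws.

What the generator does **not** emulate: observation error and
detectability, seasonal structure, abundances, spatially autocorrelated
environments, or realistic trait correlation structure (the synthetic
PCA axes carry far less of the total variance than real
morpho-ecological data, where a dominant size axis typically
concentrates most inertia). Passing tests therefore demonstrate the
correctness of the computations and the internal consistency of the
assembly logic, not that any particular empirical system behaves this
way.

## Problem sizes used by tests and the acceptance script

Chosen to exercise the asymptotics that matter while keeping the suite
quick: the geometric Monte-Carlo oracle uses 2×10⁵ points per polygon
pair (50 pairs, 3-SE agreement); null calibration uses 100 replicate
datasets of 6 bands × 40 species with 199 nulls each, all three
facets; λ recovery uses 200 replicates at 100 tips; the end-to-end
gradient check uses 100 seeded runs at 8 bands × 80 species with
999-permutation Mantel tests. The acceptance script runs the full
default study (8 bands × 132 species, 999 nulls, 9999 permutations).

## Known limitations

* Exact functional intersections only in 2-D.
* The pairwise (not multiple-site) partition is the primary output;
  Baselga's multiple-site variant is reported for the taxonomic facet
  as a comparison summary only.
* The "share of regional diversity" figures (1 − mean α/γ per facet)
  are a flagged proportional-diversity interpretation, not part of the
  Sørensen partition, and are labelled as such in the outputs.
* Pair-level regressions inherit the usual pseudo-replication of
  distance matrices; inference should lean on the permutation tests.
* The richness null is the only default; fixed-fixed (both margins
  preserved) swap algorithms are out of scope.
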