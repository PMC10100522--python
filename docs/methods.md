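# Methods

`lakediv` re-implements, as a tested pipeline, a multi-dimensional analysis
of zooplankton alpha diversity across mountain-lake networks: per-lake
taxonomic, functional, and phylogenetic metrics; standardized effect sizes
against zonal null communities; geographic discretization into elevational
and latitudinal zones; and hierarchical Bayesian trend models along
elevation, latitude, and temperature gradients.  Because the compiled field
data are an external deposit, the package ships a synthetic metacommunity
generator that emulates their statistical structure and provides closed-form
ground truth, so every stage is testable end to end.

## Synthetic metacommunity generator

The generator is a stand-in with the right qualitative shape, not a fit to
any deposit.  Its defaults encode the study conditions the analysis was
designed around:

- **Sites.** 1241 lakes spanning 0–3740 m a.s.l. and 36.6–66.2° N.  Latitude
  comes from a two-component mixture (a broad peak near ~49° plus a long
  northern tail); elevation from a Beta(2, 2.8) distribution scaled to a
  ceiling that shrinks linearly toward the north (to 38 % of the maximum at
  the top of the range).  This reproduces the right-skewed marginals on both
  axes and the shorter elevational gradients at high latitude.
- **Climate.** Mean annual temperature (MAT) is a linear surface,
  `12 °C − 6.5 °C/km · elevation − 0.4 °C/° · (latitude − 36.6)`, plus
  N(0, 1 °C) noise; the 6.5 °C/km term is the standard environmental lapse
  rate.  Seasonal temperature difference rises with latitude
  (18 °C + 0.45 °C/°).  There is no spatial autocorrelation: a linear
  surface already yields the strong geography–temperature correlations the
  gradient models need (sample corr(MAT, elevation) ≈ −0.74).
- **Species pool.** 119 taxa nested in 3 classes / 7 orders / 15 families /
  45 genera, each rank non-empty and each name under exactly one parent.
  Body length is log-normal (log-mean 0 = 1 mm, log-sd 0.6); feeding guild
  is ordinal 1–4 with probabilities (0.15, 0.45, 0.20, 0.20), the seston
  filterers most common.  15 % of taxa are genus-level records (juveniles /
  unresolved identifications) that carry no species name.
- **Occupancy.** `logit P(taxon j in lake i) = −1 + α_j − ((MAT_i − opt_j)/tol_j)²`,
  with per-species offsets α ~ N(0, 1), tolerances ~6 °C (log-normally
  jittered), and thermal optima spread over a 12 °C band anchored at the warm
  end of the climate surface with density increasing toward warmth.  Most
  lakes therefore sit below most optima, making expected richness increase
  monotonically with MAT — warm, low, southern lakes are rich (~25–30 taxa),
  cold alpine lakes poor (often < 2, which is what produces the differing
  per-metric sample sizes downstream).
- **Ground truth.** Expected richness Σ_j P_ij is available in closed form on
  the noise-free climate surface, and target log-richness slopes per 1 SD of
  each standardized predictor are computed by least squares over the lake
  design; parameter-recovery tests compare model estimates against these.

What the generator does **not** emulate: spatial dispersal limitation or
autocorrelation, temporal turnover, glaciation history, fish predation, and
abundance structure (incidence only).  Tests passing on this world show the
machinery is correct and calibrated, not that the ecological conclusions
would transfer to any particular field data set.

## Compilation rules

Cumulative species lists are unioned per lake (duplicate records collapse to
one presence).  Non-target benthic and littoral groups poorly sampled by tow
nets are excluded by rank-scoped name: class Ostracoda; orders
Harpacticoida, Laevicaudata, Amphipoda, Anostraca, Notostraca, Mysida.
Laevicaudata is a suborder in some classifications, but the lineage schema
carries exactly five ranks (species, genus, family, order, class), so it is
scoped at order here.

Species richness applies a juvenile counting rule: coarse (genus-or-higher)
records add to the count only when no species-level taxon of the same clade
is present in the lake.  The shadowing scope is the coarse taxon's lowest
named rank — genus for `Daphnia spp.`, family for a family-level record.
Only richness uses coarse taxa; the trait and phylogeny metrics run on
species-level taxa (the tree's tips).

## Diversity metrics

- **Gower dissimilarity** over body length (continuous) and feeding guild
  (ordinal treated as interval-scaled — the ranked "metric" convention),
  equal weights, range-normalized per trait, renormalized over the traits
  observed in both taxa when one is missing.
- **Trait space** is a classical principal-coordinates embedding of the
  Gower matrix with two retained axes (two traits).  If the smallest
  eigenvalue is below −1e−8 the Cailliez additive correction is applied
  first.  In practice the two-trait city-block Gower matrix is never
  Euclidean, so the correction fires routinely; a rank-2 embedding of such
  a metric is necessarily inexact (embedded-vs-input distance correlation
  ≈ 0.97 on random pools), which is an inherent property of the method, not
  an implementation artifact.
- **FRic** is the community convex-hull area divided by the pool hull area.
  Communities with ≤ 2 distinct points, or affinely degenerate ones, get a
  missing value rather than zero — zero would conflate "no spread on one
  axis" with "no function", and the hull requirement is exactly why FRic has
  the smallest eligible n.
- **FDis** is the mean Euclidean distance of community points to their
  centroid; **CWM**s are unweighted means (incidence data, no abundances),
  body length on the arithmetic mm scale.
- The **taxonomy tree** assigns one unit of branch length per rank step, so
  tips sit at depth 5 and the patristic distance between two taxa is exactly
  twice their taxonomic distance (congeners 2, different classes 10).  A
  taxonomy-derived tree built from complete five-rank lineages reduces the
  distinctness-clustering construction to the rank hierarchy itself, so the
  tree is built directly; single-child chains are collapsed with summed
  lengths, and the root always survives the collapse so depth is preserved.
  **Faith's PD** sums the spanning subtree (root path included by default);
  **MPD** averages patristic distances over all pairs.

## Null models and SES

Observed FRic, FDis, PD, and MPD are compared with richness-matched random
communities: uniform draws of S species (equal weights, no occupancy-
frequency weighting) from the focal lake's zonal pool.  The default pool is
the "cell" — species observed in lakes sharing both the elevational and the
latitudinal zone — widening to the union of the two zones and then the
global pool when the cell holds fewer species than the community; fallbacks
are recorded per lake.  All four metrics score the same draws (common random
numbers), so SES contrasts between metrics are not confounded by draw noise.

The effect size is the probit of a quantile p-value with midpoint tie
handling and a continuity correction:

    p = (n_below + 0.5·n_equal + 0.5) / (n_iter + 1),    SES = Φ⁻¹(p).

p is strictly inside (0, 1), so SES is always finite; at 999 iterations the
extremes are ±3.29.  SES of 0 means the observation sits at the null median;
positive is overdispersion, negative clustering, for all four metrics (no
sign flip is applied to the net-relatedness convention).  Under the null
generative process p is uniform on a lattice and SES has mean ~0 and
variance ~1, which the calibration tests check at n_iter = 999 over 200
communities.  The default n_iter is 999 (full profile) and 199 (desk).

## Zoning and design columns

Sturges' rule, k = ⌈log₂ n⌉ + 1, sets the number of zones (12 at n = 1241).
The exact Fisher-Jenks dynamic program (O(k·n²), vectorized inner loop)
partitions each axis into k contiguous classes minimizing within-class SSE;
ties break toward the smallest last class, and intervals are closed on the
right (a lake exactly on a break falls in the lower zone).  Exhaustive
enumeration over all contiguous partitions is the test oracle.

Predictors are standardized (mean 0, sd 1, sample sd) over all lakes
entering a model, then expanded into unit-norm orthogonal linear and
quadratic columns by Gram–Schmidt with fixed signs (linear column positively
correlated with the predictor; quadratic positive at the extremes).  The
stored transform evaluates the same basis on new grid points for prediction
curves.

## Gradient models

Each metric–predictor model is a GLMM with population-level intercept,
linear (β₁, "steepness") and quadratic (β₂, "curvature") effects, and
zone-level random intercepts and slopes for all three terms — latitudinal
zones group the elevation models and elevational zones the latitude models,
so the random effects carry the geographic interaction.  Inside the model
the orthogonal columns are rescaled by √n to roughly unit standard
deviation, making β₁/β₂ per-SD effects; this is the scale the N(0, 5) slope
prior is placed on and the scale all reported coefficients use.

Families: Poisson (log) for richness with a negative-binomial option for
overdispersion, Gamma (log) for PD, Gaussian for SES and CWM responses, and
a two-component Gaussian mixture on logit(FRic) for the bimodal functional
richness.  Climate-versus-geography models (e.g. elevation on MAT) z-score
the response as well, so their slopes read as correlation strengths.
Remaining priors are weakly informative: N(0, 10) intercepts,
half-Student-t(3) scales for random-effect standard deviations and
dispersion parameters.  Random effects are non-centered with independent
per-term scales; a full covariance with an LKJ prior was considered and
dropped — the correlations are not consumed anywhere in the analysis, and
with analytic gradients the independent parameterization is simpler and
mixes well.

Posteriors are sampled by an adaptive Hamiltonian Monte Carlo sampler
written for this package: leapfrog dynamics, diagonal mass matrix estimated
from a mid-warmup window, dual-averaging step-size adaptation to a 0.8
acceptance target, and randomized path lengths (uniform 1–32 leapfrog steps
per iteration) to avoid resonance.  Transitions with energy error > 1000 or
non-finite states count as divergences.  Every parameter's split R-hat and
effective sample size are computed (via arviz); a fit with any R-hat > 1.01
or any divergence is flagged, and flagged fits are excluded from
information-criteria comparisons.  Two profiles: `desk` (4 chains ×
400 + 400) for routine runs and tests, `full` (4 chains × 1000 + 3000)
matching the production MCMC settings.  Parameter-recovery tests show a
known Poisson slope of −0.4 covered by the 95 % CI in ≥ 43/50 simulations
(observed 98 % at n = 600, 12 groups) and posterior means within 0.1 of a
maximum-likelihood oracle on shared data.

The mixture model uses component-specific intercepts **and** polynomial
coefficients (reported as μ₁/μ₂ sets) with a shared residual scale, ordered
intercepts enforced by an exponentiated gap (so labels cannot switch), and
no random effects.  One degenerate-case caveat: with unimodal data the two
components collapse onto each other and the mixing proportion becomes
unidentified (its posterior follows the prior near 0.5) — the "mixing goes
to 0 or 1" intuition only holds when the components are kept apart.

**Model comparison.** WAIC is computed from the pointwise log-likelihood
matrix as −2(lppd − p_waic) with p_waic the summed over-draws variance
(sample variance, ddof = 1; arviz's population-variance convention differs
by O(p/S)); LOOIC comes from Pareto-smoothed importance sampling via arviz.
Deltas are reported against the best model.  On synthetic grouped data with
real group-level slope variance the multilevel model beats the
fixed-effects-only model by > 200 WAIC/LOOIC points.

**Prediction curves.** Population-level curves set group effects to zero;
group-level curves add each zone's random effects; both are medians and
95 % intervals of the inverse-linked linear predictor over a grid mapped
through the training polynomial basis (extrapolation beyond the training
range is permitted, not an error).

## Pipeline and reproducibility

`pipeline.run_pipeline` executes ingest/generate → filter → tree → metrics →
zones → null SES → models → report, writing all artifacts (CSV tables,
Newick tree, JSON manifest) with SHA-256 checksums.  A single global seed
deterministically derives one sub-seed per randomness-consuming stage via
`numpy.random.SeedSequence.spawn`, and each lake's null draws use a further
per-lake spawned stream, so results are independent of evaluation order and
reruns reproduce every checksum bit-for-bit.  Inputs are canonicalized
(lakes and taxa sorted by id, occurrence matrix sorted on both axes), which
makes a user-data run on tables written by a synthetic run reproduce the
synthetic results exactly.  Lakes absent from a presence-only long-form
occurrence file are treated as surveyed-but-empty communities.

Problem sizes in the shipped tests and the acceptance script — 4 chains ×
400 + 400 draws (desk), 199 null iterations in pipeline runs, 999 in the
calibration experiment, 50 recovery simulations at n = 600 — were chosen as
the smallest designs at which the stochastic checks have comfortable
statistical margins.

## Known limitations

- The rank tree discards real branch-length information; PD/MPD resolve
  relatedness only to the five Linnaean levels.
- Two traits give a coarse functional space, and its PCoA embedding is
  inherently inexact (see above).
- The null model is richness-matched with equal species weights;
  fixed-occupancy (swap-style) nulls are out of scope.
- The exact zonal pool definition, iteration count, and tie rule of the
  original analysis are not published in the main text; the cell-scope pool,
  999 iterations, and midpoint ties here are reconstructions exposed as
  configuration.
- Mixture models carry no random effects; multiplicative-interaction
  reference models are not implemented.
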