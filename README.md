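# lakediv

Multi-dimensional diversity gradients of mountain-lake zooplankton:
metrics, zonal null models, and hierarchical Bayesian trend estimation.

## The problem

Species richness is expected to decline toward high elevations and high
latitudes, but the two gradients need not be interchangeable: they differ in
length, rate of temperature change, and underlying drivers, and their
interaction can produce hump-shaped patterns that neither axis shows alone.
Testing this requires more than richness — functional metrics (from species
traits) and phylogenetic metrics (from relatedness) separate *how many*
species co-occur from *how similar* they are, and null-model standardized
effect sizes reveal whether communities are more clustered or more
overdispersed than chance given their richness.

`lakediv` implements that entire analysis chain for lake incidence data
(sites × taxa, 0/1), aimed at community ecologists working with compiled
survey data:

- **Compilation rules** — cumulative (union) species lists, removal of
  non-target benthic groups (Ostracoda, Harpacticoida, Laevicaudata,
  Amphipoda, Anostraca, Notostraca, Mysida), and a juvenile counting rule in
  which genus-level records add to richness only when no congeneric
  species-level record is present.
- **Diversity metrics** per lake: richness *S*; functional richness (FRic,
  convex-hull fraction in a Gower/PCoA trait space over body length and
  ordinal feeding guild), functional dispersion (FDis), community-weighted
  means; Faith's PD and mean pairwise distance (MPD) on an ultrametric tree
  built from Linnaean ranks (patristic distance = 2 × rank distance).
- **Null models** — richness-matched random draws from zonal species pools,
  with SES computed as probit-transformed quantile p-values,
  `SES = Φ⁻¹((n_below + ½·n_equal + ½)/(n_iter + 1))`, so SES is finite,
  tie-robust, and ~N(0, 1) under the null. Positive = overdispersion.
- **Zoning** — Sturges' rule `k = ⌈log₂ n⌉ + 1` and an exact Fisher-Jenks
  dynamic program split the study region into elevational and latitudinal
  zones (12 each at n = 1241).
- **Gradient models** — Bayesian GLMMs of each metric on first/second-order
  orthogonal polynomials of elevation, latitude, mean annual temperature, or
  seasonality, with zone-level random intercepts and slopes (latitudinal
  zones group elevation models and vice versa). Families: Poisson/negative
  binomial, Gamma, Gaussian, and a two-component Gaussian mixture for
  bimodal FRic. Sampled with a purpose-built adaptive HMC sampler;
  diagnostics (split R-hat, ESS, divergences), WAIC and PSIS-LOO included.
- **Synthetic metacommunity generator** — 1241 lakes over 0–3740 m and
  36.6–66.2° N with right-skewed site distributions, a 119-taxon pool with
  nested taxonomy and traits, and thermal-niche occupancy with closed-form
  expected richness, so the full pipeline is testable with known ground
  truth (see `docs/methods.md` for what it does and does not emulate).

## Worked example

The numbered scripts under `analysis/` run the study end to end on the
synthetic metacommunity:

```bash
python analysis/01_simulate_metacommunity.py --seed 1
python analysis/02_compute_diversity_metrics.py
python analysis/03_zone_and_standardize.py
python analysis/04_null_model_ses.py
python analysis/05_fit_gradient_models.py
```

Step 01 prints the world it generated:

```
1241 lakes spanning 33-2811 m and 37.9-66.2 deg N (medians 993 m, 49.9 deg)
119 taxa (16 genus-level); raw richness mean 12.4 (max 40)
corr(MAT, elevation) = -0.74; corr(richness, MAT) = +0.92
ground-truth log-richness slopes per SD: elevation -0.691, latitude -0.238
```

so the truth to recover is a richness decline of about 0.69 log units per
standard deviation of elevation. Step 02 reports the eligibility accounting
(richness n = 1241 ≥ PD/MPD/FDis n = 1141 ≥ FRic n = 1073 — lakes with
fewer than two species-level taxa carry no dispersion metrics, and
degenerate hulls thin FRic further), step 03 confirms Sturges' rule gives
12 zones per axis, and step 04 summarizes the SES columns. Step 05 fits
the model battery; its report includes, for example,

```
richness~elevation[poisson|lat_zone]: beta1=-0.94 (negative), beta2=-0.19 (negative)
richness~mat[poisson|lat_zone]:       beta1=+0.87 (positive), beta2=-0.23 (negative)
elevation~mat[gaussian|lat_zone]:     beta1=-0.91 (negative)
```

read as: species richness falls steeply and concavely with elevation
(slope −0.94 per SD on the log link, 95 % CI excluding zero), rises with
mean annual temperature, and elevation is strongly negatively correlated
with temperature — the elevation gradient is temperature-driven, which is
exactly how the world was generated. Models whose split R-hat exceeds 1.01
at the desk MCMC profile are marked `[flagged]` in the report and excluded
from information-criteria comparisons; rerun with `--profile full` for
production-length chains.

The same chain is available as a single seeded call,
`lakediv.pipeline.run_pipeline(RunConfig(...))`, which writes every artifact
with SHA-256 checksums and reproduces them bit-for-bit on rerun.

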