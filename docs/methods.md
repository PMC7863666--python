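# Methods

## Data model and conventions

A *lake* carries WGS84 coordinates, five basic quantitative traits —
surface area (ha), maximum depth, shape index, Secchi clarity, pH — a
trophic class and a suitability flag. Depth and Secchi are stored in the
source's units and never converted: published tables in this domain mix
metres and feet, and a silent conversion is worse than an honest unit tag.
Missing traits are loaded and flagged, never dropped; the completeness
filter (both lakes of a visit must have all five traits) is explicit and
reports before/after counts.

The **shape index** is shoreline perimeter (km) divided by the square root
of surface area (ha). Under this unit convention a circular lake scores
2√(πA)/ (100·√A/100) ≈ 0.354 regardless of size — the analytic minimum —
and the index is invariant under uniform linear rescaling of the outline.

The **trophic taxonomy** is a closed set of 12 codes: the eight
combinations of sportfish richness (Complex ≥ 4 species / Simple < 4,
boundary count assigned to Complex, threshold configurable), temperature
(Warm/Cool) and clarity (Clear/Dark); two-story lakes (TS), whose vertical
stratification supports both warm- and cold-water communities and
overrides the clarity/temperature split; and three non-lake water-body
categories (RIVER, TROUT_POND, SPRING_POND) that appear in regional
datasets but are never loon habitat and are only ever data tags, not
classification outputs. Suitability filtering removes excluded classes and
lakes under 10 ha.

## Randomization test

Observed statistic: mean absolute natal–destination trait difference over
all visit records. The resampling unit is the visit record, not the
juvenile — repeat visits count once per record — because the observation
process (weekly surveys) samples visits, not birds; a per-juvenile
collapse can be performed upstream by deduplicating the visit table.

Null: per iteration, every visit's destination is replaced by a uniform
draw, with replacement, from that visit's pool — suitable lakes excluding
the natal lake (the actual destination remains eligible; a random chooser
could pick it). Default 10,000 iterations. The p-value is lower-tail
(preference for similarity = smaller differences than null) with the
add-one form p = (#{null ≤ observed} + 1)/(N + 1), so finite resampling
reports a resolution floor (1/(N+1)) rather than p = 0. The null's
2.5/97.5% quantiles are reported for interval plots; they are descriptive,
not the decision rule. Families of traits use Bonferroni α/m.

Two spatial-constraint modes exist because the design question admits two
readings: `pool_radius_km` restricts each null pool to lakes within a
radius of the natal lake (resampling only the autocorrelated
neighbourhood — very conservative), while `subset_radius_km` instead drops
observations whose actual travel exceeded the radius. Both are exposed;
the pipeline uses the pool restriction.

### Calibration behaviour worth knowing

With no preference and a spatially unstructured trait, the test's type-I
error at α = 0.05 is close to nominal but measurably above it (≈ 0.065–0.07
in our replicate experiments, vs 0.041 when the choice pool and the null
pool coincide). The cause is structural, not a bug: juveniles choose from
travel-limited local pools while the unconstrained null resamples the
whole study area, so the observed statistic carries extra between-dataset
variance that the conditional null cannot see. This is a mild, finite-lake
form of exactly the pool-mismatch confounding the constrained variant
addresses, and it disappears as the travel radius approaches the study
extent.

## Semivariograms and range estimation

Method-of-moments estimator, γ(h) = (1/2N_h) Σ (zᵢ−zⱼ)², with default
2 km bins and max lag equal to half the maximum pairwise distance (the
standard geostatistical heuristic; longer lags have too few pairs and edge
bias). Distances are haversine (R = 6371 km) everywhere — no flat-Earth
shortcuts — so thresholds are commensurable across modules. Directional
variograms fold pair bearings modulo 180° and use half-open ±22.5°
windows; the default four bearings (0/45/90/135) therefore partition the
pair set exactly, and the SW–NE axis is the 45° window.

Model fits (exponential or spherical) minimise pair-count-weighted squared
error over nugget, partial sill, and range, with a three-point multi-start
on the range to avoid local minima. Practical range = distance to 95% of
sill: 3× the range parameter (exponential) or the range parameter itself
(spherical). A variogram flat at zero yields a degenerate fit flagged
`no_structure` (practical range undefined). In the pipeline's screening
step a trait counts as spatially structured only when the fit has
structure **and** its practical range lies within the observed lag span —
a flat-but-noisy variogram otherwise fits an arbitrarily long, unresolvable
range — and the constrained test is run only when the majority (> 0.5,
configurable) of observed travel distances fall within that range.

## Synthetic landscape generator

The generator's defaults emulate the kind of north-temperate glacial lake
district the method targets: 120 lakes uniform over a 60 × 60 km square;
pH from a Gaussian random field with exponential covariance (practical
range 20 km, sill 1, nugget 0.05, via Cholesky factorization of the site
covariance) plus a gentle linear gradient (0.03 latent units/km) along the
45° (SW–NE) bearing, affinely rescaled into the printed trait bounds
(pH 4.7–9.4); area 8–1,400 ha and depth 3–117 log-uniform, clarity
0.75–6.9 m and shape 0.35–3.9 uniform, all spatially unstructured; trophic
classes drawn from a fixed mix over the nine natural-lake codes with
Complex classes assigned preferentially to large lakes. Coordinates are
converted to lat/lon on a local tangent plane about 45.7°N, 89.5°W, which
keeps haversine distances within 1% of the planar kilometres.

Because the pH field is min–max rescaled into its bounds, the sill and
nugget act as relative variance controls (structured : unstructured);
the realized spread follows from the bounds (≈ unit standard deviation for
a few dozen lakes). The rescaling is affine, so the autocorrelation range —
the quantity the screening estimates — is untouched.

The visit simulator samples natal lakes uniformly with replacement among
suitable lakes (default 43 juveniles × 2 visits, matching the scale of a
multi-year banding study); each destination is a softmax draw over
suitable non-natal lakes within the travel radius (default 30 km) with
utility −w_ph·|ΔpH| + w_size·log area + w_complex·1[Complex]. Weights are
simulation knobs with no biological calibration. What the generator does
*not* emulate: observation error in traits, unequal detection effort,
within-season depletion, multi-year individual effects, and real lake
geometry (shape is independent of area). Passing tests therefore show the
inference machinery is correct and calibrated under its own assumptions,
not that any particular field system satisfies them.

## Trophic goodness-of-fit

Expected class proportions are the class composition of suitable lakes
within 40 km of **at least one** natal lake (the union reading; an
intersection mode exists but is usually empty and kept only for
completeness). The chi-square statistic is direct summation over classes
with positive expectation, df = (#such classes) − 1, upper-tail p from the
χ² law. Classes are never pooled when expected counts are small; a
warning flag is set instead, keeping df interpretable. An observation in a
zero-expectation class is an error: the availability model cannot explain
it and the window or filters need revisiting. Own-class preference is
reported descriptively (observed vs expected own-class proportion per
natal class), not as a second test.

## Baseline statistics

Welch two-sample t tests (scipy, two-sided, Satterthwaite df) compare the
natal and destination **lake sets** trait by trait — each lake once, not
each visit — at Bonferroni-adjusted α. Travel summaries report per-visit
haversine distance and initial bearing, mean/max, and a bearing histogram
for polar plots.

## Problem sizes and numerical choices

The validation experiments use 40–60 lakes and 60 visits per replicate
dataset with 500-iteration tests (300 replicates for type-I error, 100 for
power and for the constrained-vs-unconstrained comparison), 200 sites ×
20 replicates for range recovery, and 50,000 iterations against
exhaustive enumeration on instances small enough to enumerate (≤ 3 visits,
pools ≤ 6). These sizes give binomial/standard errors comfortably inside
the asserted bands while keeping the whole suite fast. Ties in the
randomization null are handled by `≤` with no tolerance except the 1e−12
guard in the enumeration oracle; the variogram fit uses tight (1e−15)
least-squares tolerances so noiseless inputs are recovered to ~1e−6.

## Known limitations

- The unconstrained test's mild anti-conservatism under travel-limited
  choice (above) is inherent to conditioning on the realized landscape.
- Anisotropy handling is a directional scan (sill comparison across four
  bearings), not a rotated-ellipse model fit.
- The constrained test needs enough lakes inside the radius; with sparse
  landscapes pools shrink and its null becomes coarse.
- Range estimates from ~40 sites are noisy; screening decisions at that
  size should be read as heuristics, which is why both constraint radii
  remain user-overridable.
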