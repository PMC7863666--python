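# loonlakes

Statistical tools for testing **natal habitat preference induction (NHPI)**
in lake-visiting birds: do juveniles visit lakes that resemble their natal
lake more than random choice from the surrounding study area would predict?

The package is aimed at movement ecologists working with two tables — a
lake attribute table (coordinates, area, depth, shape, water clarity, pH,
trophic class) and a visit table (juvenile, natal lake, destination lake,
date) — who want similarity-based habitat-selection inference that is
honest about spatial autocorrelation.

## The statistics

**Randomization test.** For a trait *z*, the observed statistic is the mean
absolute natal–destination difference over the *n* visit records,

&nbsp;&nbsp;&nbsp;&nbsp;D̄ = (1/n) Σᵢ |z(natalᵢ) − z(destᵢ)|.

A null distribution is built by replacing each visit's destination with a
uniform draw, with replacement, from that visit's candidate pool (suitable
lakes excluding the natal lake) and recomputing D̄, 10,000 times by default.
The p-value is lower-tail with an add-one correction,
p = (#{D̄\*ₖ ≤ D̄} + 1)/(N + 1), and five-trait families use a
Bonferroni-adjusted per-test α = 0.05/5 = 0.01.

**Spatial screening.** Nearby lakes have similar chemistry, and juveniles
do not travel far, so a naive test can mistake geography for preference.
Empirical semivariograms γ(h) = (1/2N_h) Σ (zᵢ−zⱼ)² per lag bin are fitted
with exponential/spherical models by count-weighted least squares; the
practical range (95% of sill; 3× the exponential range parameter) is the
operational autocorrelation threshold. Traits whose range covers the
majority of observed travel distances get a second, deliberately
conservative test in which each null pool is restricted to lakes within
that threshold of the natal lake.

**Trophic selection.** Destination trophic-class counts are compared with a
chi-square goodness-of-fit test against the class composition of suitable
lakes within 40 km of the natal lakes — availability as the birds
experience it — overall and per natal class.

**Synthetic landscapes.** A generator produces lake landscapes with a
Gaussian-random-field pH surface (exponential covariance, configurable
range/sill/nugget, optional SW–NE gradient) and a softmax destination-choice
model with tunable pH-similarity, lake-size and complexity attraction, so
every stage of the inference can be validated end to end with known truth.

## Worked example

```sh
loonlakes simulate --n-lakes 40 --n-juveniles 40 --visits-per-juvenile 2 \
    --w-ph 3.0 --seed 5 --out-dir demo
loonlakes analyze --lakes demo/lakes.csv --visits demo/visits.csv \
    --iterations 2000 --seed 5 --out demo/results.json
```

This simulates 80 visits on a 40-lake landscape whose juveniles prefer
pH-similar lakes (w_ph = 3 per pH unit), then runs the full pipeline. The
unconstrained randomization tests in `demo/results.json` give (trait,
observed D̄, null mean, p):

```
area_ha      308.36   269.65   p = 0.941
max_depth     21.94    24.21   p = 0.214
shape_index    1.238    1.175  p = 0.765
secchi         2.305    2.060  p = 0.956
ph             0.517    1.382  p = 0.0005   (significant at α = 0.01)
```

Only pH shows the planted similarity preference: visited lakes differ from
the natal lake by 0.52 pH units on average where random choice predicts
1.38. Because the fitted pH variogram has a resolvable practical range
(~35 km) covering most travel distances, the pipeline also runs the
constrained test — destination pools restricted to lakes within that
radius — and the pH preference survives it (p = 0.0005), the hallmark of a
real preference rather than a spatial artifact.

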