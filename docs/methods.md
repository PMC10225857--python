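# Methods

This note records the statistical model, its assumptions, the defaults that
matter, and the design decisions taken where the design was genuinely open.
It states nothing the test suite or `scripts/acceptance.py` does not itself
compute.

## Inputs and preparation

The pipeline consumes per-species annual index series (values with standard
errors; arbitrary scale), absolute population estimates (min/max/best with a
reference year or range), a species trait table (body mass in grams,
habitat, migration strategy, trophic niche), optionally a Newick phylogeny
and annual climate-suitability series. All tables are UTF-8 CSV; years are
calendar integers; rates are per calendar year; logarithms are natural.

Preparation rules, in order:

1. **Named exclusions** come from the config exclusion list (used in
   practice for species whose trends are imprecise and strongly negative),
   never from hard-coded names.
2. **Truncation and zero offset.** A series starts at its first positive
   count. If zeros remain in the retained window, 1% of the mean *retained*
   raw value is added to every retained value. The mean is taken over the
   retained window rather than the full raw series so the offset is on the
   scale of the data actually analysed; zeros that occur only before the
   first positive count therefore trigger no offset.
3. **Coverage filters.** A species is excluded when the most recent year of
   its series represents less than 50% of its current population; years
   with coverage below 5% are dropped individually.
4. **Span rule.** First and last years must be at least 10 years apart
   (configurable).

Preparation is idempotent, and exclusions are returned as values with
machine-readable reasons, not exceptions.

## Trend expansion

For species covered only by periodic national reporting, the annual
multiplier is λ = T̄^(1/trend period) and the population in year *i* is
Ē_N(i) = Ē_N(ȳ)·λ^(i−ȳ). National series are summed across countries
(assumed exchangeable and independent); uncertainty is attached by a
parametric bootstrap (default n = 1000, percentile 2.5/97.5) that redraws
population estimates lognormally with median at the point estimate and
log-sd matched to the standard error by the delta method — lognormal
because populations are positive and estimate errors are plausibly
multiplicative. Assemblage-level point estimates from bounds use the
geometric mean of summed minima and maxima, with SE a sixth of the span;
a best-only value acts as both bounds (SE 0).

## Smoothing

Log index series are smoothed with a penalized cubic B-spline regression:
equally spaced knots, exact integrated-squared-curvature penalty ∫(f″)²
(assembled by two-point Gauss quadrature per knot interval, so the penalty
null space is exactly the straight lines), observation weights 1/se_log²,
and the smoothing parameter chosen by generalized cross-validation over a
23-point log-spaced grid. Basis size defaults to min(10, ⌈n/3⌉) (floored at
the cubic minimum of 4) — standard practice that prevents overfitting short
series; series with fewer than 4 observations fall back to a weighted
log-linear fit and are flagged. Fitted values and standard errors are
returned at every calendar year in the span, including interior gaps.

A species' average annual growth rate is the endpoint log difference of the
smoothed series divided by the span. Endpoints (rather than the mean of
year-on-year rates) make the rate exactly the average log change per year
over the period. Growth rates are computed over each species' full series
by default; a common window can be imposed by truncating the inputs.

## The hierarchical abundance model

Specified fully in the `hierarchical` module docstring; in brief, with
reference year r(s) per species:

- observation: m\_{s,y} ~ N(α_s + λ\_{s,y}, w\_{s,y});
- latent: λ\_{s,y} = θ_s·(y−r(s)) + ε\_{s,y}, ε a random walk anchored at
  r(s) with per-species innovation variance η_s²;
- shrinkage: θ_s ~ N(μ + a\_hab + b\_mig + c\_{hab×mig}, τ²);
- scale: P_s ~ Lognormal(log point_s, se_s/point_s).

Choices that matter and why:

- **Raw vs smoothed observations.** The observation layer accepts either;
  the pipeline default is the *raw* log index, because raw errors are
  independent across years, which is what the likelihood assumes — feeding
  the smoothed series (whose errors are serially correlated and whose
  pointwise SEs exclude smoothing bias) understates endpoint uncertainty.
  The smoothed series remain the source of growth rates for the trait
  models.
- **Random-walk deviations.** An independent-deviations prior lets the
  fitted trend line over-concentrate the endpoints of a trajectory (the
  whole series then pins each year's value); a random walk anchored at the
  reference year lets trajectories bend smoothly while uncertainty grows
  with distance from the anchor. Innovation variance is per species because
  deviation scale varies strongly across species; it carries a weak
  inverse-gamma(2, 10⁻⁴) prior.
- **Missing years.** Leading (and trailing) years outside a species' series
  take the nearest observed value with variance inflated by c²·(gap)²,
  c defaulting to the species' mean observed log-scale SE. Distant filled
  years therefore carry essentially no likelihood weight and the early
  trajectory is governed by the group trend and random walk. Interior gaps
  get effectively infinite observation variance.
- **Group structure.** Additive habitat and migration effects plus an
  interaction term with a tighter prior (effect prior sd 0.1; interaction
  0.05) keep sparse habitat × migration cells identifiable while allowing
  cell-level departures.
- **Reference year for a range** (e.g. 2013–2017) is the midpoint, rounded
  down.
- **Sampling.** Partially collapsed blocked Gibbs, vectorised over species:
  θ_s and η_s² are updated against the ε-marginal likelihood (banded
  Woodbury identities; a conjugate update from the sampled deviations is
  degenerate — the variance collapses), then ε is redrawn from its
  tridiagonal-precision Gaussian full conditional, then α, group effects
  and τ². Defaults 4 chains × (1000 warmup + 1000 draws); split-R̂ is
  reported and values above 1.05 warn without suppressing output. P_s is
  independent of the trend layer and drawn directly.

Totals are per-draw sums T_y = Σ w_s·P_s·exp(λ\_{s,y}); biomass uses
w_s = body mass × 10⁻⁶ tonnes/g, constant per species. All summaries
(medians, 2.5/97.5 percentiles, increase/decrease decompositions, group
breakdowns) are computed per draw first, so sum identities are exact; a
species' headline sign is its posterior-median change. Percent change is
100·(end−start)/start; the per-annum rate is the geometric
100·((end/start)^(1/span)−1) with span = year_end − year_start, which
compounds back to the percent change exactly. Posterior medians of derived
ratios are not additive, so reported group medians need not sum exactly to
the assemblage median even though every underlying draw does.

## Climate suitability trends

The CST is the OLS slope of logit(annual mean suitability) on year, with
its SE, R² and t-test p-value; suitability is clamped to [10⁻⁶, 1−10⁻⁶]
with a warning before the logit. The bundled SDM is a single logistic GLM
with linear + quadratic terms per climate covariate (humped responses),
refit with a small ridge penalty under separation; any external SDM can be
substituted since only the annual suitability series enters downstream.
At least 20 presences and 5 years are required.

## Covariates and trait models

Abundance classes are equal-count quartiles of the population *point*
estimate (rare/scarce/common/abundant, ascending); remainders go to the
rarer classes so "abundant" is always exactly the top quartile; ties break
by species id for determinism. Collinearity screening uses Pearson's r,
Cramér's V, or single-term-regression R² according to variable types, with
the statistic recorded per pair and NaN for undefined (constant) cases.

The trait models take the log annual growth rate as response. The global
model has main effects migration, habitat, body mass, CST, trophic niche
and abundance class, plus the six interactions of the continuous predictors
(mass, CST) with migration, habitat and trophic niche. Continuous
predictors are z-transformed (population-sd convention). Marine species and
species without CST are excluded before fitting (counts logged). AIC is
Gaussian, counting the residual variance (and, for PGLS, λ) among the
parameters; AICc is not used by default. PGLS multiplies the off-diagonal
Brownian covariance by Pagel's λ, profiles λ by ML on a 21-point grid
refined by bounded search, reports a 1.92-log-likelihood-unit profile
interval, and tests λ against 0 and 1 with a 50:50 χ²₀/χ²₁ boundary
mixture. Branch lengths are assumed proportional to expected covariance; a
star phylogeny is flagged and falls back to OLS. All-subsets selection
enumerates marginality-respecting submodels (refusing above 10⁵), ranks by
AIC, discards models nested within a retained model of lower AIC, and keeps
ΔAIC ≤ 6.

## Breakpoint regression

Two-segment continuous least squares (hinge basis) on log totals; every
interior year with ≥3 points per side is a candidate and the minimal-SSE
fit wins, which equals brute-force enumeration by construction. Slopes are
reported as 100 × the natural-log slope (percent-per-annum convention,
consistent with printed slope magnitudes of ~1 for visually evident trends
in log series of this kind); base-10 logs would scale them by ln(10).
Straight-line inputs are flagged degenerate.

## Synthetic data

The generator emulates the structure of real inputs: lognormal reference
abundances (log-sd 2.0, so a few species dominate totals, as observed in
real assemblages), linear log trends from additive habitat/migration
effects (sd 0.005) plus species deviations (sd 0.008) around an assemblage
mean of −0.003/yr, a smooth sinusoidal wiggle (amplitude 10% of each
species' total log change, random phase and period, zeroed at the reference
year) so that smoothing is non-trivially exercised, heteroscedastic
lognormal observation noise (CV 5%) with matching reported SEs, population
estimates with 10% lognormal error and ±3 SE min/max bounds (so
SE = span/6 exactly), trait tables with configurable mass–trend coupling, a
Yule phylogeny built by successive random splits (ultrametric), and
suitability series with known logit slopes. Optional leading missing years
and zero counts exercise the preparation rules.

What it does *not* emulate: country-level scheme idiosyncrasies, serially
correlated observation error, taxonomic mismatches, non-native species, or
density dependence. Passing tests therefore demonstrate correctness of the
machinery and calibration under stated-error conditions, not robustness to
the full messiness of real monitoring data.

`paper_like_scenario()` is a fixed-seed assemblage of 180 species over
1966–2018 in which abundance and body mass are negatively coupled and
trends are negatively coupled to abundance (abundant small-bodied species
decline; rare large-bodied species increase). A uniform and a
mass-proportional trend adjustment are solved (by root finding on the
wiggle-free skeleton) so the true totals change by −19% in abundance and
+7% in biomass; the realised trajectory adds the wiggle, so its endpoint
change differs from the calibrated value by up to ~1 point.

## Calibration and numerical notes

- The acceptance campaign (100 assemblages of 40 species × 40 years at
  default noise, reduced MCMC of 2 chains × (250 + 250)) measures 93/100
  coverage of nominal 95% intervals on total percent change. The residual
  few-percent understatement traces to the deliberate misspecification
  between the generator's smooth sinusoidal deviations and the model's
  random walk; standardized errors have sd ≈ 1.08 with negligible bias.
- Problem sizes in tests and the acceptance script (species counts,
  replicate counts, chain lengths) are chosen as the smallest that make the
  statistical checks sharp; defaults in the library itself are larger.
- GCV on an exactly log-linear noiseless series is penalty-indifferent (all
  penalties reproduce the line); ties in quartile assignment break by
  species id; the reference-year deviation is pinned to zero through a
  large precision (10¹²) that cancels exactly in all Metropolis ratios.
- Bootstrap intervals are bit-reproducible under a fixed seed; all MCMC
  seeds derive from a single `SeedSequence`.

## Known limitations

- The observation layer treats log-scale SEs as known; severely
  misreported SEs propagate directly into interval width.
- The per-km² change rates require a user-supplied region area
  (`AnalysisConfig.area_km2`); none is built in.
- PGLS assumes the supplied branch lengths are proportional to expected
  trait covariance; no rate transformation other than λ is offered.
- The bundled SDM is a deliberately simple logistic GLM; ensemble SDMs
  should be run externally and supplied as suitability series.
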