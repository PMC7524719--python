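# Methods

This note documents the statistical procedures implemented in `palmfrug`,
the assumptions behind them, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
choices that matter for reproducibility.

## Assemblage aggregation

The sampling grain is the botanical country. For each country and faunal
scenario the package reports the median and the "maximum" — defined
throughout as the 95th percentile across member species — of palm fruit
length (cm) and frugivore body mass (kg). The 95th percentile is used as a
robust maximum to limit the influence of single outlier species. Quantiles
use linear interpolation with plotting position h = (n-1)p + 1 (numpy's
default); a nearest-rank rule would differ only for very small assemblages.
Aggregation happens on the natural scale; logs are taken at the modelling
stage (slopes of log-log regressions are invariant to the log base; natural
logs are used).

Palms with missing fruit length are filled with the unweighted mean of
measured congenerics; a species with no measured congener is dropped with a
warning. Four species are excluded by default: one naturally occurring
sterile hybrid (no congeners to fill from) and three water-dispersed species
whose fruits are rarely taken by animals. Exclusions are flagged, not
deleted, so provenance survives to the output tables.

Two faunal scenarios are supported. "Current" uses extant frugivores and
present-day occurrences. "Present-natural" is the counterfactual assemblage
had Late Pleistocene/Holocene extinctions not happened: extinct taxa are
added under one of three classification tiers, all of which require a
predominantly herbivorous diet —

* liberal: any herbivorous extinct taxon;
* default: family-level frugivory fraction >= 0.40 among extant relatives,
  or an explicit paleo-diet override naming the species;
* conservative: family fraction >= 0.50.

Tier membership is nested (conservative within default within liberal). The
override list is the configuration hook for taxa whose extant relatives are
poor dietary analogues. Countries with no extant frugivore or no palm are
dropped with a warning in every scenario.

## Climate predictors

Six bioclimatic variables are reduced by PCA on the correlation matrix
(variables are z-scored first, since their units are incommensurate); the
first three components are the current-climate predictors. PCA signs are
arbitrary, so each component is pinned to have its largest-magnitude loading
positive — without this, coefficient signs would not be reproducible across
runs. Past climate change enters as the anomaly between the Last Glacial
Maximum ensemble-mean surface and the present value for mean annual
temperature and annual precipitation. The default anomaly is the absolute
magnitude |LGM - present| so that larger values always mean more change; the
signed difference is available by flag. All predictors are standardized to
unit sample variance before model fitting so effect sizes are comparable;
the scaling is stored and inverted exactly for raw-scale slopes.

## Model averaging

Candidate models are all 2^p subsets of the predictors, intercept-only model
included. Each is an OLS fit scored by AICc, with k counting intercept,
slopes and the Gaussian residual variance (the standard ML convention).
Akaike weights are normalized exp(-dAICc/2). Averaged coefficients use the
zero-fill convention — a predictor absent from a model contributes zero —
which deliberately shrinks predictors that only appear in poorly supported
models. Unconditional standard errors use the revised squared-term
estimator, `se_j = sum_m w_m sqrt(se_mj^2 + (b_mj - bbar_j)^2)`, with the
zero-filled terms included; 95% CIs are normal-approximation intervals
around the averaged coefficient (the interval construction is labelled in
the output since other constructions exist).

The partial-SD averaging mode rescales each candidate's coefficient by
`SD(x_j) * sqrt(1/VIF_j) * sqrt((n-1)/(n-p))` divided by SD(y), where the
VIF is computed among that model's own predictors and p is that model's
predictor count, before averaging. This blunts the inflation of averaged
effect sizes under collinearity.

Relative importance of predictors in the full model uses the LMG
decomposition: a predictor's share of R² is its incremental R² averaged over
all p! orderings of entry, computed exactly from subset R² values with
combinatorial weights. Shares are nonnegative up to collinearity artifacts,
order-invariant, and sum to the full-model R² to machine precision (this is
asserted in tests at 1e-10). The enumeration is limited to p <= 10.

## Spatial regression

Botanical countries are irregular in size and spacing, so neighborhoods use
the sphere-of-influence rule: each unit's circle has radius equal to its
nearest-neighbor distance, and two units are neighbors when their circles
strictly overlap. Tangency does not count — ties are measure-zero but the
rule must be deterministic. The rule leaves no isolates (every unit reaches
its nearest neighbor) and is symmetric by construction. Distances are
Euclidean on the supplied projected coordinates; callers supply an
equal-area projection when working with real geography. Weights are
row-standardized (w_ij = 1/deg(i)), which makes W asymmetric whenever
degrees differ; that asymmetry is expected and documented.

The SAR error model y = Xb + u, u = lambda W u + eps is fitted by maximum
likelihood: for fixed lambda, b and sigma² follow from OLS on the filtered
variables (I - lambda W)y and (I - lambda W)X, and the concentrated
log-likelihood uses log|I - lambda W| = sum log(1 - lambda e_i) with the
eigenvalues e_i of W obtained from its similar symmetric form
D^-1/2 A D^-1/2 (real for symmetric neighbor graphs). lambda is searched on
(1/min(e), 1) with a bounded scalar optimizer (xatol 1e-8); estimates within
1e-4 of a bound are flagged. Pseudo-R² is the squared Pearson correlation of
fitted and observed values. Residual autocorrelation is tested with Moran's
I on the filtered innovations, reporting both the normal-approximation
p-value and a permutation p-value (999 permutations by default), since the
two inference variants can disagree at small n.

The spatial variance decomposition is two-stage: an intercept-only SAR error
model is fitted first, and the LMG decomposition is then applied to an OLS
of its response residuals on the predictors. The resulting shares are a
pseudo-decomposition — variance explained after spatial structure has been
absorbed by the spatial intercept model — and sum to the stage-2 R².

## Red List CTMC

Category change is modelled as a continuous-time Markov chain on the ordered
categories LC, NT, VU, EN, CR, EX, where EX merges Extinct, Extinct in the
Wild and possibly-extinct CR flags. Transitions are allowed only between
adjacent ranks, so the generator is tridiagonal with ten rates (five up,
five down); the EX->CR rate is fixed at zero by default, making EX
absorbing, because reversals out of putative extinction are unobserved and
the free parameter would otherwise soak up noise. The likelihood of a
transition-count table observed over t years is `sum_ij n_ij log P_ij(t)`
with P(t) = expm(Qt): each species' category history is an independent
realization of the chain observed at two time points.

Rates are estimated in log space (bounds e^-14 to e^3 per year) with
L-BFGS-B from multiple random restarts (default 10, uniform log-rates in
[-8, 0]); the best restart is kept and rates below 1e-6/yr are flagged as
boundary estimates. Two datasets are fitted separately — defaults emulate a
broad mammal table observed over 12 years and an ungulate/carnivore table
over 33 years — and the two ML rate vectors are averaged element-wise
(rates, not probabilities; a fixed zero participates in the mean).
Parametric bootstrap resamples end categories from the fitted P(t) holding
observed start totals, refitting each replicate.

The "low" defaunation scenario takes P_i,EX(100) from the averaged chain.
The "high" scenario uses constant per-category rates via
P_ext = 1 - exp(-rt); the default rates correspond to the conventional
criterion-E-style 100-year extinction probabilities (LC 0.001, NT 0.01, VU
0.1, EN 0.667, CR 0.999) and are ordinary config inputs, not estimates made
here. Data Deficient species take the LC probability, a conservative choice.

A note on validation power: a transition rate observed through N direct
events has sampling error of roughly 1/sqrt(N) in relative terms, so a
25%-relative-error recovery check passed in >=90% of replicates is only
meaningful when every rate has on the order of 100+ expected events (25%
then being a >=2.5-sigma band). The rate-recovery study in the test suite
and acceptance script uses a chain designed to meet that bar at 5000
species over 12 years; chains with thinly observed rates would fail such a
check for purely statistical reasons even though the estimator is unbiased.

## Defaunation projection

Extinction is simulated 1000 times (configurable): each extant frugivore
survives with probability 1 - P_ext(category), drawn once per simulation
globally — a species dies in all countries at once, because Red List
categories encode global risk (per-country independent draws are available
by flag). Per country and simulation the 95th-percentile and true maximum
surviving body masses are recorded; all-extinct assemblages score zero, and
countries extirpated in every simulation are reported as undefined rather
than projected (log of zero mass).

Mean simulated maxima are pushed through a full OLS model (all climate
predictors plus log current maximum body mass, on the raw scale) to predict
the fruit size the fitted relationship would require; predictions are
back-transformed by plain exponentiation without a smearing correction. The
impact is a difference of fruit sizes in cm. Two baselines exist: observed
present-day fruit size (the headline definition, default for the
95th-percentile variant) and the model's prediction at present-day body mass
(default for the true-max variant). The predicted-minus-predicted mode
isolates the body-size term, removing residual noise, and is the only mode
under which the true-max impact is guaranteed nonpositive — the true
maximum of a surviving subset cannot exceed the present maximum, whereas a
95th percentile can rise when small species are lost. Each variant projects
through a model fitted on its own maxima (95th percentile or true maximum).

## Synthetic worlds

The generator produces every pipeline input with known truth. Country
centroids are uniform on a 1000 x 1000 km plane, split into three regional
bands. Climate is built from three latent Gaussian-process fields with
exponential covariance exp(-d/range) — the simplest positive-definite kernel
with a tunable correlation length (default 250 km) — mixed into six
bioclim-like variables with small noise so three components capture >90% of
the variance; LGM surfaces are offset by further smooth anomaly fields.

Mammals have log-normal masses (default log kg mean -1, sd 1.8) and
family-structured diets spanning the 0.40/0.50 frugivory-fraction tier
thresholds. Extant species get IUCN categories from an ordinal-logistic
latent variable in standardized log mass (slope 0.8 by default), making
threat size-biased; 4% are relabelled Data Deficient. The extinct cohort
(12% of the extant count by default) draws masses shifted upward by 4
natural-log units, emulating strongly size-selective extinction, and is
biased toward frugivorous families.

Occurrences are spatially contiguous: each mammal occupies the countries
within a disk around a range center (radius log-normal around the value
giving ~45 frugivores per country), thinned by independent Bernoulli draws
tied to country richness multipliers. Contiguity matters: it makes the
95th-percentile body mass vary smoothly in space, which is what makes
neighboring countries' trait values mutually consistent once palm species
are shared across borders. Palms have a home country (a few genera per
country, so congeneric gap-filling stays local); only below-median
("small-fruited") palms spill over into the nearest neighboring countries,
reflecting the dispersal limitation of large-fruited species that motivates
the analysis in the first place. About 8% of palm fruit lengths are blanked
to exercise gap-filling, and the four default-excluded species are injected
with large fruit values so exclusions are consequential.

Fruit lengths are drawn per home country around a target
`alpha + beta * log M95_c + climate terms + Gaussian noise` (beta defaults
to 0.6; country-level noise sd 0.15, within-country spread 0.35 on the log
scale) and then calibrated by a short fixed-point iteration so the
*realized* assemblage 95th percentile — including shared species — follows
the stated relation. The generator therefore guarantees the estimand, not
merely an approximation to it; residual deviation (median well under 0.05
log units) comes from the later gap blanking and from countries whose
percentile is pinned by shared species.

What the generator does not emulate: phylogenetic structure in traits,
realistic range geometry beyond disks, island/mainland contrasts,
observation error in trait measurements, and any dependence of extinction
risk on range size. Passing tests therefore demonstrate that the estimators
recover the generating process under clean conditions, not that real
checklist data satisfy these assumptions.

## Numerical and design notes

* Determinism: one integer seed feeds named SeedSequence child streams, one
  per generator stage; pipelines rerun bitwise-identically for a fixed
  config, and every output CSV carries a hash of the configuration.
* Matrix exponentials use scipy's scaling-and-squaring `expm`; tiny negative
  round-off in P(t) is clipped and rows renormalized (deviations are below
  1e-12 before renormalization).
* The 95th percentile of an assemblage with one species is that species'
  value; constant assemblages return the constant.
* Degenerate inputs fail loudly: empty assemblages, constant predictor
  columns, duplicate centroids, unknown IUCN labels, rank-deficient designs
  and invalid configs all raise with the offending name or row.
* The candidate set always includes the intercept-only model; AICc ties need
  no tie-breaking because weights are continuous in dAICc.
* Default problem sizes (129 countries, 2400 palms, 1800 mammals, 1000
  simulations, 50-replicate recovery studies) keep a full pipeline run in
  the tens of seconds while leaving Monte Carlo errors well inside the
  tolerances asserted in tests.

## Known limitations

* The unconditional CI for averaged coefficients is a normal approximation;
  no small-sample or model-selection-aware interval is offered.
* SAR fitting uses dense eigenvalue decomposition — fine for hundreds of
  units, not thousands.
* The LMG decomposition is exponential in the predictor count (capped at
  10).
* The defaunation projection holds climate fixed and treats the fitted
  size relationship as causal and stationary; it quantifies required change,
  not a forecast of evolutionary response.
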