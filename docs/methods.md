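# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limitations of the `skyglow` pipeline. It describes what the
code computes; every number quoted as an outcome is recomputed by the test
suite or by `scripts/acceptance.py`, not stated from memory.

## Count model

Survey counts are modelled as negative binomial with a log link, in the
mean–dispersion (size) parameterisation used throughout the package:

    y_i ~ NB(mu_i, k),   Var[y_i] = mu_i + mu_i^2 / k,

so the Poisson model is the k → ∞ limit (asserted numerically in the tests).
The linear predictor contains each landscape covariate at exactly one buffer
radius (its scale of effect), an optional ALAN × urban product whose two
parents carry their own scales, temporal covariates (sun angle and its
square, day of year and its square, lunar illumination), geographic
covariates chosen by a preliminary AIC screen, and a prior-count covariate
(the mean count over earlier surveys at the same station in the same or the
previous calendar year; zero when no earlier survey qualifies — a documented
default for a case the protocol leaves silent). Zero-inflated Poisson is
available for the model-form comparison; its structural-zero component is
intercept-only.

Counts are treated as *relative* abundance: a constant unknown fraction of
the individuals present, valid when detection probability is approximately
equal across surveys — the assumption the detection module is built to check.

## Priors and sampler

Priors (all configurable; these are the defaults): Normal(0, 2.5²) on
coefficients of standardized covariates, Gamma(0.1, 0.1) on the NB dispersion
k, Uniform(0, 1) on the ZIP inflation. These are weakly informative stand-ins
chosen on the standardized scale; no prior sensitivity beyond that is built
in.

The sampler is an adaptive random-walk Metropolis-within-Gibbs scheme:
coefficients update one at a time with scalar Gaussian proposals, the
dispersion on the log scale, the inflation on the logit scale. Step sizes
adapt toward a 25–40% acceptance rate during burn-in only, so the retained
chain is a fixed-kernel Markov chain. The linear predictor is maintained
incrementally (one O(n) likelihood evaluation per scalar update). Final
inference uses 3 chains × 12,000 iterations with 3,000 burn-in, retaining all
27,000 post-burn-in draws unthinned; thinning is deliberately not offered
because it only discards information at fixed chain length. Convergence is
checked by split-chain potential scale reduction (classic R-hat; constant
parameters report NaN rather than raising).

## Scale selection (BLISS)

Each multi-scale covariate j carries a latent categorical indicator s_j over
the radius set {400, 1600, 6400} m with a uniform prior; the design column
that multiplies β_j is x_j(s_j). Per sweep the sampler (1) updates all
coefficients given the current scales, (2) draws each indicator from its
full conditional over the radii holding the coefficient fixed, and (3)
updates the dispersion. This update was chosen over reversible-jump for
simplicity: the coefficient is shared across scales of the same standardized
covariate, so holding it fixed while switching columns keeps the chain valid
and mixes well at K = 3. The interaction product carries two parent
indicators of its own, so the interaction's scales are selected separately
from the parents' main effects. The radius count is guarded (`max_radii`,
default 3): with six nested buffers the indicator chain fails to mix because
neighbouring radii are nearly collinear, so local/intermediate/landscape is
the supported resolution.

Scale-selection output is the proportion of retained draws selecting each
radius per covariate; the selected scale is the argmax, with exact ties
broken toward the smaller radius (logged) — a tie means the data do not
separate the scales, and the smaller buffer is the more conservative claim.
A covariate is flagged as sign-conflicted when two scales' conditional 80%
intervals (computed only over draws selecting that scale, minimum 100 draws)
sit on opposite sides of zero; the 80% level and the 100-draw floor are
explicit package choices for a qualitative rule that has no canonical
numeric form. Sign-conflicted covariates are then entered at both scales as
separate columns in the final model.

## Derived quantities

* **Prediction curves**: per draw, `E[y] = exp(eta)` over an ALAN grid at a
  fixed urban level with all other covariates at their standardized means
  (zero); summaries are the across-draw mean and 2.5/97.5 percentiles. Grids
  are capped at the conditional 99th percentile of ALAN among surveys with
  urban cover at or below the referenced level (nearest-rank quantile), so
  curves never extrapolate beyond the joint support of ALAN and urban cover.
* **Percent change**: `100·(E[y|a1]/E[y|a0] − 1)` per draw, summarized by the
  posterior mean and percentile CI. Summarising per-draw ratios (not ratios
  of posterior summaries) matches how posterior predictions compose; point
  arithmetic on a posterior-mean coefficient can differ by about a point.
* **Sign-switch threshold**: with an interaction, `d eta / d ALAN = 0` at the
  standardized urban level `−β_ALAN/β_int`, mapped to a natural proportion
  through the urban column's scaling constants. Draws whose signs admit no
  switch in [0, 1] are retained untruncated (the percentile CI absorbs
  them); a clipped triple is provided for reporting on the proportion scale.
* **Posterior coefficient correlations** among ALAN, urban and the
  interaction flag non-identifiability (advisory at |r| > 0.9), mirroring
  the practice of dropping the interaction when it cannot be separated.

## Detection model

Minutes-detected out of six per individual is a binomial GLM with logit link
(maximum likelihood, via statsmodels) on ALAN plus the temporal covariates;
minutes are treated as independent Bernoulli trials, which the binomial
response implies — within-survey autocorrelation of cues is not modelled.
The whole-survey detection probability is `p_survey = 1 − (1 − p_min)^6`.
The sensitivity filter retains surveys with `p_survey ≥ 0.9` (at-threshold
surveys are kept; the rule removes those strictly below) and refits the
abundance model, reporting coefficient deltas and CI-overlap flags.

The simulate-refit harness generates counts from a fitted model's
posterior-mean coefficients at the selected scales over the original design
rows (a draw-based mode exists behind a flag), refits, and reports which
generating values fall inside the refit 95% CIs plus scale-match flags.

## Synthetic-data generator

The generator emulates the structure the analysis assumes, not any
particular geography:

* **ALAN raster**: point sources with lognormal intensities deposited on a
  300 m grid (the radiance product's grain), lightly blurred, plus a
  Gaussian-blurred skyglow field (bandwidth 2,000 m by default — skyglow
  reaches much farther in reality; the kernel is a stand-in with the right
  qualitative reach, and the bandwidth is configurable).
* **Urban coupling**: urban patches attach to the brightest light sources —
  with footprint and peak cover scaling with source intensity, since towns
  are both bright and large — or sit at random locations; the mix between
  the two is scanned so the realized station-level ALAN–urban correlation at
  the 1600 m buffer lands within ±0.15 of the configured target (default
  0.6; 0.78 reproduces the correlation observed in the poorwill range). If a
  source layout cannot reach the target the sources are redrawn, at most
  four times, before failing.
* **Survey design**: straight roadside transects of 6–10 stations spaced
  1600 m ± 5% (keeping every gap within the ±10% the protocol implies), two
  surveys per station per year over two years by default. Routes are
  straight lines, not road networks, and volunteer route-choice bias is not
  modelled.
* **Temporal covariates**: sun angle uniform over the crepuscular window
  [−9°, +2°], day of year uniform over June–July, lunar illumination uniform
  [0, 1] — drawn, not computed from ephemerides.
* **Counts**: NB with default dispersion k = 2, a value chosen once to give
  variance roughly twice the mean at the observed count levels, since count
  distributions beyond means/SDs are not reported for this kind of survey;
  default intercept log(1.67) matches the reported mean count where birds
  were present. The three behaviour groups (territorial, extra-territorial,
  poorwill) are simulated independently with separate parameter sets.
* **Detection**: per-minute Bernoulli slots with a logit-linear model;
  a negative ALAN slope makes detection decay with light, which is what the
  confounding-control check exploits.
* **Calibration designs**: `make_multiscale_design` draws standardized
  multi-scale columns directly from a correlated Gaussian (within-covariate
  inter-scale correlation and cross-covariate correlation configurable).
  Sampler-calibration studies (scale recovery, coverage, DIC ordering,
  confounding control) use it because only the correlation structure matters
  there and it removes the raster cost from tight loops.

What passing tests on these data do **not** show: robustness to spatial
autocorrelation of counts, observer heterogeneity, route-level clustering,
real skyglow physics, or misclassified land cover — none of which the
generator produces.

## Numerical choices

* Buffer means use a center-in rule (a cell contributes iff its center lies
  within the radius); radiance pixels are coarse relative to the 400 m
  buffer, so area weighting would change little, and the rule is isolated in
  one function so it can be swapped. Edge-truncated buffers are allowed with
  a warning and a coverage fraction.
* Land-cover mode compositing breaks ties toward the most recent tied year.
  Gap-filling gives primary-inventory classes precedence; cells unclassified
  in both inventories get zero in every indicator.
* Standardization is population z-scoring; quadratic columns are the square
  of the standardized linear term, re-standardized, so linear and quadratic
  columns stay on comparable scales. Scaling constants are stored and
  invertible to 12 digits.
* Quantiles for ALAN caps use the nearest-rank rule; posterior intervals use
  linear-interpolation percentiles (numpy default).
* DIC uses the Spiegelhalter effective-parameter form
  `pD = Dbar − D(theta_bar)`; the half-variance form is available behind a
  flag.
* AIC counts the NB dispersion as a parameter. The all-subsets screen
  (`dredge`) treats quadratic columns as independent candidates, so a square
  can enter without its linear term, and is capped at four terms per model
  and 20 candidates total.

## Problem sizes

Sampler-property studies run at n = 800 surveys with 3 chains × 2,000
iterations (500 burn-in) and 10–20 replicates; DIC and confounding studies at
n = 500–800 with 3 × 1,500 (400). These sizes were chosen as the smallest at
which the Monte-Carlo properties under study are comfortably resolved; the
full-length configuration (3 × 12,000, 3,000 burn-in) is exercised where the
claim is about draw accounting itself.

## Known limitations

* No random effects (route, observer, year) and no spatial autocorrelation
  terms — matching the target analysis, which also omits them.
* The Metropolis-within-Gibbs sampler is adequate for tens of parameters but
  not hundreds; there is no HMC/NUTS path.
* BLISS selects among a small discrete radius set; it does not estimate a
  continuous scale of effect, and the selected scale inherits the coarseness
  of the grid.
* The detection GLM pools individuals across surveys with survey-level
  covariates only; station effects on detectability are not modelled.
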