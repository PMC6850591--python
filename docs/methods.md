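# Methods

This note documents the statistical models implemented in `thermoniche`,
the choices made where the design was genuinely open, and what the
synthetic-data tests do and do not demonstrate.

## The estimation problem

Local abundance along an environmental gradient is noisy, zero-heavy and
confounded by everything that is not temperature. The package therefore
estimates the *ceiling* of abundance — its 80th quantile — as a function
of temperature, after first removing the influence of non-thermal
covariates, and summarises each species' realised thermal niche by a
split-Gaussian geometry: a peak T_opt with separate scales on the cool
and warm sides.

## Synthetic data generator

`synthetic_data` simulates the joint structure the analysis assumes:

- **Sites.** SST uniform over a configurable gradient (default 5–30 °C).
  Latitude decreases linearly with SST (plus scatter) so thermally
  similar sites are spatially close — required for buffer-based absence
  construction. Eight continuous covariates are generated through a
  Gaussian copula with a target Spearman correlation to SST (default
  0.6), emulating the collinearity between leading environmental axes
  and temperature. Coral and macroalgae cover trade off sigmoidally and
  cross near 23 °C; their sum stays ≤ 100 %.
- **Species.** Ground truth per species: T_opt, σ_min, σ_max > 0, a peak
  Poisson mean (log-normal across species, median 12 per 500 m² — the
  between-species abundance distribution is a configuration choice, not
  an empirical calibration), a structural-zero probability π ∈
  [0.10, 0.30), and a signed coral-vs-macroalgae preference. Guild
  membership (fraction tropical = `guild_mix`, exact by rounding) sets
  the T_opt range on either side of 23 °C. Scenarios control σ
  asymmetry: `symmetric` (σ_min = σ_max), `warm_skew` (σ_min > σ_max,
  T_skew < 0), `cool_skew` (the reverse), `mixed` (two thirds of each
  guild get the guild-typical skew). In `mixed`, skewed species are
  placed near the truncating end of the gradient, because truncation of
  niche space is the mechanism that produces skewed *realised* shapes;
  a skewed σ pair far from the gradient edge still yields an
  abundant-centre realised distribution.
- **Counts.** Per species × site: zero with probability π, otherwise
  Poisson with mean peak_lambda · exp(−((T−T_opt)/σ_side)²) ·
  exp(pref · (coral − macroalgae)/100). The habitat link is a bounded
  monotone choice (zero preference ⇒ multiplier 1); no generative form
  is claimed beyond that. Counts are integers and are treated as already
  site-averaged densities.
- **Randomness.** One master seed; every operation draws from an
  independent child stream derived with fixed `SeedSequence` spawn keys
  (offsets in `config.py`), so outputs are bit-reproducible and adding a
  consumer never shifts existing streams.

Ground truth includes `true_shape_class`: the shape label implied by the
truth and the gradient, obtained by applying the edge-drop rule to the
true intensity at presence-probability-weighted edge quantiles. Recovery
tests score the pipeline against this oracle, not against the scenario
tag, since the two legitimately differ for weakly truncated species.

What the generator does **not** emulate: coastline geometry and
dispersal limits, temporal/seasonal dynamics, observation error beyond
Poisson noise, and fine-scale habitat mosaics. Passing recovery tests
therefore demonstrates statistical correctness of the estimators under
the assumed data-generating process, not robustness to every feature of
field data.

## Survey preparation

Absences are constructed, not observed: a species receives a zero at a
surveyed site if it was absent there but present somewhere within a 10°
buffer, with distance computed as planar Euclidean in degrees (the
buffer is a degree-space construct; no great-circle correction).
Eligibility is inclusive at the stated thresholds (≥ 30 presences,
≥ 3 °C presence range). Absences are subsampled without replacement to
the presence count inside each bootstrap replicate. Sampling intensity
is distinct sites per °C across the species' frame; being constant
within a species it is dropped automatically (with the other
zero-variance columns) from per-species model designs.

## First stage: residualization

Covariates are standardised and decomposed by species-level PCA; axes
with variance fraction strictly > 0.10 are retained. The count model is
a zero-inflated Poisson with log link on the Poisson mean (retained PC
scores + depth + protection) and an intercept-only logit inflation part
— the simplest identifiable choice, as no inflation design is implied by
the problem. Non-convergent fits fall back to a plain Poisson GLM,
flagged. Residuals are response residuals y − (1−π̂)λ̂, keeping the
second-stage quantile interpretable as a maximum-abundance anomaly on
the count scale. A seeded permutation Mantel test (999 permutations,
p = (1 + #{r* ≥ r})/(n+1)) checks residual spatial autocorrelation; no
spatial term is added to the models.

## Second stage: the quantile ceiling

The 80th quantile of residuals vs temperature is fitted by minimising
pinball loss plus a second-derivative roughness penalty over a **natural
cubic regression spline with k = 4 quantile-placed knots** (dimension 4;
linear beyond the boundary knots). Two numerical choices matter:

- *Basis.* A clamped B-spline of dimension 4 has no interior knots and
  collapses to a single cubic polynomial, which biases peak location by
  up to ~2 °C when the sampled range is asymmetric about the peak; the
  natural-spline basis with interior knots does not.
- *Knot placement.* Knots are placed at quantiles of the **presence**
  temperatures, concentrating flexibility where abundance information
  lives; beyond the occupied range (where only constructed absences
  exist) the fit is linear by construction.

Optimisation uses a convolution-smoothed pinball loss (ε = 10⁻³ × IQR)
with analytic gradients under L-BFGS; the problem is convex. The
smoothing parameter is chosen from a 10-point log-spaced grid by 5-fold
cross-validated (unsmoothed) pinball loss, ties going to the smallest
value; it is selected on the first bootstrap replicate and reused for
the rest (re-selecting per replicate costs ~7× and does not change the
aggregated curve in simulation). Predictions from the 25
absence-subset replicates are averaged pointwise on a common 200-point
grid spanning the occupied range; T_opt is the argmax, ties broken
towards the lower temperature.

The temperature-effect permutation test uses the pinball-loss reduction
of the smooth over the constant-quantile fit (clipped at zero, since the
spline family nests the constant) with 199 temperature permutations.

## Shape classification

The aggregated curve is shifted so its minimum is zero (residual curves
can be negative; "% of maximum" presumes a non-negative scale) and
evaluated at T_min and T_max (clamped into the grid span). With
threshold θ = 0.75 (and 0.50 as a sensitivity check): both edges < θ ⇒
abundant-centre; neither ⇒ no-trend; only the warm edge ≥ θ ⇒
warm-skewed; only the cool ⇒ cool-skewed. Category proportions are
tested against a uniform n/4 expectation by Pearson chi-square (df = 3).
`chi_square_from_percentages` reconstructs the statistic from printed
category percentages with expectation n/4.

## Niche geometry

T_min/T_max are 2.5th/97.5th empirical quantiles (linear interpolation
between order statistics — the type-7 convention, used everywhere in the
package). σ's are |edge − T_opt|/1.96. The printed one-sided formula
(T_min − T_opt)/1.96 is negative whenever the edge lies below the
optimum, while the skew semantics (centred ⇒ skew 0, warm-skewed ⇒
negative) require non-negative scales, so absolute distances are used. A
T_opt outside [T_min, T_max] is clamped to the nearer edge with the
corresponding σ = 0, logged. Guild ties at exactly 23 °C go to tropical.
Habitat association is the abundance-weighted mean cover at presences
minus the unweighted mean over the species' frame.

## Pooled split-Gaussian model

Presences are standardised (t = (SST − T_opt)/mean(σ_min, σ_max);
a = abundance/max abundance) and reduced to per-species 99th percentiles
within half-open [left, right) bins of width 0.1 anchored at zero. The
exponent uses the printed form −((T−T_opt)/σ)², without the conventional
Gaussian ½ factor; the ½-factor question is noted as an ambiguity of the
source formulation and the printed form is implemented unchanged.

The observation model is Gaussian on the binned percentiles — the mean
function and sampler settings are fixed by the analysis design, the
likelihood is not, and Gaussian error on a bounded [0, 1] summary is the
simplest adequate choice at these noise levels. Priors are weakly
informative: c ~ Uniform(0, 2), t_opt ~ Normal(0, 1), σ's ~
half-Normal(0, 5), error sd ~ half-Normal(0, 0.5); recovery tests show
the posterior is data-dominated at the simulated sizes.

Sampling: four-chain adaptive random-walk Metropolis, vectorised across
chains; the proposal covariance is re-estimated every 200 burn-in
iterations from recent history (scaled 2.38²/d) and frozen at the end of
burn-in, preserving detailed balance for the retained draws. Defaults:
10 000 iterations, burn-in 2 500, thinning 5 ⇒ exactly 1 500 retained
draws per chain. Convergence requires Gelman–Rubin
R̂ = √(((n−1)/n · W + B/n)/W) < 1.01 for every parameter; failure
triggers one automatic doubling of the iteration budget, after which an
unconverged fit is returned flagged, never silently. Sampler
correctness is enforced by an independent brute-force grid-search MLE
oracle (the Gaussian error sd profiles out, so the MLE minimises the
residual sum of squares over a refined 4-D grid): posterior means agree
with the oracle within 1 % in simulation. R² is computed from the
posterior-mean curve, both against per-species binned percentiles and
against cross-species bin means; aggregation removes between-species
scatter, so the second is systematically higher.

## Skew inference

T_skew ~ T_opt + coral + macroalgae per guild, with an order-level
random intercept plus family and genus variance components (nested
taxonomy as a proxy for shared ancestry). REML estimates are reported;
ML refits are used for likelihood-ratio tests (REML likelihoods are not
comparable across fixed-effect structures). Singular variance
components are dropped innermost-first with a flag; the fallback is OLS.
AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) with k counting fixed effects plus
variance parameters. Guild slopes are compared by the two-sample Wald
statistic z = (β₁ − β₂)/√(SE₁² + SE₂²); on reported guild coefficients
(−0.63 ± 0.02 vs −0.40 ± 0.04) this gives z = −5.14 — a slightly
different magnitude than a model-based interaction Wald test would give,
which is documented rather than forced.

## Problem sizes and determinism

Recovery tests run at the study conditions the analysis targets: 50
species × ~400 presences for end-to-end recovery (median |T_opt error|
≤ 1 °C, ≥ 80 % oracle-class agreement, ≥ 90 % skew-sign agreement), 500
binned points for split-Gaussian recovery, 100 for the MLE oracle,
n = 1 000 for quantile coverage, n = 5 000 for ZIP recovery. All
randomness flows through the master-seed protocol; identical seeds give
bit-identical outputs.

## Known limitations

- The quantile spline has 4 degrees of freedom by design; very sharp or
  multi-modal ceilings are under-resolved, and peak estimates for
  species truncated hard against the gradient edge carry ~1 °C bias
  toward the edge.
- Constructed absences encode a detectability assumption (insufficient
  local abundance), not true absence; no detection model is fitted.
- The deviance-explained summary sometimes quoted for quantile GAMs has
  no agreed definition for a pinball-loss fit and is not computed.
- The pooled model's Gaussian observation error ignores the boundedness
  of standardised abundance; at error sd ≲ 0.2 this is immaterial in
  simulation.
- Taxonomic random intercepts approximate, but do not replace,
  phylogenetic comparative methods.
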