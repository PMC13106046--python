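# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical choices, and the known limitations of the package.

## Scope and notation

Nine ANC indicators are estimated per country and year over a configurable
panel (default 1995–2023). Proportions are modelled on the logit scale,
the two means (content mean, mean visits) on the natural-log scale; the
content mean is additionally clamped to [0, 5] after back-transform.
Clinic-conditional quantities (the four clinic items, the composites,
early initiation) are modelled among ANC attendees and later multiplied by
ANC1 coverage; iron supplementation and mean visits are modelled directly
among all women with a livebirth (survey respondents are asked about iron
regardless of attendance, and non-attendees contribute zero visits at
tabulation). ANC1 itself enters as an input draw cube: attendance is
estimated by a separate model in the production setting this mirrors, so
the generator emulates its posterior directly.

## Tabulation

* Only the most recent livebirth within 24 months of the interview is
  retained (boundary inclusive: a gap of exactly 24 months stays). This
  limits cohort effects and recall bias relative to the 3–5-year windows
  surveys actually ask about.
* Estimates are survey-weighted; the effective sample size is Kish's
  (Σw)²/Σw², so unequal weights reproduce the design effect without any
  side channel from the generator.
* First trimester is operationalised as first visit in pregnancy months
  1–3; with monthly reporting this is identical to "< 4 months".
* The source year is the weighted mean birth year, rounded.
* Boundary handling: proportions are clamped to [0.5/n_eff, 1 − 0.5/n_eff]
  with the standard error floored at the binomial SE of the clamped value;
  means are floored at 0.5/n_eff with a 1% relative SE floor. Without the
  offsets, a survey where every woman reports an item would carry zero
  logit-scale variance and dominate the fit.

## Crosswalk

For each composite × alternate definition, sources reporting both give
pairs d_i = g(full_i) − g(alt_i) (g = the indicator's transform) with
variance se²_full + se²_alt (delta method). The offset is the
inverse-variance-weighted mean with DerSimonian–Laird between-source
variance γ², refitted iteratively after dropping the ⌈trim·n⌉ pairs with
the largest standardised residuals (default trim = 0.1; exact ties broken
by lowest source id, making trimming permutation-invariant; at most 100
iterations, with a convergence flag). Adjusted estimates get
g(value) + β and variance + β_se² + γ², so a crosswalked source is never
more precise than its unadjusted self. This is an intercept-only,
regularised-by-trimming stand-in for a full Bayesian meta-regression
tool: it preserves the offset + variance-inflation + outlier-robustness
contract at desk scale, without splines or covariates.

## The three-stage estimator

**Stage 1 (prior).** y = Xβ + u_c + ε with country random intercepts
u_c ~ N(0, τ²) and heteroscedastic noise Var(ε_i) = σ²·v_i, where v_i is
the datum's transform-scale sampling variance. Fitted by REML on the
profiled (σ², τ²) likelihood (Woodbury identities keep it O(n) per
country; Nelder–Mead on the log-parameters). Predictions add each
country's BLUP; unseen countries get the fixed-effects part only. A
fixed-effects-only weighted regression is the fallback for singular fits
or fewer than two countries with data. Wald standard errors ignore
variance-component uncertainty and are mildly anticonservative
(|z| > 2 occurs ~8% of the time over replicate panels instead of 5%); the
recovery tests therefore assert unbiasedness tightly and calibration
loosely.

**Stage 2 (space–time smoothing).** m₂(c, t) = m₁(c, t) + Σᵢ wᵢ rᵢ / Σᵢ wᵢ
over all residuals rᵢ = yᵢ − m₁, with w = tricube(|Δt|/λ) × s, where s is
1 for the same country, ζ for other countries in the region, ζ² elsewhere.
Defaults λ = 10 years, ζ = 0.3, degree-0 (weighted mean — stable at sparse
edges). Cells with zero total weight keep m₁, so the prior is exact where
no data exist anywhere.

**Stage 3 (GP).** Per country, a Gaussian process with prior mean m₂ and
Matérn-3/2 covariance (amplitude η, length scale ρ = 10 years) is
conditioned on that country's own data with observation noise vᵢ. The
amplitude is the robust residual scale η = 1.4826 × MAD(y − m₂) across the
indicator's data, floored at 0.01 (configured default 0.3 when fewer than
five residuals exist). Cholesky solves try the matrix as-is and escalate
jitter 1e−8 → 1e−4 (×10) only on failure; posterior covariances are
symmetrised, and sampling uses an eigendecomposition square root with
negative eigenvalues clipped at zero so degenerate posteriors sample
cleanly. Draws (default 1000) are back-transformed to the natural scale.

## Draw-level postprocessing

Rescaling by ANC1, raking, and aggregation all happen per draw, in that
order:

1. attendee-conditional cubes × ANC1 draws → all-women scale;
2. content proportion ← min(content, five items) per cell and draw. The
   rake runs *after* rescaling because iron only exists on the all-women
   scale (its extraction denominator is all livebirths), so the all-women
   scale is the only one on which all six cubes are commensurable. For the
   four clinic items the min-constraint commutes with the shared positive
   ANC1 factor, a property the tests verify; for iron the all-women
   ordering anc1·P(all five | attend) ≤ iron coverage holds by
   construction.
3. region and global draws are livebirth-weighted means of member-country
   draws per year. Aggregation precedes summarisation: the weighted mean
   of draws is a draw, whereas a weighted mean of intervals is not an
   interval of anything — summarise-then-aggregate is deliberately not
   offered.
4. summaries report the draw mean and the 2.5/97.5 percentiles using the
   linear-interpolation quantile definition (numpy default).

Outcome correlations (maternal mortality ratio, neonatal mortality,
stillbirth rate) are Spearman by default, computed within each draw across
countries at a target year and summarised over draws; Pearson and
point-estimate variants are exposed. Draw-level Spearman is the default
because the outcome scales are heavily skewed and the draw level is where
the rest of the pipeline's uncertainty lives.

## Synthetic-data generator

The generator is the package's study design, not a fixture:

* **Covariates**: three smooth per-country series (an ANC4-like coverage
  trending upward, health-worker density, an access/quality index), each
  standardised to mean 0, sd 1 over the panel.
* **Truth**: for each channel, logit-scale linear predictor =
  intercept + β·x + country intercept (sd 0.25) + smooth temporal GP
  (squared-exponential, amplitude 0.25, timescale 10 y). Default
  β = (0.8, 0.3, −0.2). The heterogeneity scales are residual scales
  *after* conditioning on the covariates — the covariates exist precisely
  because they absorb most systematic cross-country variation — hence
  deliberately smaller than raw cross-country spread.
* **Items and composites**: each woman carries a shared N(0, 0.7²)
  logit-scale compliance factor; items are conditionally independent given
  it. Item logit offsets are solved numerically (Gauss–Hermite quadrature,
  60 nodes) so the item *marginals* equal the inverse-logit of their
  linear predictors exactly; the factor then only induces positive
  dependence. The content proportion is the joint all-five probability
  under this model (≥ the product of marginals, ≤ every marginal) and the
  content mean is the sum of the marginals — composites are never drawn
  independently.
* **Surveys**: Poisson number per country (default 5), interview dates
  uniform over the panel, Poisson(3000) women each, births uniform within
  a 60-month recall window (so the 24-month tabulation filter really
  filters), lognormal weights whose Kish design effect matches a
  U(1.2, 3) draw, a survey-level N(0, 0.1²) logit bias (non-sampling
  error), negative-binomial visit counts (1 + NB, dispersion 4) and
  first-visit months from a discretised Beta(a, 2) on months 1–9 with *a*
  solved so P(month ≤ 3) matches the early-initiation truth. Surveys drop
  the weight column, iron column, or one other item column with
  probabilities (0.11, 0.09, 0.01) — the observed shares of abbreviated
  sources among real ones. Iron for non-attendees uses a 2-logit penalty
  (supplements are obtainable outside ANC, but mostly delivered there).
* **Outcomes**: log-scale, strictly positive, decreasing in the all-women
  content mean with controllable noise.

What the generator does **not** emulate: nonresponse and selection bias,
age/parity structure, subnational heterogeneity, survey-instrument
wording effects, DHS recode layouts. Passing tests therefore show the
estimation machinery is correct and internally consistent under the
stated assumptions — not that real surveys satisfy those assumptions.

## Reproducibility

Every stochastic stage derives its generator from the master seed through
CRC-keyed `SeedSequence` spawn keys of (stage, indicator) names, so adding
an indicator never perturbs another's draws, and rerunning a configuration
is byte-identical. All numeric output is written at full double precision.

## Known limitations

* **Interval calibration in sparse panels.** The GP amplitude is a
  plug-in estimate from residuals at data cells, where stage 2 has already
  absorbed most of the signal; it therefore saturates near the survey
  noise scale. In panels with ~2 surveys per country over 29 years, truth
  deviates from the stage-2 prior at data-free cells by more than that,
  and the 95% draw intervals undercover (pooled coverage ≈ 72–78% in the
  replicate studies the acceptance script reports). Denser panels shrink
  the gap. This is a structural property of plug-in amplitude estimation
  in this estimator family, and the package reports the measured coverage
  rather than hiding it.
* Stage-1 Wald SEs are mildly anticonservative (no Satterthwaite-type
  correction).
* The crosswalk has no covariates or splines; definition effects are
  assumed constant across the panel.
* No subnational estimation, no age stratification, no holdout-based
  hyperparameter selection; λ, ζ, ρ are configuration defaults chosen for
  smooth multi-decade trends, not tuned values.
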