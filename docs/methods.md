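# Methods

## The Annual Anomaly

Each spring's daily catches `n_{y,d}` over the fixed window (day 1 = 1
April … day 45 = 15 May) define a cumulative fraction curve
`C_y(d) = Σ_{i≤d} n_{y,i} / N_y`. A multi-year baseline `C̄` summarizes the
average passage pattern, and the Annual Anomaly is

    AA_y = Σ_{d=1..45} [ C̄(d) − C_y(d) ]   (days).

The operand order is fixed by the sign convention: an early season runs its
curve *above* the baseline, making the differences negative, so negative AA
means earlier-than-average passage. The statistic has convenient exact
properties that the test suite relies on: a whole-season shift by k days
gives AA = ±k; AA is antisymmetric in its two curves; |AA| ≤ 44 for any
valid pair; and moving any single bird to a later day can never decrease
AA.

Two baseline variants are provided. `pooled` (the default) is the
cumulative curve of the across-years *sum* of daily counts, i.e. years
weigh in proportion to their totals. `mean_of_curves` averages the annual
fraction curves with equal weight; only this variant makes the included
years' AA values sum to exactly zero, which is why the zero-sum oracle test
uses it. The focal year is always part of the baseline (one common baseline
for all years), and excluded years contribute nothing to it.

Percentile dates use the first-crossing convention: d_p is the first
ordinal day whose cumulative fraction reaches p. Counts are daily integers,
so no within-day interpolation is attempted; users comparing against
interpolating conventions should expect differences of up to one day.
Duration is d90 − d10. Trends of AA, the percentile dates and duration are
ordinary least squares against the year number (first study year = 1), and
"total change" over the study multiplies the slope by the span in years.

## Data preparation

A date absent from the input inside the window is treated as *missing*
(mist-netting suspended), distinct from an explicit zero row (a true zero
catch). A missing (year, day) is imputed as the mean of the observed counts
on that ordinal day over the ±6 neighbouring years, the focal year
excluded; the window truncates at the archive edges, only originally
observed values act as donors, and imputed means are kept fractional
(rounding would bias the cumulative fractions for no benefit). Imputation
is idempotent and never alters observed cells. After imputation, springs
whose total is below 31 birds are excluded (a total of exactly 31 is kept);
their AA values exist only as trend-predicted fill-ins for the
autocorrelation screen and never enter the regression.

## Climate covariates

Monthly index series (NAOI, SCAND, SAH, IOD, SOI) are averaged over four
seasonal windows mapped onto each focal spring: Apr–May of the same year
(arrival), Nov–Mar ending in the focal year (wintering), Aug–Oct of the
previous year (southward migration) and Jun–Jul of the previous year
(previous breeding season). Daily station temperatures (ECA&D layout, 0.1
°C units, quality flag 9 = missing) give the local Apr–May mean. Together
with the year number this yields a 14-column covariate table. A month
missing inside a required window is a hard error, not a silent skip —
skipping would quietly change the estimand.

Response and covariates are standardized to mean 0, sample SD 1 (n−1
denominator), so regression coefficients are comparable across covariates.
Each windowed series (and the gap-filled AA) is screened with the Ljung-Box
portmanteau statistic, Q = n(n+2) Σ_{k≤m} r_k²/(n−k) at m = 10 lags,
against χ²_m. Q is invariant to shifting and scaling the series; the
implementation is cross-checked against an independent statistical library
in the unit tests.

## Regression and model choice

The standardized AA is regressed on the 14 standardized covariates. Model
search is exhaustive: all 2^14 = 16 384 subsets, each scored by
AICc = AIC + 2k(k+1)/(n−k−1) with AIC = −2ℓ̂ + 2k, where k counts the
intercept, the slope coefficients *and* the residual variance (the
information-criterion convention of the model-selection literature; stated
explicitly because conventions differ). Subsets with n − k − 1 ≤ 0 or a
saturated fit are skipped and logged. The enumeration is vectorized: with
Gram matrix G = A'A and c = A'y, each subset's residual sum of squares is
y'y − c_S' G_S⁻¹ c_S, solved in batches per subset size. Ties break
deterministically (smaller subset, then lexicographic term order). A
stepwise-backward pass — scored by plain AIC, starting from the full model
and dropping the term whose removal lowers AIC most until none does —
cross-checks the choice; the report flags whether the two methods agree.
Because AIC penalizes less than AICc at n = 34, the stepwise result
occasionally keeps one extra marginal term, so agreement is expected but
not guaranteed.

Diagnostics follow the workflow's needs: VIF_j = 1/(1−R²_j) from regressing
covariate j on the others (for two covariates this is exactly 1/(1−r²));
partial R² uses Type-II sums of squares, SS_j/(SS_j+SS_res) with SS_j the
RSS increase when term j alone is dropped (verified against brute-force
drop-one refits); each covariate is offered quadratically and the quadratic
form is kept only if it beats the linear one by more than 2 AICc; the
leave-one-covariate check refits the best model without each term and
regresses the residuals on the omitted term; residual normality uses
Shapiro-Wilk, with an explicit degenerate flag for exact fits.

## The synthetic generator

The generator is the test bed: it emulates the statistical structure the
analysis assumes, with known ground truth.

* Monthly index values are i.i.d. standard normal (optionally
  cross-correlated between indices within a month via a user Cholesky
  factor), so windowed annual covariates are white — matching the
  screening outcome the workflow requires before using OLS.
* Daily Apr–May temperatures combine a within-season warming ramp, a
  N(0, 1.2 °C) year anomaly and N(0, 2 °C) daily noise.
* Year y's true mean passage day is
  μ_y = 23 + trend·(y − 1982) + Σ_j e_j z_{j,y} + ε_y, with z the
  standardized covariates, e_j the effects in days per SD and
  ε ~ N(0, 1 day). Expected daily counts follow a Gaussian passage curve
  (SD 6.5 days) discretized to days 1–45 and renormalized; realized counts
  are Poisson (the minimal count-noise model). Expected totals are
  lognormal around 250 birds.
* Defaults are the study conditions: springs 1982–2017; missing days at
  rate 0.02; the springs of 1993 and 2011 forced to low realized totals
  (multinomial counts over a drawn total of 5–24 birds) so the exclusion
  path always runs with n = 34; and seven negative effects of −1.3 days/SD
  on the covariates of the selected model (local Apr–May temperature,
  Apr–May and Nov–Mar NAOI, Nov–Mar SAH, Aug–Oct IOD and SOI, Jun–Jul
  SCAND). Low-catch springs carry no missing days: imputation borrows
  from normal-level neighbour years and would otherwise inflate a low
  total above the exclusion threshold, which is not how real suspended
  netting behaves in a poor season.

With seven equal day-scale effects and this noise level, the realized
standardized coefficients come out near −0.4. Note the geometry: seven
orthogonal standardized effects of exactly −0.4 on a standardized response
are impossible (they would imply R² = 7·0.16 > 1); with independent
covariates the coefficients converge to ≈ −1/√7 ≈ −0.38 as noise shrinks.
A consequence of independent covariates at this effect size is a model R²
(~0.8–0.9) higher than field datasets typically show — real climate
indices are mutually correlated, which lowers attainable R² at the same
coefficient scale. The generator accepts a cross-correlation matrix for
users who want that regime.

What passing tests show, and what they do not: the generator reproduces
unimodal passage, covariate-driven timing shifts, missing days, low-catch
years and white covariates, so green tests demonstrate the pipeline's
correctness and its statistical calibration *under those conditions*. Real
data add observation-effort variation, weather-dependent catchability,
multi-modal passage from overlapping populations and covariate
autocorrelation, none of which the generator emulates; conclusions about
real archives still require the screening and diagnostic stages the
pipeline itself provides.

### True coefficients under window truncation

AA responds to a one-day shift of the mean passage day by slightly less
than one day: part of the passage curve's tails falls outside the finite
window (the shape is renormalized within it), and a year is compared
against a pooled baseline that includes itself (damping ≈ 1/n). For
coverage tests the true standardized coefficient is therefore taken as
e_j · a · sd(z_j)/sd(AA), where a is the delta-method factor computed from
the generator's own deterministic passage shape averaged over the realized
mean days, times (1 − 1/n). The factor is ≈ 0.95 under the defaults.
Confidence-interval coverage is evaluated on the full 14-covariate model,
not the post-selection model — post-selection intervals are known to
undercover and would test selection, not estimation.

## Numerical choices and edge cases

* Percentile crossing uses a 1e−12 tolerance so exact fraction boundaries
  (e.g. 0.5 reached exactly) count as crossed.
* A constant trend response returns slope 0, R² 0 by convention rather
  than erroring.
* Exact fits (zero RSS) are legal in `fit_ols` (infinite log-likelihood)
  but are skipped in the AICc ledger and flagged degenerate in
  diagnostics.
* Perfect collinearity raises an error naming the dependent columns, in
  both fitting and VIF.
* All randomness flows from a single `numpy` Generator seeded from the
  config; identical (config, seed) reproduce archives, climate files and
  ground truth bit for bit.

## Problem sizes

The acceptance script and test suite use the study-scale problem
throughout: 36 simulated springs (34 after exclusion), 14 candidate
covariates, full 16 384-subset enumeration per replicate; 200 replicates
for the recovery and null-calibration suites (100 in the acceptance
script) and 1 000 white-noise series for the Ljung-Box size check — sizes
at which the whole suite runs in a few minutes on a single core.
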