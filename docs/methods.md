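# Methods

This note records the statistical model behind `fittriage`, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
cohort does and does not emulate.

## Censored FIT and imputation

Quantitative FIT reports faecal haemoglobin in µg Hb/g faeces. Laboratories
censor at assay detection limits; different sites run different analysers,
so raw values arrive as `<7`, `<10` or `>400` alongside exact numbers.
Censored values are imputed to the limit itself (7, 10, 400 µg/g) before any
modelling. This is a deliberate simplification — it stacks probability mass
at three points — and two downstream choices depend on it:

- AUC uses the Mann–Whitney convention with ties counted 1/2, so the point
  masses are handled coherently;
- the CUSUM scan expects, and the documentation flags, mechanical jump
  points at the detection limits.

Assay limits are per-site configuration (lower limit ∈ {7, 10}, upper 400 by
default). Parsing is lossless: the raw string is preserved and re-serialised
verbatim.

## The urgent-conversion label

The binary outcome is whether a colon-capsule examination would convert to
conventional colonoscopy because of colonic pathology. Referral criteria
differ between services and are therefore explicit configuration
(`ConversionCriteria`); the default — colorectal cancer, any polyp ≥ 10 mm
(the usual "advanced polyp" size cut), or ≥ 3 polyps — is a documented
stand-in, not a normative claim. The label is a pure function of findings
and criteria, so re-derivation is idempotent and monotone in polyp size and
count. Conversion drivers other than pathology (poor bowel preparation,
incomplete transit) are deliberately out of scope; predicted conversion
rates are therefore lower bounds on real-world conversion.

## Cohort ingestion

Loading is complete-case: rows missing the FIT result, polyp count or
largest polyp size are excluded and counted in a completeness report; rows
failing validation (age < 18, implausible haemoglobin, malformed values) are
rejected with row-indexed diagnostics. Haemoglobin is fixed to g/L and
values outside 30–250 g/L are treated as unit errors (a g/dL entry would sit
near 11, far outside the band). No covariate imputation is performed.

## Diagnostic accuracy

AUC is the Mann–Whitney concordance probability. Confidence intervals use
DeLong's structural-components estimator, computed with the midrank
algorithm (the per-positive and per-negative placement values yield the
variance and, for two markers on the same patients, the covariance for the
paired test). Bootstrap intervals (stratified, seeded, 2000 replicates) are
available behind a flag. Intervals are Wald-type on the AUC scale, clipped
to [0, 1]; degenerate variance (e.g. perfect separation) collapses the
interval to the point estimate and the paired test returns p = 1.

Logistic models are fitted by maximum likelihood (statsmodels `Logit`) and
reported as odds ratios with Wald 95% intervals and p-values, matching
standard clinical reporting; profile-likelihood intervals are not
implemented. Complete separation raises an explicit diagnostic rather than
returning divergent estimates (detected via the optimiser's warnings and a
coefficient-magnitude guard at |β| > 50). The "adjusted" ROC is the ROC of
the multivariable model's in-sample predicted probabilities and is flagged
`apparent=True`: no cross-validation is applied, so it is optimistic for
out-of-sample discrimination.

## CUSUM threshold scan

The grid runs from `floor(min FIT)` to `max FIT` in steps of 0.1 µg/g,
stored as **integers in deci-µg/g** so grid arithmetic is exact (asserted:
consecutive grid points differ by exactly one unit). At each threshold t the
scan counts urgent conversions and all patients with FIT ≤ t (inclusive
comparison; imputed values participate like exact ones). A jump point is a
grid point whose urgent count exceeds the immediately previous grid point's
by ≥ `min_jump` (default 5) cases.

The conversion rate at t divides by the patients with FIT ≤ t — the
subpopulation that would be triaged to capsule at that threshold — rather
than the whole cohort; this reading reproduces the expected order of
magnitude (a fraction of a percent at low thresholds rising toward overall
prevalence at the grid maximum, which it equals exactly). The whole-cohort
denominator is available via `denominator="cohort"`. Off-grid queries raise
an error naming the nearest grid point instead of silently snapping.

## Incremental significance scan

Group 1 is FIT ≤ 10 µg/g (low FIT); for each t in 11–29 µg/g (1 µg/g steps)
Group 2 is (10, t] — it grows with t, so early rows may be empty and are
flagged rather than dropped; the alternative reading Group 2 = [t, 29] is
available via `group2_mode="upper"`. Each comparison is a logistic
regression of the urgent label on group membership (for a 2×2 layout the
odds ratio equals the cross-product ratio, which the tests assert to six
significant figures). Rows with a zero cell are flagged unevaluable and
excluded from the sustained-run logic. "Persistently significant" means:
significant at t and at every larger evaluable t in the scan range; the
scan reports the smallest such t, or none.

## Decision-curve analysis

The risk model is the univariate logistic model of urgent conversion on the
continuous (imputed) FIT value. Over threshold probabilities p_t ∈ [0, 1] in
0.01 steps, patients with predicted probability ≥ p_t are classified
high-risk and

    NB(p_t) = TP/n − (FP/n) · p_t/(1 − p_t).

Conventions at the endpoints: p_t = 0 gives the treat-all value (the event
prevalence); p_t = 1 is the classify-none limit, NB = 0, and the treat-all
reference is undefined (NaN) there. Each interior p_t maps to a FIT
threshold through the model inverse `FIT = (logit(p_t) − β0)/β1` (requires
β1 > 0); images outside the observed FIT range are flagged extrapolated.
The *optimal band* is the maximal contiguous run of grid points where the
model's net benefit strictly exceeds both references; the reported "best"
threshold is the band's argmax (at p_t = 0 the model ties with treat-all by
construction, which is not a usable operating point).

## Monetary cost–benefit model

At FIT threshold t, a patient is predicted positive (straight to
colonoscopy) iff FIT > t; the four confusion cells against the urgent label
are priced and summed per patient:

    NB(t) = (value_tp·TP + value_tn·TN − loss_fp·FP − loss_fn·FN) / n.

The default `CostModel` is normalised to the colonoscopy cost (1.0) with the
capsule at 0.83 — a published 17% cost saving — and derives: a true positive
saves the skipped capsule (0.83), a true negative avoids a colonoscopy
(1.0), a false positive loses the price difference (0.17), and a false
negative loses the capsule that converts anyway. Two readings of the
false-negative loss exist — incremental (capsule only, the default) and
absolute (capsule + colonoscopy, `fn_absolute=True`) — and both are exposed
because the narrative supports either; absolute GBP values are user
configuration. The curve is affine in the cost vector (tested by finite
differencing) and identically zero under zero costs. `steepest_declines`
reports the k grid points with the largest one-step drop, ties broken toward
the lower threshold.

## Sample size

The study design detects an expected FIT difference of 20 µg/g against a
common SD of 117 µg/g (Cohen's d = 20/117 ≈ 0.171) with a two-sided
two-sample t-test at α = 0.05 and 90% power. The per-group n solves the
noncentral-t power equation (bracketed by doubling before Brent's method,
because the noncentral-t CDF loses accuracy at extreme df); the reported
total is the ceiling of twice the continuous per-group solution, which at
the defaults gives 1441 — note this rule can yield an odd total. The
alternative per-group-ceiling convention is exposed as
`total_per_group_rounding`, and the large-sample normal approximation is
reported for transparency. (Design-source documents sometimes quote an
"effect size of 0.8" alongside d ≈ 0.17; the two are inconsistent and only
d = delta/sd is implemented.)

## Synthetic cohort: what it emulates, and what it does not

The generator is label-first: FIT is drawn, the urgent label is drawn from
`P(urgent|FIT) = expit(β0 + β1·FIT)` on the *imputed* value, and findings
are then synthesised conditionally on the label so that re-deriving the
label from findings under the active criteria reproduces it exactly (the
generator asserts this for every record). All randomness flows from one seed
through spawned child generators.

Calibration targets and defaults:

- **FIT**: log-normal with µ = ln 16, σ = 2.4. After per-site censoring
  (lower limit 7 or 10 with equal probability, upper 400) and imputation
  this yields median ≈ 16 µg/g, mean ≈ 78, SD ≈ 122, and ~60% of values
  ≤ 30 µg/g. The median is the hard anchor; a single log-normal also hits
  the censored mean and SD, so no mixture component was needed. σ = 2.4 is
  large for a biomarker but is what the censored moments demand.
- **Conversion risk**: β0 = −2.0, β1 = 0.006 per µg/g, giving urgent
  prevalence ≈ 0.20 and FIT→urgent AUC ≈ 0.69 at large n.
- **Findings**: 33% of urgent cases carry CRC; the rest split 75/25 between
  an advanced polyp (size uniform on [10, 30) mm) and a high count of
  sub-threshold polyps. Non-urgent patients draw a Poisson(0.25) polyp
  count truncated below the count threshold, sizes below the size cut.
  At n = 20000 this gives any-polyp ≈ 35%, CRC ≈ 6.4%, advanced polyps
  ≈ 12.4%. Polyp sizes are rounded to 0.1 mm with guards so rounding never
  moves a polyp across the size cut.
- **Demographics**: age ~ Normal(65.4, 14.3) truncated at 18; 56.6% female;
  haemoglobin ~ Normal(112.2, 19.1) g/L clipped to the loader's plausible
  band; bowel-prep adequacy ~ (42% adequate, 2.6% poor, 55.5% missing).
  Demographics are independent of FIT — the joint distribution is
  unreported, so the multivariable model's covariates carry no signal in
  simulation beyond chance.

Consequently, passing tests demonstrate the *machinery* (counting, scanning,
net-benefit arithmetic, model fitting, reproducibility) under a realistic
marginal structure; they do not validate clinical effect sizes, covariate
adjustment gains, or real-world conversion rates, all of which depend on
joint structure the simulator does not claim to know.

## Problem sizes and numerical conventions

Tests run the oracle-equivalence checks on dozens of random cohorts up to
n = 1000, calibration checks at n = 20000, and parameter recovery over 200
replicates at n = 5000 (95% Wald coverage observed ≈ 92%, within the 90–98%
band expected of a correctly specified model with finitely many replicates).
The full pipeline is exercised at n ≈ 1500, the study's scale. Exact
equality is asserted for integer counts and jump sets; 1e−12 absolute
tolerance for net-benefit arithmetic; 1e−6 relative for closed-form logistic
identities; Monte-Carlo assertions use 3·SE bands.

JSON outputs are written with sorted keys and hashed (SHA-256) in the run
index; figures are excluded from hashing since image encoding is
presentation, not result. Reruns with identical config and seed produce a
byte-identical index.

## Known limitations

- No cross-validation or optimism correction anywhere; all model
  performance is apparent.
- No changepoint inference beyond the counting rule (no likelihood-based
  CUSUM control limits or segmentation methods).
- The monetary model is linear and per-patient; no QALYs, discounting, or
  waiting-list dynamics.
- Censored-FIT imputation to the limit is a convention, not an estimate;
  analyses sensitive to the shape of the censored region inherit it.
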