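# Methods

## Window classification

Participation in the last screening round is defined per programme by a
look-back window ending at the woman's reference date: 6 years for cervical,
4 for breast, 3 for bowel screening (the recommended interval plus one year
for delays).  Several conventions are deliberate choices, because "at least
one screening record during the recommended interval plus one year" leaves
them open:

- **Boundary inclusivity.** Windows are half-open `[anchor − L years,
  anchor)`: a screen exactly L years before the anchor is inside, a screen on
  the anchor day is not.  Any fixed convention would do; this one is
  deterministic and testable, and changing it moves individual women only on
  exact boundary days.
- **"Screening record" = completed screen.** Invitation events never count
  toward participation; they are used only to restrict the cohort to women
  with a sufficiently old bowel invitation (roll-out robustness analysis,
  default lag 1 year).
- **Year arithmetic** is calendar subtraction of whole years (same
  month/day), mapping Feb 29 to Feb 28 in non-leap years.  Fractional lags in
  the invited-subset filter use 365.2425-day years.
- **Hysterectomy** is carried on the roster but never used by the
  classifiers: cervical-eligibility loss is addressed by the pre-age-54
  analysis (anchor = 54th birthday, breast and cervical windows only), when
  very few women have yet had a hysterectomy.  A flag-based filter remains
  available for synthetic experiments.

The 8-pattern tabulation orders rows by number of programmes attended.
Percents are integers rounded half away from zero, so the 8 printed percents
can sum to 100 ± 4.

## Randomness null and χ² construction

The null splits the cohort into ever participants (independent participation
across programmes, at the observed marginal rates) and never participants
(structural zeros).  Expected counts for the two headline cells follow the
product formulas in the README; on the studied cohort's counts they evaluate
to 881.67 → 882 (all three) and 147.02 → 147 (none).  Expectations are kept
unrounded internally and rounded only in reports.

The source analysis does not state the test's cells.  Implemented here is a
1-df two-cell Pearson χ² per headline cell — observed vs expected on
{in cell, not in cell} — which directly matches "comparing the observed with
the expected numbers … in all three programmes, or in none" and reproduces
p < 0.001 for both cells (the statistics are ≈ 66.5 and ≈ 180.6).  An 8-cell
variant over the full pattern table is exposed as `pattern_chi_square`
(df = 7, no correction for the plug-in margins; documented approximate).

**Calibration caveat.**  The pipeline's expectation is computed from the same
cohort's margins.  That plug-in step makes the test *conservative*: in
simulations under exact independence (n = 3000, no never participants) the
all-three cell rejects far below the nominal 5% and the none cell at roughly
2%, because var(O − Ê) is much smaller than the binomial variance the χ²
reference assumes.  Fed its *true* expectation, the same statistic is the
standard one-proportion χ² test and calibrates at ≈ 5% (the none cell sits
slightly low, ≈ 4%, from binomial discreteness at its smaller expected
count ≈ 76).  The test suite checks both facts: nominal calibration with
known expectations, and conservatism of the plug-in version.  For the
studied cohort this distinction is immaterial — the departures are enormous —
but the plug-in test should not be read as an exact 5%-level test near the
null.

## Relative proportions

RP = (a/n₁)/(b/n₂) comparing participants with non-participants of an index
programme, with 95% CIs assuming ln RP is approximately normal:
var(ln RP) = 1/a − 1/n₁ + 1/b − 1/n₂ (delta method for a ratio of
independent binomial proportions; z = 1.96 fixed).  This reproduces every
published CI to two decimals, and agrees with a parametric percentile
bootstrap (2·10⁴ resamples) to within ~3% of interval width on the published
contrasts.  A zero numerator in either group is returned as a flagged
degenerate result, never a silent infinity.

## Practice ecology

- **Coverage class.**  `above` requires coverage at or above the national
  average (defaults 72.1 / 71.7 / 57.3 %, overridable) in all three
  programmes concurrently; equality resolves upward, as the class definition
  states ("same or higher").  `below` requires strictly below in all three.
- **Tertiles.**  Cutpoints are the 1/3 and 2/3 sample quantiles rounded to
  two decimals; ties at a cutpoint go to the lower tertile.  Heavy ties that
  empty a tertile raise an error listing the cutpoints.
- **Unadjusted ORs** come from the tertile × class contingency table with
  Wald CIs on the log scale (var = Σ 1/cell); for grouped binary data these
  equal the univariate-regression estimates, and they reproduce all 24
  published values and CIs to two decimals.
- **Adjusted ORs** come from one logistic fit per outcome contrast
  (mixed ∪ below; above ∪ below — two separate binary fits, not a
  multinomial model), containing all six characteristics as middle/highest
  indicator pairs with the lowest tertile as reference.  Tertiles are
  entered as indicators, not ordinal scores.  Fitting is Newton-type maximum
  likelihood (statsmodels) with a post-fit score-norm check (< 10⁻⁶);
  non-convergence raises with the iteration count and detected complete
  separation raises naming the suspect columns.  The published adjusted ORs
  cannot be reproduced without the practice microdata; the estimation code
  is instead validated by a parameter-recovery study (below) and by the
  exact single-covariate identity between regression and contingency
  estimates.
- Practices with any missing characteristic or coverage are dropped before
  analysis.  No multiple-testing adjustment is applied.  These are
  area-level correlations; no individual-level or causal reading is implied.

## Synthetic-data generators

**Women.**  Defaults are the study conditions: 3060 women aged 60–65
(reference dates uniform over 2010–2011, attained age uniform over 60–64),
never-participant probability 71/3060, ever-participant marginals
(2525, 1908, 1635)/2989 ≈ (0.845, 0.638, 0.547).  Dependence is a Gaussian
copula: latent trivariate standard normal with equicorrelation ρ (or a full
PSD matrix) thresholded at the marginal quantiles.  ρ = 0.3001 was fixed
once by bisection on the exact multivariate-normal rectangle probability so
that the all-three probability among ever participants equals the observed
1086/2989 ≈ 0.363 (`calibrate_rho` re-derives it; a test pins the
constant).  One ρ cannot match the whole 8-cell table — the simulated
"none" cell lands near 8% rather than the observed 10% — and is a modelling
device, not an estimate of the real cohort's dependence.  The pre-age-54
breast/cervical pair uses its own bivariate copula (equal marginals
0.79341, ρ = 0.17887), calibrated so the cohort reproduces 63% both / 29%
one / 8% neither.  Screens are placed uniformly inside their windows; every
ever participant receives one guaranteed cervical screen at ages 44–47
(before any window) so ever/never status is exact by construction.  Bowel
invitations honour a 78% probability of predating the one-year lag,
independent of participation; real invitation–attendance coupling and
round timing are *not* modelled, so the generator supports tests of the
classification and inference machinery, not of invitation-behaviour
questions.

**Practices.**  Six characteristics are drawn independently from clipped
normals with plausible English practice-level means and spreads (e.g. IMD
21.7 ± 12, smoking 17 ± 6.5%, satisfaction 84 ± 8%); real characteristics
are mutually correlated, so unadjusted-vs-adjusted confounding patterns in
real data are richer than in these files.  The coverage class follows a
baseline-category logit in the tertile indicators: above-vs-below log odds
are the stated effects (defaults with the sign and rough magnitude of the
nationally observed adjusted gradients), the mixed class receives half the
linear predictor (yielding the dose-response ordering), and the mixed
intercept 0.45 balances the three classes to rough thirds.  Conditional on
{below, above} this is exactly a logistic model with the stated
coefficients, which is what makes the recovery study well-posed.  The
coverage triple is then drawn consistent with the class (half-normal spread
6 percentage points around the national averages, with a guard so rounding
cannot push a below-average coverage onto the threshold), so
classification recovers the generating class exactly.

## Validation studies run by the test suite

Problem sizes were chosen so the whole suite runs in about a minute:

- **Null calibration**: 2000 cohorts of n = 3000 under ρ = 0 with known
  expectations → rejection rate within (3%, 7%) at the 5% level.
- **Power/sign**: under ρ = 0.3, the observed all-three count exceeds its
  plug-in expectation in every one of 50 replicates.
- **Copula monotonicity**: with common random numbers, the all-three count
  at n = 10⁵ strictly increases over ρ ∈ {0, 0.2, 0.4, 0.6}; marginals stay
  within 3 Monte-Carlo SEs of their targets.
- **Parameter recovery**: 200 practice files of n = 1500 → fitted
  above-vs-below coefficients within 2 SE of truth for ≥ 93% of
  (replicate, coefficient) pairs.
- **Oracle checks**: the logistic fit matches a Nelder–Mead maximization of
  the binomial log-likelihood to 4 decimals and the contingency OR exactly
  in the saturated case; the delta-method CI matches the bootstrap as above.

## Known limitations

- Event histories are minimal (no repeat screens within windows, no
  inadequate-test events, no cervical-interval age dependence).
- The copula is exchangeable by default; programme-pair-specific dependence
  requires passing a full correlation matrix.
- The plug-in χ² test is conservative near the null (see above).
- Practice characteristics are simulated independently; ecological
  confounding structure is therefore simpler than in the real national data.
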