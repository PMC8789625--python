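# Methods

This note documents the statistical machinery implemented in `womab`, the
choices made where the procedure admits variants, and what the synthetic
cohorts can and cannot show.

## Battery scoring

Each span task administers two lists per sequence length, lengths
increasing by one, and stops after a *double fail*: both lists of the same
length failed.  A fail on the second list of one length followed by a fail
on the first list of the next length does **not** stop the task — the rule
is read per length, consistent with the two-lists administration.  Trials
recorded after the stop point are ignored rather than rejected, since
paper forms occasionally contain them.  Sequences containing intrusions
score 0; self-corrections count as success (the trial record stores the
final response only).

Start lengths are not part of the published outcome definitions and were
back-derived from the outcome ranges so that T-max = 2 × (number of
lengths): DOT 3–8, ICT 3–10, FDS 2–9, BDS 2–8.  They live in `TestSpec`
and can be overridden.

Digit-span ratios are computed on **raw** scores (never adjusted ones),
are undefined (missing, flagged, never an exception) when the forward
denominator is 0, and are never clamped: values above 1 occur empirically.

## Demographic adjustment and model selection

The published instrument fixes, per outcome, an adjustment equation
`AS = RS + Σ coefₖ·(tₖ(x) − cₖ) ± sex offset` with printed coefficients and
centering constants; `womab.published` applies these verbatim.  The two
cubic-age coefficients are printed rounded (2·10⁻⁶, 3·10⁻⁶), so regenerated
grids are guaranteed to agree with the printed ones only to ±0.01; the
package deliberately stores the printed values and does not "improve" them.

For re-derivation on a new cohort the selection procedure is not uniquely
determined by the instrument, so the package adopts a documented one:
every pair of one age form ({age, ln(100 − age), age³, 1/age, ln(age)})
and one education form ({education, 1/education}) is fitted jointly with a
±1 sex contrast by OLS; the pair with the highest log-likelihood wins;
terms are then removed by backward elimination at α = .05 and the model is
refitted with the retained terms only.  This reproduces the per-outcome
heterogeneity of transforms seen in published norm tables without claiming
to replicate the original authors' exact search.  Two consequences are
worth knowing:

* the transform search inflates the familywise type-I rate above the
  nominal ≈14% of three independent α = .05 screens — on pure-noise
  cohorts about one in five ends with a spuriously retained term
  (measured ≈0.80 empty-model rate over 300 null cohorts of n = 168);
* on cohorts simulated from a known equation the generating age form is
  reliably recovered when its effect is real (see the parameter-recovery
  test: CI coverage of the generating coefficients is close to nominal).

Adjustment subtracts the fitted, *mean-centered* effects, so the cohort
mean of the adjustments is zero by construction.  Sex is coded +1 female /
−1 male, matching the "+offset if female, −offset if male" convention of
the printed equations.  Education 0 is rejected at ingest (the transform
family uses 1/education); ages outside the stated inclusion range 20–90
draw a warning but are retained, since the observed normative sample spans
18–86.

## Tolerance limits

With p = .05 and confidence .95, the outer tolerance limit is the largest
order statistic a (1-based, ascending) with P[Bin(n, p) ≤ a − 1] ≤ .05 and
the inner limit the smallest b with P[Bin(n, p) ≤ b − 1] ≥ .95.  At
n = 168 this gives ranks (4, 14).  For n < 59 no valid outer rank exists
at these settings and the package raises an explicit error rather than
degrading the guarantee.  Ties at the limiting rank share the limit's
value.

## Equivalent-Score partition

ES 0 ends at the oTL; following the norm table's printed convention a
value *equal* to the oTL is ES 0 (the literature also contains the strict
"< oTL" reading; both are implemented, `es_zero_inclusive` selects).  ES 4
starts above the sample median.  The ES1/ES2 and ES2/ES3 thresholds sit at
the cumulative normal areas Φ(−1.0966) ≈ .1364 and Φ(−0.5483) ≈ .2918 —
the points splitting the z-interval [z(.05), 0] into three equal widths —
so the five classes carry ≈5%, 8.6%, 15.6%, 20.8% and 50% of a normal
population.  By default those areas are read off the *sample* quantiles
("rank" strategy); a fitted-normal variant ("normal" strategy) is provided
because published ES derivations differ on this point and the original
choice is not recoverable.  On a standard-normal sample the rank bounds
converge to (−1.645, −1.097, −0.548, 0).

Degenerate samples (fewer distinct adjusted values than bins) collapse
with a warning instead of failing.

One norm-table reconstruction detail: the DOT-WM row of the printed table
runs its ES 1 bounds together; the reading ES 1 = 4.06–4.57 is shipped
(its lower bound continues ES 0's "≤ 4.05" and its upper bound precedes
ES 2's "4.58"), flagged here because the printed iTL (4.5) does not —
and need not — coincide with the ES 1 upper bound.

## AES composites

AES-T averages the ES levels of {DOT-T, ICT-T, FDS-T, BDS-T, DSR-T};
AES-WM/S the five WM/S analogues.  Five constituents (four tests + ratio)
are used because the observed composite minimum of 0.6 is a multiple of
1/5 but not of 1/4; the constituent lists are configurable.  A composite
is computed only when all five constituents are present; partial profiles
still return their per-test results.  AES values are compared to their
tolerance limits unrounded.  For AES rows only tolerance limits are
published — requesting an ES level for a composite is an explicit error.

## Power analysis

`min_sample_size` searches the smallest denominator df v at which the
noncentral-F power of the overall regression test — numerator df u,
noncentrality λ = f²·(u + v + 1), level α — reaches the target, and
returns N = u + v + 1.  With f² = 0.10, u = 3, α = .05 and power .90 this
yields N = 146 (v = 142, power .9007).

## Validation screens

Normality is screened with |skewness| > 1 or |kurtosis| > 3.  Kurtosis is
*excess* kurtosis by default: applying the |3| threshold to raw kurtosis
would flag roughly half of all genuinely normal samples (raw kurtosis of a
normal is 3), which cannot be the screen's intent; a raw-kurtosis flag is
available.  Flagged outcomes switch the correlation method to Spearman.
The eight base outcomes form C(8,2) = 28 pairs and the Bonferroni
threshold .05/28 ≈ .002; the ratios are correlated in their own pass.
Sex contrasts use the pooled-variance t-test (df = n − 2; 166 at n = 168),
with Welch available by flag.

## Synthetic cohorts

`womab.simulate` emulates a stratified normative sample: the default
sampling frame reproduces the published age-band × education-band × sex
cell counts exactly (n = 168, 73 M / 95 F), with ages and educations
uniform inside their band — a stated simplification, as the real
within-cell joint distribution is unknown.  Per outcome the generator
draws

`RS = round(clip(intercept + demographic effect + λ·g + ε))`

where the demographic effect *inverts the published adjustment equation*
(so refitting on synthetic data is a genuine recovery exercise), g ~ N(0,1)
is a shared ability factor and ε is outcome-specific noise.  Intercepts
and target dispersions come from the published sample descriptives; the
shared factor carries 75% of the non-demographic standard deviation, a
one-time calibration chosen so the realized inter-test correlations land
in the reported .39–.96 band (measured ≈.60–.86 on the default seed) with
age correlations negative around −.5 and a male backward-span advantage.
Integer scores are rounded then clipped to their theoretical ranges (a
warning fires if clipping touches >10% of an outcome), and each (T, WM)
pair is projected onto the pairs reachable under the stop rule
(k ≤ T ≤ 2k with k = WM − start + 1), so trial-level records can always be
reconstructed; ratios are recomputed by division, never sampled.

What passing tests on these cohorts show: the pipeline's estimators
recover known generating structure, directions of all reported
associations emerge, and every interface handles realistic data shapes.
What they do not show: agreement with the real normative sample's exact
means, SDs or cutoffs (sample realizations, not model truths — the
published constants are shipped, not re-estimated), floor/ceiling
behaviour of real patients, or item-level response processes.

## Problem sizes and numerics

Default problem sizes used by the test suite: 200 replicates of n = 168
for parameter recovery; 10⁵ draws for the ES-partition limit; 1000 random
pairs per test for the scoring round trip; exhaustive n ∈ [20, 500] for
the tolerance-rank oracle — sizes at which the Monte-Carlo error is well
inside the asserted tolerances.  All internal arithmetic is double
precision and unrounded; rounding (half away from zero, 2 decimals, 3 for
ratio outcomes) happens only when rendering grids and tables.  Every
random routine takes an explicit seed; identical (spec, seed) pairs yield
byte-identical cohort CSVs.

## Known limitations

* The printed instrument's coefficients are reproduced at print precision;
  ±0.01 grid agreement is the attainable fidelity.
* The transform-selection procedure is a documented reconstruction, not
  the original authors' code; alternative selections (e.g. AIC, forward
  search) may retain different forms on borderline cohorts.
* The discontinuation rule's edge case — a lone fail at the end of one
  length followed by a fail opening the next — is interpreted as
  *continue*; recorded administrations that used a stricter reading would
  score at most one sequence differently.
* No MMSE adjustment, no test–retest reliability, factor analysis or IRT;
  none are part of the instrument's normative apparatus.
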