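# Methods

This note documents the model, its assumptions, the defaults, and the
numerical choices, in the order the pipeline runs them.

## Study structure

Adults aged 25+ are partitioned into 24 age–sex strata: both sexes in
five-year bands 25–29 … 75–79 and an open 80+ band. Band edges are
configuration (`SynthConfig.age_band_edges`), not code: survey programs
differ in how they cut bands, and only the 70-year boundary matters
structurally (it is where the young/old reporting split sits, so it must
be an edge). Ten causes are modelled: eight CVD subtypes (ischemic heart
disease, ischemic and hemorrhagic stroke, aortic aneurysm, endocarditis,
hypertensive heart disease, rheumatic heart disease, pooled other CVD),
CKD, and stomach cancer. Endocarditis and rheumatic heart disease are
inflammatory: their onset is independent of blood pressure, so they are
excluded from averted incidence and DALYs, but lower blood pressure still
reduces their case fatality, so they count toward averted deaths.

## Stage 1 — intake estimation

Per-category sodium intake per stratum is a survey-weighted mean over
persons, with persons who did not consume a category contributing zero.
Standard errors use the ratio-estimator form
SE² = Σ wᵢ²(yᵢ − ŷ)² / (Σw)². The source-data convention for intake SEs is
not standardized across surveys; any consistent estimator is acceptable
here because the SE only parameterizes Monte Carlo draw (a).

A single 24-hour recall underestimates sodium, so all category means are
rescaled by a sex-specific factor f_s = share × urinary_s / recall_total_s,
where `share` = 0.85 is the nondiscretionary fraction of
urinary-excretion-based intake (the remaining 15% being salt added in
cooking or at the table) and urinary_s is the sex's 24-hour urinary
excretion estimate. The factor is deliberately uniform across categories —
each category keeps its share of the sex's total — and sex-specific only,
not age-specific, because urinary calibration data are published by sex.
Foods outside any program's scope (scratch cooking, restaurant and
takeaway food, uncovered categories) form an explicit `remainder`
category: it is carried through all totals but never reformulated.

Stratum totals combine category SEs assuming independence (root sum of
squares). This understates the variance slightly, since category intakes
within a person share one recall; the simplification is acceptable because
the intake SE is a minor contributor to output uncertainty.

## Stage 2 — reformulation effects

A target set maps food categories to maximum sodium densities (mg/100 g).
Full compliance clamps each covered product to its target; products at or
below the target are unchanged. The category effect is the proportional
reduction of the sales-weighted mean density, r_c = 1 − post/pre, with
annual kilograms sold as weights, held fixed pre/post (no consumer
substitution is modelled). Only maximum targets are supported; average
targets are out of scope.

The "optimistic" scenario sets each category's target at the
sales-weighted 25th percentile of current densities. The weighted
quantile rule is left-continuous with no interpolation: the smallest
density whose cumulative sales share reaches q. This guarantees the
defining property that at least a fraction q of the sales volume already
complies with the derived target.

Company attribution uses independent single-company counterfactuals (only
that company's products clamped, all sales weights unchanged), expressed
as a share of the all-company total. Because clamping acts per product and
the sales-weighted mean is linear in densities, single-company effects add
exactly to the all-company effect; ranking is by central averted deaths
with deterministic company-id tie-breaks.

## Stage 3 — exposure shift

Per stratum, Δ = Σ_c intake_c × r_c and the post-intervention mean is
x′ = max(x − Δ, 0). The pre-intervention mean x is the full
nondiscretionary total (targeted categories plus remainder).

## Stage 4 — comparative risk assessment

Relative-risk forms are given in the README. Parameter defaults:

| parameter | default | units | notes |
|---|---|---|---|
| TMREL | 2.0 ± 0.2 | g/d sodium | zero-truncated normal in draws; sensitivity 1.0 ± 0.2 and 3.0 ± 0.6 |
| M_Na | 22.99 | g/mol | fixed constant |
| SBP main effect | 3.74 ± 0.35 | mm Hg per 100 mmol/d | at reference age 50, normotensive |
| SBP age interaction | 0.105 ± 0.03 | mm Hg per year | larger response at older ages |
| SBP hypertension interaction | 1.87 ± 0.55 | mm Hg | per unit prevalence |
| nondiscretionary share | 0.85 | — | sensitivity 0.75 |
| exposure CV (lognormal mode) | 0.25 | — | delta mode is the default |

The SBP coefficients and the cause- and age-specific relative risks ship
as data files (`sodium_cra/data/`), not code, with values in the range of
the published meta-analytic literature (sodium→SBP meta-regression across
~100 trials; SBP→CVD/CKD pooled cohorts; sodium→stomach-cancer
meta-analyses); users with access to a specific risk table substitute
their own file. The hypertension adjustment applies prevalence-weighted
k_as per stratum rather than splitting strata into hypertensive and
normotensive sub-populations — simpler, and equivalent to first order.

Whether to integrate the PIF over a continuous exposure distribution or
use the shift-in-mean (delta) closed form is genuinely open; both are
first-class. Delta is the default (reproducible, exact, fast); the
lognormal mode integrates RR·pdf on a fixed grid of 2,001 points over
[0, mean + 10 SD] by the trapezoid rule, erroring if that bound leaves
more than 1e-6 of probability mass uncovered. (Ten SDs, not the Gaussian
eight: a lognormal right tail at CV 0.25 needs the extra width to meet
the mass rule.) The grid is fixed rather than adaptive to keep runs
bit-reproducible. Every run logs its distribution mode, TMREL, and share
in the report header.

## Uncertainty propagation

Monte Carlo, default n = 1,000. Draw families — normal for intake means,
reformulation effects (relative SD 0.2, clipped to [0, 1]) and SBP
coefficients; moment-matched beta for prevalences; normal on the log
scale for relative risks and baseline event counts (sigma from 95%
interval widths); zero-truncated normal for the TMREL — follow common CRA
practice; the source conventions name no families, so each is an
implementation choice and each is overridable through `DrawSpec`. Draws
are independent across parameter blocks even where real inputs may be
correlated; this is a known simplification.

Substreams are keyed by (seed, draw index, block) via numpy
`SeedSequence` spawning, so draws are order-invariant, the first n draws
of a longer run reproduce a shorter run, and parallel execution would not
change results. Percentiles (50th central, 2.5th/97.5th UI) use linear
interpolation between order statistics. Aggregates are summarized from
per-draw sums, so the median of a total need not equal the sum of
component medians — both are reported from the same draws.

Sensitivity runs (TMREL 1.0 ± 0.2, TMREL 3.0 ± 0.6, baseline intake
× 0.9, share 0.75) reuse the base seed so their deltas reflect the
changed assumption, not simulation noise.

## What the synthetic data does and does not emulate

The generators reproduce the *structural* features the pipeline is
sensitive to: right-skewed (lognormal) intakes and sodium densities with
wide within-category spreads, so every target set has compliant and
non-compliant products; a Zipf-like concentration of products across
companies (exponent 1.0 over 25 companies by default, putting roughly
60% of sales with the top five, the first three of which are retailers);
burden rising exponentially with age and higher in men; urinary-based
intakes near 4,000 (men) / 2,900 (women) mg/d; and multiplicative burden
uncertainty. Target sets are nested by construction (narrow/lenient ⊂
broad/stricter ⊂ optimistic-25th-percentile), which is what makes the
scenario ordering provable on any generated supply.

They do **not** emulate: real food taxonomies or category mappings,
nutrient fields other than sodium, household- vs person-level purchasing,
differential underreporting by food group, brand market shares differing
by age or sex, or correlations between input uncertainties. Passing tests
therefore demonstrate correctness of the estimator machinery under known
ground truth — not the realism of any particular national estimate.

Problem sizes used by the shipped runs (600 survey persons, 30 products
per category, 25 companies, 1,000 draws) were chosen as the smallest
sizes at which every stratum is well populated and Monte Carlo summaries
are stable to ~1%.

## Numerical and degenerate-input choices

* Persons are apportioned to strata deterministically (largest remainder,
  floor of 3 per stratum) so no seed can leave a stratum empty.
* A person recalled with zero foods is retained via a single zero-gram
  row and contributes zero intake with full weight.
* Zero total sales in a category, unmapped recall foods, missing burden
  cells, inverted uncertainty intervals, and zero survey weight in a
  stratum are hard errors, never silently repaired.
* A failing Monte Carlo draw aborts the run with its draw index; draws
  are never skipped.
* Negative draws are truncated at natural bounds (intakes and Δ at 0,
  reductions to [0, 1], TMREL > 0, prevalence in [0, 1]).
* `%` columns in reports use central baseline burden totals as
  denominators, so they are linear transforms of the averted-count
  summaries and remain recomputable from the report's absolute columns.

## Known limitations

No time dimension (no lag between exposure change and disease), no
recurrent events, no behavioral response to reformulation, no direct
(non-BP-mediated) sodium effects on CVD/CKD, no health-equity
stratification, and independence of all Monte Carlo draws. These mirror
the standard limitations of comparative risk assessment; the package is a
scenario-comparison tool, not a forecast.
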