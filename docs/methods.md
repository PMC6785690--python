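# Methods

## Scope and model

`actimpact` implements a categorical comparative risk assessment for total
physical activity.  The exposure is weekly energy expenditure in
MET-min/week, summed over four self-report domains (recreation,
occupation, commuting, household) and grouped into four bands:
`[0,600)`, `[600,4000)`, `[4000,8000)` and `[8000,∞)`.  The bands carry the
conventional integer-style labels `<600`, `600–3999`, `4000–7999`, `≥8000`,
but classification uses real half-open intervals because MET products are
real-valued; every non-negative total maps to exactly one band, lower
bounds inclusive.

For band prevalences *Pᵢ* (current), *P′ᵢ* (counterfactual) and relative
risks *RRᵢ*, the potential impact fraction is
`PIF = (Σ Pᵢ RRᵢ − Σ P′ᵢ RRᵢ) / Σ Pᵢ RRᵢ`.  The population attributable
fraction is the special case with *P′* degenerate at the reference band,
and is computed by that exact code path (no separate closed form), so
`PAF ≡ PIF(tmrel)` holds bit-for-bit.  With monotone non-increasing RRs,
any scenario that moves mass only upward yields a non-negative PIF, and the
exposure-elimination scenario dominates all others; both facts are asserted
as property tests.

Assumptions inherited from this class of model: risks act
multiplicatively and independently across individuals, the counterfactual
changes the exposure distribution with all else held constant, and one RR
vector per outcome applies to all strata and ages (breast cancer is
women-only; the men's cell is structurally not applicable, reported as NA
and never as zero).

## Inputs and their units

* **Survey microdata** — one row per respondent: sex, age, survey weight,
  and per domain the weekly frequency (0–7 days), session duration
  (minutes; "hours and minutes" responses must be normalised to minutes at
  ingest) and, for recreation, an activity code.
* **Compendium** — MET values (dimensionless multiples of resting
  metabolic rate) per recreational activity code plus one average MET per
  non-recreation domain.  The shipped table is an illustrative placeholder:
  the average-MET-per-domain convention is implemented, but the specific
  values should be replaced by the study's own assignments.
* **Relative risks** — per outcome × band, reference band fixed at exactly
  1.  An RR vector whose reference entry differs from 1 is rejected rather
  than renormalised, because a silent rescale would change every PIF.
  Confidence limits are carried through I/O but not propagated; interval
  propagation is an extension point, not a feature.
* **Deaths** — premature deaths (ages 30–69) per outcome × stratum plus
  major-NCD and all-cause denominators.  Denominators are consumed as
  data, never derived from the five outcomes, because they cover a wider
  ICD range.  Both-sex counts may exceed men + women: deaths with missing
  sex information enter only the both-sex row.  The shipped table holds
  the Brazil 2015 register counts.

## Prevalence estimation

Band prevalence is a Horvitz–Thompson style point estimate: the share of
band *i* is the summed expansion weight of records in *i* over the total
summed weight of the stratum.  With all weights equal this reduces to
simple proportions.  No design-based variance is computed — the pipeline
reports point estimates only, so the complex-survey design enters only
through the weights.  Strata are combined by population-weight-weighted
averaging of shares, which conserves mass.

Percentages are rounded (one decimal for prevalence, two for PIF) only in
the report writers; all computation keeps full precision.

## Scenario engine

Scenarios act on distributions, never on microdata.  Freed mass under the
recommendation and relative-reduction scenarios goes entirely to the
`600–3999` band — the minimal-shift reading of "reaches at least 600",
under which the published counterfactual rows are reproduced exactly
(e.g. 44.6 + 41.3 = 85.9).  `relative_reduction` with fraction 0 is the
identity and with fraction 1 coincides with `recommendation`; every
scenario conserves mass to 1e-9 and never increases the cumulative share
below any band boundary.  The gender-equality both-sex row is recombined
from the per-sex counterfactuals with the observed sex weights; because
the two sexes then share one distribution, the combined row equals the
reference row regardless of those weights.

## Attribution arithmetic

Preventable deaths per cell are `round(PIF × deaths)` with ties away from
zero; stratum totals sum the *rounded* cells.  This is deliberate: it is
the arithmetic under which a published table of integer cells is
internally consistent (cells summing exactly to their printed total),
whereas summing unrounded products generally is not.  For a women-only
outcome the women's count enters the both-sex total while the both-sex
cell itself stays NA.

## Synthetic survey generator

The generator emulates the 2013 Brazilian adult survey's *category
structure*, not its diaries.  Defaults are the study conditions: a
47/53 men/women split; per-sex band targets equal to the published
one-decimal rows (normalised to sum to 1); and per-band domain mixes taken
from the published per-band domain means, so occupational activity
dominates the top band.  Generation samples a band per the per-sex
targets, draws the total uniformly within the band (open top band capped
at 16 000 MET-min/week for sampling — downstream computation uses bands
only, so any finite cap is equivalent), splits it across domains by the
band's mix, and back-solves integer frequency (1–7 days) and real duration
from the domain MET value.  Scoring a generated diary therefore lands it
exactly in its sampled band, which makes parameter recovery (tabulated
shares vs. targets within binomial sampling error) a sharp test.

Uniform-within-band totals are a declared modelling choice, not an
inference about any real survey.  What the generator does *not* emulate:
the three-stage cluster sampling design (weights are 1.0 by default, with
a unit-mean gamma option purely to exercise the weighted-estimation path),
realistic joint demographics, correlated domain behaviour, or reporting
error.  Passing tests on synthetic data therefore validate the pipeline's
arithmetic and contracts, not questionnaire measurement properties.

Determinism is a contract: the seed is mandatory, and a fixed seed fixes
every generated byte.

## Numerical choices

* Band edges are lower-bound inclusive; generated totals keep a 1e-3
  MET-min/week margin from the edges so float round-tripping through CSV
  cannot flip a band.
* Distribution shares must sum to 1 within 1e-9; published one-decimal
  rows (which can sum to 99.9) are normalised on ingest, keeping each
  share within rounding distance of its printed value.
* Rounding of counts is half-away-from-zero, not banker's rounding.
* The PIF denominator `Σ Pᵢ RRᵢ` is always positive (RR > 0, ΣP = 1), so
  no guard is needed.

## Problem sizes

The default synthetic run uses 50 000 respondents — comparable to the
survey being emulated and large enough that band shares recover their
targets within three binomial standard errors.  Unit tests use 2 000 to
20 000 respondents; the enumeration oracle for the PIF formula uses 10⁵
pseudo-individuals per distribution in routine tests and 10⁶ in the
headline check (agreement to 1e-3).

## Known limitations

* No uncertainty: neither sampling variance of prevalence nor RR
  confidence intervals propagate to PIFs or death counts.
* One RR vector per outcome for all strata; no age-specific risks, no
  dose–response (continuous-exposure) PIF, no multi-exposure joint PAF.
* Activity intensity is not modelled (the source questionnaires do not
  collect it); the compendium's per-domain average MET is a coarse
  instrument.
* Scenario rows computed from *printed, rounded* prevalence inputs can
  differ in the last decimal from rows computed on unrounded internals
  (e.g. a 10% reduction of a both-sex `<600` share of 44.6 prints 40.1,
  while unrounded survey internals can print 40.2); the package always
  keeps full precision internally and rounds only at the edge.
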