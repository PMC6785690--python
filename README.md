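# actimpact

Comparative risk assessment of physical activity for premature mortality
from non-communicable diseases (NCDs): score activity diaries to
MET-min/week, estimate the population distribution over four activity
bands, apply counterfactual scenarios, and translate the resulting
potential impact fractions into preventable premature deaths.

The package is aimed at epidemiologists and burden-of-disease analysts who
want a tested, reproducible implementation of this pipeline — for example
to quantify what reaching the physical-activity recommendation, or closing
the gender gap in activity, would mean for deaths between ages 30 and 69.

## The model

Total physical activity is the sum over four domains (recreation,
occupation, commuting, household) of

```
MET-min/week = frequency (days/week) × duration (min/session) × MET
```

where MET is the compendium energy cost of the activity.  Totals are
grouped into four exposure bands: `<600`, `600–3999`, `4000–7999` and
`≥8000` MET-min/week; `<600` is insufficient activity and `≥8000` is the
theoretical minimum risk exposure level (TMREL), the reference with
relative risk 1.

For a current band distribution *Pᵢ*, a counterfactual *P′ᵢ*, and band
relative risks *RRᵢ*, the potential impact fraction is

```
PIF = ( Σᵢ Pᵢ·RRᵢ − Σᵢ P′ᵢ·RRᵢ ) / Σᵢ Pᵢ·RRᵢ
```

When the counterfactual puts everyone at the TMREL, the PIF is the
population attributable fraction (PAF), the Levin-type multi-category
form `(Σ Pᵢ RRᵢ − 1) / Σ Pᵢ RRᵢ`.

Four counterfactual scenarios are built in:

1. **tmrel** — everyone reaches ≥8000 MET-min/week (yields the PAF);
2. **recommendation** — everyone reaches ≥600 MET-min/week (the `<600`
   mass moves to `600–3999`);
3. **reduction** — the `<600` prevalence shrinks by a relative fraction
   (default 10%, the WHO 25×25 target);
4. **gender-equality** — women adopt the men's distribution; men are
   unchanged.

Preventable premature deaths per outcome are `round(PIF × deaths)` (ties
away from zero), summed over outcomes and expressed as shares of premature
deaths from major NCDs and from all causes.  Relative risks are an
*external input* — the shipped `rr_example.csv` is illustrative only.  The
shipped deaths table carries premature deaths (ages 30–69) in Brazil in
2015 by outcome and sex.

## Worked example

Applying the scenario engine to the published current band distributions
for Brazilian adults (2013), `examples/02_counterfactual_scenarios.py`
prints:

```
Both sexes
  current                                 44.6 /  41.3 /   7.6 /   6.5
  everyone to >=8000 (TMREL)               0.0 /   0.0 /   0.0 / 100.0
  everyone to >=600 (recommendation)       0.0 /  85.9 /   7.6 /   6.5
  10% cut in insufficient activity        40.1 /  45.8 /   7.6 /   6.5
  gender equality (recombined)            40.9 /  38.7 /   9.7 /  10.6
Women
  current                                 47.9 /  43.6 /   5.7 /   2.7
  gender equality (adopt men's row)       40.9 /  38.7 /   9.7 /  10.6
```

Each row is the population share (%) over the four bands after the
scenario: the recommendation empties `<600` into `600–3999` (44.6 + 41.3 =
85.9), the 10% reduction moves a tenth of the inactive share up one band,
and gender equality replaces the women's row by the men's, which also
becomes the combined row.

The other examples score a single diary (`01`), compute impact fractions
for the five outcomes under the illustrative RR table (`03`), and run the
full synthetic pipeline end to end (`04`).  The same stages are available
from the shell:

```
actimpact simulate --n 50000 --seed 2013 --out survey.csv
actimpact run --survey survey.csv --out-dir results/
actimpact run --seed 2013 --sensitivity recreation-commuting --out-dir results_rc/
```

`run` writes a prevalence table (stratum × scenario × four bands), the
per-cell attribution table (PIF %, preventable deaths, with NA for
structurally undefined cells such as breast cancer in men) and per-stratum
aggregates; `--sensitivity recreation-commuting` reruns everything on
totals restricted to those two domains.

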