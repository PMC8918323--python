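# assistqc

Real-time consistency screening for repeated administrations of the WHO
ASSIST cannabis subscale.

## The problem

Online surveys in addictions research attract invalid responding — careless
or random answering, straightlining, bots, and eligibility-seeking
misreporting — at rates high enough to bias group differences, effect sizes
and reliability estimates. One direct, automatable defence in a two-stage
recruitment design is to administer the same instrument twice (once at the
eligibility screener, again at the start of the baseline interview) and
screen out anyone whose two sets of answers are inconsistent, *before*
randomisation, instead of deleting cases post hoc.

`assistqc` implements that screen for the ASSIST cannabis subscale, for
methodologists who want to study the screen's behaviour and trial teams who
want to run it:

- **instrument** — the ASSIST cannabis subscale with the WHO V3.0 weight
  table. The total is S = Σᵢ wᵢ(xᵢ) over items i = 2…7, S ∈ [0, 39], banded
  lower (0–3), moderate (4–26), high (27–39); brief intervention is
  indicated for moderate risk, so eligibility requires S ≥ 4.
- **consistency** — an 11-check rule engine over a screener/baseline pair in
  three families: total-score checks (baseline S < 4; |ΔS| > 10),
  item-regression checks (any of items 3–7 endorsed at screening but
  "never" at baseline), and usage-report checks (four baseline probes all of
  which can independently deny cannabis use). Any fired check screens the
  participant out (threshold configurable).
- **pipeline** — the two-stage recruitment flow (eligibility → consent →
  duplicate exclusion → withdrawal → baseline completion → consistency
  assessment) with conserving consort accounting, including an
  aggregate-replay mode for published consort charts.
- **simulator** — synthetic cohorts mixing faithful respondents (test–retest
  noise calibrated to the subscale's published per-item kappa range
  0.43–0.72), uniform-random responders and bots, straightliners, and
  eligibility-seeking inflators, with demographics matching the recruited
  cohort's marginals.
- **analysis** — screened-in vs screened-out comparisons (Welch t,
  2×2 chi-square), per-check frequency tables with union-based family rows,
  per-family descriptives with overlapping membership, detector
  sensitivity/specificity against simulator ground truth, and an exhaustive
  enumeration oracle for the random-responder flag probability.

## Worked example

Score and compare one pair in Python:

```python
from assistqc import (
    AssistResponse, UsageAnswers, default_instrument, evaluate_pair, total_score,
)

inst = default_instrument()
scr = AssistResponse({2: "Weekly", 3: "Monthly", 4: "Monthly", 5: "Never",
                      6: "Yes, in the past 3 months", 7: "No, never"}, "screener")
base = AssistResponse({2: "Weekly", 3: "Monthly", 4: "Never", 5: "Never",
                       6: "Yes, in the past 3 months", 7: "No, never"}, "baseline")
print("screener total:", total_score(scr, inst))
print("baseline total:", total_score(base, inst))
ua = UsageAnswers(pattern="Spread evenly through the week",
                  times_weekday=2, times_weekend=3,
                  hours="1 to 3 hours after waking")
rep = evaluate_pair(scr, base, ua, inst, participant_id="P00042")
print("fired:", [c.value for c in rep.fired_checks])
print("decision:", rep.decision, "| checks fired:", rep.n_fired, "of", len(rep.results))
```

prints

```
screener total: 19
baseline total: 14
fired: ['ITEM4_TO_NEVER']
decision: screened_out | checks fired: 1 of 11
```

The participant's totals are both eligible and the 5-point drop is within
the ±10 tolerance, but item 4 ("use led to health, social, legal, or
financial problems") was endorsed at screening and reverted to "Never" at
baseline, so the single item-regression check screens them out.

The same flow from the shell:

```sh
assistqc simulate --n 500 --seed 7 --out records.csv --truth-out truth.csv
assistqc screen --records records.csv --out checks.csv --consort consort.yaml
```

```
consort flow
  screener_completed: 500
  ineligible_age: 2
  ineligible_never_used: 11
  ineligible_low_score: 4
  no_consent: 250
  duplicate_excluded: 20
  baseline_incomplete: 44
  consistency_assessed: 169
  screened_out: 83
  screened_in: 86
  screened_out_pct: 49.1
```

Every record ends in exactly one terminal stage and the counts conserve
(500 = 2 + 11 + 4 + 250 + 20 + 44 + 169; 83 + 86 = 169). `assistqc report`
then writes the group-comparison, inconsistency-frequency and
per-family-descriptive tables, plus sensitivity/specificity when truth
labels are supplied.

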