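# Methods

## The screening procedure

A participant answers the ASSIST cannabis subscale twice: at the eligibility
screener and again at the start of the baseline interview (in the motivating
design, a median of a few days later). The subscale total is the sum of the
item weights over items 2–7 and ranges 0–39; eligibility requires the
moderate-risk floor of 4. After the baseline re-administration the pair is
compared by eleven atomic checks in three families:

| family | checks | predicate |
|---|---|---|
| total score | 2 | baseline total < 4; \|baseline − screener\| > 10 |
| item regression | 5 | item *i* ∈ {3…7} endorsed (ordinal > 0) at screener and "never" at baseline |
| usage report | 4 | baseline item 2 = "Never"; weekly-pattern probe non-use; 0 times/day on weekday **and** weekend; hours-after-waking probe non-use |

Any fired check screens the participant out (the threshold is configurable;
the default of 1 matches the motivating design). The engine always evaluates
all checks — no first-failure short-circuit — because the downstream
frequency tables need complete per-check accounting, and family "any" rows
are unions over members, never sums, since one participant can fire several
checks of one family.

Interpretation choices the published design leaves implicit, fixed here:

- "changed by more than 10 points" is strict: |Δ| = 10 passes, |Δ| = 11
  fires, symmetrically in both directions.
- "endorsed" means any option above the ordinal-0 "never" option; a
  reduction that stops short of "never" (Weekly → Monthly) does not fire.
- item 2 reverting to "Never" belongs to the usage-report family (it denies
  use outright), not the item-regression family, which covers items 3–7.
- each participant's fired-check count is tallied at the 11-check
  granularity: a baseline that denies use entirely can legitimately fire
  most of the catalogue at once.

## The instrument

The subscale ships with the WHO ASSIST V3.0 cannabis weights
(Q2 0/2/3/4/6, Q3 0/3/4/5/6, Q4 0/4/5/6/7, Q5 0/5/6/7/8, Q6 = Q7
0/6/3 over "No, never" / "Yes, in the past 3 months" / "Yes, but not in the
past 3 months"). This table is externally sourced from the published
instrument rather than re-derived; it is the unique published table
consistent with the hallmark cells (Q2 "Weekly" = 4, Q5 "Weekly" = 7) and
the 39-point maximum, and `default_instrument()` asserts those anchors at
load time. Note the recency items' weights are deliberately **not**
monotone in display order (recent use scores above older use), so weights
are attached by label and monotonicity properties are stated on weights.
Items 1 and 8 are carried unscored for forward compatibility. Alternative
substances or weight tables can be declared in a YAML instrument config;
category bounds must tile [0, max] exactly or the definition is rejected.

The three usage-probe questions print no canonical option lists in the
source design, so their option sets and single non-use labels are
configuration (shipped defaults in `DEFAULT_USAGE_PROBES`), not instrument
fact.

## The recruitment pipeline

Eligibility sub-criteria are evaluated in the fixed order age → recent use →
score, attributing a multiply-ineligible record to its first failure —
the convention that makes published single-count-per-person consort
arithmetic (e.g. 19 + 60 + 220 = 299 ineligible) reproducible. Partial
baselines (missing item answers or usage probes) route to the
baseline-incomplete exit rather than being scored as partial sums. Link
expiry and contact verification are represented only as boolean fates
(baseline absent, duplicate), since the motivating flow publishes counts,
not mechanisms. `replay_flow` accepts pre-aggregated exits so a published
consort chart can be checked without reconstructing records. Percentages
are rounded half-up to one decimal, the usual reporting style.

## The simulator

The generator's defaults describe the study conditions of the motivating
recruitment:

- **Demographics.** Age is a truncated normal on [18, 95] whose *observed*
  mean/SD hit 37.5/13.5 — the latent location and scale (≈ 27.3/19.6) are
  solved numerically, because truncating at 18 would otherwise inflate the
  sample mean by about two years. Binary marginals: 36.7% male, 57.8% some
  post-secondary, 45.0% married, 52.7% employed, 55.4% low income.
  Days-of-use in the past 30 uses the same moment-matched truncation with
  target mean 24 and SD 5.5 on [0, 30]; a single truncated normal cannot
  reach the heavier observed spread (SD ≈ 10) at that mean, so the
  generator reproduces "near-daily use" but under-disperses the tail of
  infrequent users.
- **Latent severity.** Faithful totals come from a truncated normal
  (mean 21, SD 8, on [0, 39]), consistent with screener group means of
  roughly 19–24. A latent total is realised as an item pattern by escalating
  randomly chosen items one weight-ladder step at a time until the target is
  bracketed; any positive severity endorses item 2 first, since a genuine
  recent user never reports "Never" there.
- **Test–retest noise.** Each item is repeated with probability `p_agree`,
  otherwise drifts one display-ordinal step (reflecting at the ends;
  item 2 never drifts into "Never" while severity > 0). Drift is local
  rather than a resample because retest error comes mostly from remembering
  or forgetting specifics between administrations. The default
  `p_agree = 0.74` was frozen from one bisection run targeting the
  subscale's published mean test–retest kappa of 0.64: at 0.74 the six
  per-item kappas on 10,000 simulated pairs span ≈ 0.59–0.66 (inside the
  published 0.43–0.72 range).
- **Invalid behaviors.** Uniform-random responders (and "bot" as a labelled
  alias with uniformly drawn usage probes), straightliners (a fixed ordinal
  everywhere, clamped per item — perfectly self-consistent and therefore
  invisible to this screen), and eligibility-seeking inflators, whose
  screener escalates every item `inflate_steps = 2` ladder steps above a low
  true severity (0.15 × the cohort's latent draw) and whose baseline reverts
  to truth with ordinary faithful noise.
- **Mixture.** The default cohort is 55% faithful, 20% random, 15%
  inflators, 5% straightliners, 5% bots. The real composition of any
  screened-out group is unknowable from published counts; the mixture is a
  scenario tool chosen to exercise every detector, not an estimate.
- **Attrition.** Consent, duplicate, withdrawal and baseline-completion
  rates default to the motivating flow's empirical stage fractions
  (1849/4153, 207/1849, 6/1642, 1381/1636), so simulated consort tables
  have realistic shape.
- **Reproducibility.** One master seed; each record draws from a substream
  keyed by (seed, record index), so regenerating or subsetting a cohort
  never changes an individual record.

What the simulator does **not** emulate: correlations between demographics
and behavior kind (real screened-out respondents skewed older with lower
totals; simulated demographics are independent of behavior), response
times, free-text answers, and within-person attrition mechanisms. Passing
tests therefore demonstrate the rule engine's and pipeline's correctness
and the screen's discriminating behaviour under controlled mixtures — not
the prevalence of invalid responding in any real cohort.

## Statistics

Group comparisons use Welch's unequal-variance t for continuous variables
(group sizes and SDs differ between screened groups; pooled-variance is
available by flag) and the 2×2 chi-square without continuity correction for
binary ones (large samples; with correction available by flag — the
uncorrected default reproduces the printed borderline income-row p of
0.047 from its published counts, where the corrected test would not). Tests
are two-sided, unadjusted for multiplicity (matching the reporting style
being emulated), with p-values displayed as "< 0.001" below that floor.
`summary_ttest` computes the Welch t directly from printed (mean, SD, n)
cells so published tables can be checked without raw data.

Detector evaluation reports per-behavior flag rates, sensitivity (flagged
fraction of truly non-faithful respondents) and specificity (unflagged
fraction of faithful ones) against simulator ground truth. The
random-responder flag probability has an independent oracle: exhaustive
enumeration of every eligible screener × baseline pair with the predicates
re-derived inline (instruments with ≤ 10⁷ pairs), against which the Monte
Carlo mode — which drives the actual rule engine — is checked within
binomial sampling error.

## Numerical choices and problem sizes

- Moment-matching for truncated normals solves a 2-parameter root-finding
  problem (`scipy.optimize.fsolve`, residual tolerance 10⁻⁶; infeasible
  targets raise rather than silently approximating).
- Per-item kappa uses the unweighted Cohen's kappa from the
  screener × baseline ordinal contingency table
  (`statsmodels.stats.inter_rater.cohens_kappa`).
- Default verification sizes: kappa calibration on 10,000 pairs; the
  flagged-fraction monotonicity grid at 5,000 pairs per `p_agree` point; the
  Monte Carlo oracle at 100,000 draws (binomial SE ≈ 0.0015 near p = 0.35);
  type-I calibration of the group comparison over 1,000 null replicates of
  two 500-observation groups. The end-to-end acceptance run screens a
  4,000-respondent cohort.
- Ties/degenerate inputs: zero-variance continuous comparisons are flagged
  as undefined rather than tested; empty report collections raise; a
  non-conserving consort table is an accounting error, never silently
  renormalised.

## Known limitations

- Straightliners are structurally invisible to cross-administration
  consistency checks (both administrations identical); the simulator and
  performance metrics quantify this blind spot rather than paper over it.
- The screen also excludes a nontrivial share of genuinely faithful noisy
  respondents (specificity well below 1 at calibrated noise), mirroring the
  design tension between data quality and excluding valid cases.
- Published cohort-dependent quantities (per-check frequencies among the
  screened out, group means) depend on the unavailable raw data; the
  package reproduces their table shapes and the printed aggregate replays,
  not their values.
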