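# Methods

## The decision model

The guideline is modelled as four deterministic lookups over row-enumerated
decision tables:

1. **Screening** — family history only: counts of affected first- and
   second-degree relatives and the youngest diagnosis age per degree. The
   four raw inputs are binned by the ruleset (counts 0/1/2/3+ and 0/1/2+;
   diagnosis-age bins per degree, applicable only when the count is
   nonzero), giving 10 x 9 = 90 scenarios in one table. The recommendation
   is a modality (stool test or colonoscopy) and a start age.
2. **First surveillance** — findings of the index colonoscopy: counts of
   conventional adenomas and clinically significant serrated polyps (CSSPs)
   and risk-feature flags (size >= 10 mm, high-grade dysplasia, villous
   change; CSSP size/dysplasia). A derived *lesion profile*
   (adenomas-only / serrated-only / mixed) selects one of 3 tables
   (13 + 6 + 18 = 37 scenarios); the recommendation is an interval in
   months.
3. **Subsequent surveillance** — two discriminators select one of 9 tables
   (prior lesion type x current lesion profile), mirroring the two
   consecutive tables a user of the printed guideline must navigate; rows
   are then keyed on the prior interval bin and current findings
   (48 + 48 + 44 = 140 scenarios).
4. **Cessation** — a modified Charlson score (standard condition weights
   plus one point per decade of age over 40) against an age-band x
   score-band stopping table. Patients younger than the assessment age
   (default 75) always continue. Score bands start above the age-point
   floor (age >= 75 alone contributes 4 points) so every band is reachable.

All table dimensions, bins, vocabularies, weights and thresholds are *data*
in the YAML ruleset, not code; the published scenario counts (90, 37, 140,
and the 230 headline total counted as screening + subsequent surveillance)
are checkable file properties. The packaged skeleton's recommendation
payloads are synthetic, monotone-in-risk placeholders; swapping in
transcribed guideline values is pure data entry.

### Validation semantics

`validate_ruleset` enumerates, per table, the cross-product of the declared
variable domains (conditional applicability applied: an age bin is `na`
exactly when its count bin is `0`) and requires each point to match exactly
one row; zero matches are gaps, multiple matches overlaps, and rows matching
no point are unreachable. Table selectors must tile the discriminator
domains exactly once. The engine's indexed lookup (hash on discriminators,
linear scan within the selected table) is defined to be correct only by
equivalence with the naive scan over every row of the section, which the
test suite asserts over all 267 interval scenarios plus the cessation grid.

Disjunctive guideline rows are represented as multiple rows sharing a
recommendation (predicates are conjunctions of equality/in-set clauses over
bin labels), which keeps overlap checking exact.

## Evaluation instruments

* **Vignette scoring.** Each vignette is scored on six items — screening
  start age, screening modality, first interval, subsequent interval, and
  the continue/stop decision at each of the two intended procedures — with
  unit weights by default (configurable; weights must sum to the 6-point
  vignette maximum). The cessation item is posed per intended procedure:
  the patient's age is advanced by the recommended interval (months floored
  to whole years) before each stopping-rule evaluation. Missing answers
  score as wrong; intervals match on months. A section of three vignettes
  scores 0–18.
* **Answer keys are engine-derived.** The six packaged vignettes (three
  difficulty-matched pairs exercising the adenoma, serrated and mixed table
  families) store no answers; keys are computed from the engine against the
  ruleset in play, so key and engine cannot disagree. The cases are
  synthetic fixtures.
* **SUS.** Sliders 0–100 are rounded half-up and binned 0–20/21–40/41–60/
  61–80/81–100 to Likert 1–5 (boundaries belong to the lower bin, exactly as
  the bins read); the total is 2.5 x [sum_odd (L-1) + sum_even (5-L)].
  Grades use bands F <= 51.7 < D <= 62.6 < C <= 72.5 < B <= 78.8 < A (with
  percentile bands 0–15 / 15–34 / 35–64 / 65–84 / 85–100); since attainable
  scores are multiples of 2.5 the half-open bounds tile them without gaps.
  Percentiles use the normal reference distribution with mean 68 and SD
  12.5, percentile = round(100·Phi((s − 68)/12.5)); this reproduces the
  96th percentile for a score of 90. Whether the published normalisation
  used this approximation or an empirical lookup is not documented; the
  normal form is adopted as the package's convention.
* **Randomization.** Eight strata (the eight vignette combinations, each
  pair contributing one member per section) with a configurable number of
  slots per stratum (default 14, hence 112 allocations), first aid assigned
  1:1 within each stratum and the block order permuted by one seeded
  generator (`numpy.random.default_rng`). The multiset of
  (stratum, first-tool) slots is seed-independent; only order varies.

## Trial statistics

* **Paired comparison** (DA vs SR section scores): Wilcoxon signed-rank,
  zeros dropped and their count reported. For <= 25 nonzero pairs the
  two-sided p is exact — the full 2^n sign-assignment distribution computed
  by dynamic programming over doubled midranks, so ties are handled without
  approximation; larger samples use the tie-corrected normal approximation.
  The *improvement ratio* is the ratio of median scores (the quantity a
  trial summary reports as a relative risk).
* **Group comparison**: Mann-Whitney U, exact by exhaustive label
  enumeration for pooled n <= 20 (midranks for ties), asymptotic with tie
  correction otherwise; the statistic reported is U of the first group.
* **Correlation**: Spearman rho with average ranks; constant vectors yield
  an undefined-correlation notice rather than a value.
* **Balance**: Pearson chi-square of independence (no continuity
  correction) on a tool-order x vignette-order contingency table, buildable
  directly from an allocation schedule.
* **Normality**: D = max |ECDF − fitted normal CDF| with sample mean and SD
  (ddof = 1); the p-value uses the Lilliefors correction for estimated
  parameters, with the plain (anti-conservative) KS p also reported because
  the convention behind published D(n) values is ambiguous.
* **Quantiles** use linear interpolation between order statistics
  throughout (the convention that yields quartiles like 7.75 on integer
  scores at n = 80).
* **Power**: smallest per-group integer n for a two-sided two-sample t test
  reaching the target power, by noncentral-t iteration
  (power(n) = P(|T| > t_crit), T ~ noncentral t with df = n1 + n2 − 2 and
  nc = d·sqrt(n1·n2/(n1+n2))). At means 60 vs 70, SD 20 (d = 0.5),
  alpha .05 and power .80 this gives 64 per group. The routine deliberately
  reproduces the two-sample design calculation used to size the study; a
  paired/crossover analysis would need fewer subjects.

## The simulator

`simulate_trial` emulates the participant dataset of the crossover study:
default n = 80 analysed participants (specialist fraction 37/80), each
section score the sum of 18 independent per-item Bernoulli concordance
draws with tool-specific probability — defaults 10/18 (SR) and 14/18 (DA),
so expected scores of 10 and 14 out of 18 — SUS sliders truncated-normal
around favourable anchors (positively worded items at 85 ± 15, negatively
worded mirrored), and allocations drawn from the stratified schedule
generator round-robin across strata so any n stays balanced. Everything is
bit-reproducible from the seed.

What the simulator does *not* model: learning or fatigue across sections,
item difficulty differences between vignettes, within-participant
correlation between the two aids beyond independence, or any coupling
between usability ratings and performance (the correlation between SUS and
DA scores is zero by construction under the defaults). Passing
simulator-based checks therefore demonstrates that the instruments and
statistics behave correctly under the stated generative model — not that
real clinicians would reproduce any particular effect size.

Monte-Carlo checks in the acceptance tests use 200 trials (ratio recovery:
median improvement ratio in [1.3, 1.5] under the default concordance
probabilities) and 1,000 trials (type-I calibration: rejection rate
5% ± 2% under equal concordance), sizes chosen to keep the whole suite in
the tens of seconds while leaving the bands comfortably testable.

## Numerical and design choices

* Intervals are integer months (represents both 6-month and multi-year
  recommendations exactly); ages integer years.
* Exact-test thresholds (25 pairs, pooled 20) are the points where
  enumeration stays essentially instantaneous; beyond them the
  tie-corrected approximations are standard.
* The 230 headline count is screening + subsequent-surveillance rows;
  first-surveillance rows are an intermediate layer (the published total
  and section counts cannot otherwise be reconciled, since
  90 + 37 + 140 = 267).
* Which four raw screening fields the original application captured is not
  documented; counts plus youngest diagnosis age per degree are adopted,
  with all bin boundaries living in the ruleset so alternative binnings are
  data changes.
* The stopping rule is evaluated once per intended procedure (twice per
  full vignette); a ruleset can change the assessment age.
* Schema validation of ruleset files is structural and hand-rolled with
  path-naming errors; `docs/ruleset.schema.json` documents the format for
  external tooling.

## Known limitations

* The skeleton's recommendation payloads are placeholders; concordance
  scored against them exercises the machinery, not clinical truth.
* Only conjunctive predicates over declared bins are expressible; a
  guideline row needing a genuine disjunction must be expanded into
  multiple rows.
* The exact Mann-Whitney path enumerates combinations and is intentionally
  capped at pooled n = 20.
* The percentile normalisation is the normal approximation; empirical
  percentile tables differ by up to a point or two near the tails.
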