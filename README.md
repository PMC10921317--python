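# crcguide

A decision-table engine and evaluation harness for Australia's colorectal-cancer
screening and surveillance guidelines.

The current Australian guidelines are among the most complex in the world:
row-enumerated risk tables describe 90 screening scenarios (by the number,
degree and diagnosis age of affected relatives), 37 first-surveillance
scenarios across 3 tables and 140 subsequent-surveillance scenarios across 9
tables (by the number, class and risk features of lesions found at up to two
consecutive colonoscopies), plus stopping rules for older patients driven by
a modified Charlson comorbidity score. Clinicians navigating these tables by
hand make discordant recommendations often enough that digital calculators
are worth building — and worth evaluating rigorously.

`crcguide` provides both halves of that programme:

* **Engine** — a deterministic calculator over row-enumerated decision tables
  (screening modality and start age; first and subsequent surveillance
  intervals; continue/stop decisions from an age-band x Charlson-score
  lookup). Rulesets are plain YAML data; the packaged reference skeleton
  reproduces the guideline's table structure and scenario counts with
  synthetic placeholder recommendations. Every ruleset can be exhaustively
  validated: each enumerable scenario must match exactly one row, and the
  indexed lookup is checked against a naive full-row scan over all scenarios
  — the same "calculate every possible scenario" strategy used to validate
  the original applications.
* **Evaluation harness** — the instruments of a randomized controlled
  crossover comparison of a digital application (DA) against the standard
  resource (SR): vignette concordance scoring (6 points per vignette, 18 per
  section of three), System Usability Scale scoring with slider-to-Likert
  binning, letter grades and Sauro–Lewis percentile normalisation,
  stratified 1:1 allocation schedules over the 8 vignette combinations, the
  trial's statistical battery (Wilcoxon signed-rank, Mann-Whitney U,
  Spearman rho, chi-square balance checks, Lilliefors normality, noncentral-t
  power), and a synthetic participant simulator so the entire pipeline runs
  without human-subject data.

## Worked example

Compute all recommendations for a case (an affected first-degree relative
diagnosed at 52; three adenomas, one >= 10 mm, at the index colonoscopy; one
adenoma at follow-up after a 36-month interval; age 72 with diabetes):

```sh
$ crcguide recommend --case alpha.json
screening: modality=colonoscopy start_age=45 [SCR/SCR-019]
first_surveillance: interval=18mo [FS-A/FS-A-07]
subsequent_surveillance: interval=36mo [SS-AA/SS-AA-02]
cessation: continue [CES/below_assessment_age]
```

Each line is one decision: the screening table recommends colonoscopy from
age 45 for this family history; the index findings put the first
surveillance at 18 months; the follow-up findings (after navigating the
prior-adenoma table) put the next at 36 months; and at 72 the patient is
below the cessation-assessment age, so surveillance continues. The bracketed
pair is the provenance — the decision table and row that produced the value,
so every recommendation is auditable against the ruleset file.

Validate the packaged ruleset and reproduce the guideline's scenario counts:

```sh
$ crcguide validate
ruleset validation: OK
  screening: 90 scenario rows
  first_surveillance: 37 scenario rows
  subsequent_surveillance: 140 scenario rows
  cessation: 9 scenario rows
  headline scenario count: 230
```

The study-design power calculation (mean accuracy 60% vs 70%, SD 20%,
alpha .05, power .80) gives the per-group sample size:

```sh
$ crcguide power
64
```

Other subcommands: `enumerate` (list every scenario point), `randomize`
(stratified crossover schedules), `score` (vignette concordance), `sus`
(usability scoring), `simulate` (synthetic participants) and `analyze` (the
full statistical battery on a paired-scores CSV). All randomized commands
require an explicit `--seed` and are bit-reproducible.

## Scope

The packaged ruleset is a *skeleton*: its structure, dimensions and counts
follow the published guideline, but its recommendation payloads are
synthetic placeholders (provenance `skeleton`). Transcribing authoritative
values from the published guideline is a data-entry exercise in the YAML
file; no code changes. See `docs/methods.md` for the model, conventions and
limitations.
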