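# Methods

## Unit of analysis: the episode of care

The unit throughout is the hospital *episode of care*, not the claim. A
claims system may bill one continuous hospitalization as several records:
when a claim ends in a *stay* (a new claim opens in the same hospital) or an
*interhospital transfer*, the hospitalization continues. Linkage is
deterministic and uses only variables available in deidentified extracts:

- claims are **blocked** on (municipality of residence, date of birth);
- within a block they are **sorted** by admission date, ties broken by
  discharge date and then claim id — the tie-break is not part of the
  epidemiological rule, it only makes the partition reproducible and
  independent of input order;
- consecutive claims are **chained** iff the earlier one ended in stay or
  transfer and the later admission falls 0–1 days after the earlier
  discharge, with hospital equality required only for stay continuations
  (transfers change hospital by definition, so hospital equality cannot be
  enforced unconditionally even though the hospital code is a linkage
  variable);
- chaining is **greedy left-to-right**; a claim that cannot extend the
  current chain opens a new episode. Negative gaps (overlapping stays) never
  chain and are logged as data-quality warnings.

The episode's outcome is the discharge class of its last claim; age is in
completed years at the episode's admission date.

Known limitation: blocking on (municipality, birth date) can collide two
patients. A collision merges or splits chains only when their dates
interleave within the one-day window, which is rare but visible at scale
(the synthetic demo shows ~1 extra episode per 100,000 patients). This is a
faithful property of deterministic linkage on deidentified keys, not an
implementation artifact.

## Cohort

An episode is obstetric if any claim carries an ICD-10 chapter-XV ("O")
code in the principal or any secondary diagnosis field, or an obstetric
principal procedure (code list replaceable via CSV). The cohort keeps
obstetric episodes of women aged 10–49 inclusive at admission, discharged
alive or dead in hospital. The three criteria are independent predicates,
so they commute and the selection is idempotent.

Death confirmation is an optional stage (off by default, since arbitrary
inputs have no registry): a death episode is kept only if a registry entry
matches on (birth date, municipality) with a death date inside
[admission, discharge + 1 day]. The one-day grace tolerates date-entry lag
and is configurable; the matching key mirrors the deidentified linkage
variables, since registry matching practice varies by data source.

## Morbidity classification

Each ICD-10 code maps to one of 20 item labels (12 numbered groups, some
with lettered subgroups) adapted from the WHO ICD-10 grouping of maternal
deaths, widened to morbidity: codes that are reasons for admission but not
causes of death join the nearest group, and morbidity-only groups (e.g.
childbirth, supervision of pregnancy) exist alongside. Matching is
longest-prefix on dotless uppercase codes with prefixes of 1–4 characters:
chapter-level single letters cover blocks that map wholesale (J → respiratory
subgroup), longer prefixes override (D50–D64 anemia out of the D chapter,
O24.4 gestational diabetes out of O24). Anything unmatched falls into the
residual group 13, so classification is total. The shipped mapping
(`src/morbrules/data/default_mapping.csv`, 183 rows) is an approximation
assembled from the group definitions; it is versioned, validated on load
(prefix shape, label catalogue, ambiguity) and user-replaceable — no
pipeline logic depends on a specific entry. Group numbering skips 6,
following the source scheme's published tables.

An episode's transaction is the deduplicated set of item labels over every
diagnosis of every claim, plus exactly one outcome item (DEATH/ALIVE).
Classification is order-independent by construction (set union).

## Mining

Apriori is implemented from scratch, level-wise with standard candidate
generation (join frequent (k−1)-sets sharing a (k−2)-prefix; prune unless
every (k−1)-subset is frequent). Counting collapses the database to unique
transaction profiles with multiplicities and enumerates each profile's
k-subsets, which is fast because transactions carry few items. The support
threshold s is applied as an absolute count floor max(1, ⌈s·n⌉), so the
default 1e-10 means "count ≥ 1" at any realistic n — rare-outcome rules
must survive generation and be selected later, not be cut by support.

Rules are generated only with an outcome item as consequent: every reported
rule has discharge status on the right-hand side, and alive-consequent
rules (lift ≈ 1 by construction, since nearly all episodes end alive) are
generated and then removed by the lift filter rather than special-cased.
This restriction avoids the combinatorial blow-up of arbitrary consequents
without changing the analysis surface. Metrics are exact floating-point
ratios of integer counts; the identities support = count/n,
confidence = support/Supp(X) and lift·Supp(Y) = confidence hold to 1e-12
and are asserted in the tests. A consequent absent from all transactions
has Supp(Y) = 0; its rules are undefined and skipped with a warning.

Selection filters run in the order lift ≥ 1.1 → redundancy pruning →
count ≥ 4 → antecedent exclusion of group 10 (childbirth, uninformative for
morbidity), each logging its removal count. A rule is redundant when a rule
with the same consequent and a proper subset of its antecedent has
confidence ≥ its own; redundancy is evaluated against the input rule set,
which makes pruning idempotent. The count and lift filters commute; the
order is configurable. Canonical ordering everywhere (itemsets by size then
label; label ties lexicographic) keeps output files reproducible.

## Synthetic data: what it emulates and what it does not

The generator plants known structure so every downstream stage has a
measurable target:

- one episode per patient; claim counts per episode are geometric with
  continuation probability `transfer_prob` (default 0.011, i.e. ~98.9%
  single-claim episodes, the order observed in claims systems of this kind);
- admission dates uniform over a six-year window; ages uniform 15–44
  (inside the 10–49 cohort band); dates and identifiers drawn so that the
  claims CSV round-trips through the linkage stage;
- morbidity items are independent Bernoulli draws per episode at the
  configured prevalences (defaults span 0.4%–6%, plausible magnitudes for
  obstetric admissions), optionally tilted pairwise: for a pair (a, b, m),
  the odds of b are multiplied by m where a is present, applied in list
  order;
- death is multiplicative: P(death | items S) = min(1, p0 · ∏ rr_i),
  default p0 = 3e-4 (the order of in-hospital death among obstetric
  episodes). For a planted single item with prevalence p and risk r, the
  single-antecedent rule's population lift is r / (1 + p(r−1)) — the
  closed-form recovery target; for rare items it approximates r itself;
- every claim carries the canonical childbirth principal diagnosis (O80)
  and an obstetric procedure code, so all synthetic episodes enter the
  cohort; morbidity items are written as canonical ICD codes that the
  active mapping resolves back to the intended labels, distributed across
  the episode's claims so the transaction really exercises the union;
- the death registry covers each death episode independently with the
  configured coverage, with a death date inside the final claim's stay;
- claims are emitted shuffled; all randomness flows from a single seed and
  identical (seed, config) gives byte-identical CSVs across processes.

Not modelled: multiple episodes per patient, seasonal or secular structure,
inter-patient correlation, realistic municipal/hospital size distributions,
coding error. Passing tests therefore demonstrate the correctness of the
pipeline's logic and the recoverability of planted effects under clean
conditions — not robustness to the coding noise and linkage ambiguity of
real extracts.

## Calibration of the recovery experiments

The planted-effect experiments (test suite) use 100,000 episodes with a
baseline death probability of 0.05, a rare planted item (prevalence 0.002,
relative risk 10) and three null items (prevalences 0.2–0.3, risk 1).
These sizes are a power analysis, fixed in advance:

- with p = 0.002 and r = 10 the population lift is 10/1.018 ≈ 9.82, a bias
  under 2% of the target;
- the planted item's expected death count is 100,000·0.002·0.5 = 100, giving
  a binomial relative standard error of ~7% for the lift, so the 25%
  recovery band sits beyond 3 standard errors;
- expected total deaths ≈ 5,090, so a null item with prevalence 0.3 has
  lift standard error ≈ √(0.7/(5,090·0.3)) ≈ 0.021, putting the 1.1 lift
  threshold more than 4 standard errors above 1 — null rules should be
  removed in essentially all of the 20 replicates (the test requires 95%).

At the generator's default death rate of 3e-4 the planted item would expect
fewer than one death per run and no lift band would be meaningful; the
elevated rate is what makes the binomial error small enough for the bands
to be informative. The generator defaults themselves stay at the realistic
values.

## Numerical and formatting choices

- Report rounding follows the conventions of published tables of this kind:
  supports to 3 significant figures, confidence and lift to 3 decimals,
  shares of deaths to 1 decimal, the death share of all episodes to 2
  decimals. Python banker's rounding applies at exact half-way points.
- The rules CSV stores full precision (support in scientific notation with
  12 digits), so every report number is recomputable from it.
- Degenerate inputs: an empty database refuses to mine; an empty cohort
  aborts the pipeline with a diagnostic; zero filtered rules produce empty
  tables and a valid summary block.
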