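# Methods

## The model

The package evaluates a sequencing program with a decision-analytic
cost-utility model built from counterfactual care trajectories.

**Delphi consensus.** Each counterfactual statement is rated by an expert
panel on a five-point Likert scale (strongly disagree = 1 … strongly
agree = 5); "unable to comment" responses are excluded from scoring but
counted. The round statistic is the arithmetic mean over valid scores, kept
at full precision (display to panelists is formatted to two decimals).
Consensus is mean ≥ 4 or ≤ 2, both comparisons inclusive and guarded by an
absolute tolerance of 1e-9 against binary-float artifacts. A question
unresolved in round one returns to the panel with the group mean; the stop
criterion is hard-coded at two rounds — a configurable round count was
considered and rejected to keep the procedure faithful to its definition —
after which unresolved questions are discarded. Panel size is data, not a
constant (the packaged cohort uses a ten-intensivist panel and, for one
hematologic question, five hematologists); a panelist absent from round two
is simply absent from that round's mean.

**Cost ledger.** Every monetary effect is a line item with an unsigned
amount and an explicit direction (avoided / incurred), so the sign
convention — savings positive, incurred negative — is applied in exactly one
place and cannot silently double-negate. Amounts are nominal USD carried as
exact decimals to the cent; reports round to whole dollars half away from
zero. No inflation adjustment and no cost-to-charge conversion are applied
(charges serve as cost proxies). Items referencing a Delphi question enter
the totals only if that question reached consensus; exclusion is reversible
(re-including a gated item restores the original total) and aggregation is
order-independent, both property-tested. Daily hospitalization cost is the
mean of the patient's last three non-procedure inpatient days — exactly
three, by construction of the estimator — and an avoided stay is days ×
daily cost. Professional fees are hospital charges × a published ratio
supplied as configuration; the ratio's numeric value is deliberately not a
package constant, and the packaged cohort carries professional fees inside
its pre-computed line items instead of deriving them.

**QALY trees.** Outcomes are finite acyclic one-shot decision trees: internal
chance nodes whose branch probabilities must sum to one within 1e-9 (a
violation aborts, naming the node), and leaves carrying a quality-of-life
weight Q ∈ [0, 1] and a duration in years. A leaf contributes Q × years;
tree value is the expectation over root-to-leaf paths, and an intervention's
QALY gain is the difference of its with/without trees. There is no Markov
cycling and no half-cycle correction — the model is a one-shot tree.
Discounting defaults to 0, matching the printed arithmetic of the source
cohort (0.12 + 11.98 = 12.1); an optional annual rate r discounts year t by
(1+r)^−t with the fractional final year prorated linearly, which makes the
r → 0 limit continuous. Per-patient QALY components are bookkept as exact
decimals (two-decimal published values sum without float drift); the
sex-specific life-expectancy table interpolates linearly in age and clamps
outside its range.

**Cost-effectiveness.** Net cost is sequencing total minus net savings.
ICER = net cost / total QALYs, rounded to whole dollars half away from zero
(54,554 / 12.1 = 4,508.595… → 4,509). Non-positive net cost with positive
QALY gain is *dominant* (no finite ICER); positive cost with zero QALY gain
also has no finite ICER and is classified low value — the only economically
sensible class for paying something and gaining nothing. Value brackets use
strict inequality below the conservative ($20,000/QALY) and standard
($50,000/QALY) thresholds and include the upper bound ($100,000/QALY) in
"borderline"; the source material gives ranges, not comparisons, so the
boundary behavior is a documented package choice. Yields are rounded to the
nearest integer percent (nearest-integer is consistent with both published
yields, 17/38 → 45 and 13/17 → 76). The ICER denominator counts QALYs from
consensus-gated patients only.

## Tunable parameters

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| `discount_rate` | 0 | per year | matches the undiscounted published arithmetic; set ~0.03 for standard HTA practice |
| `WtpThresholds` | 20,000 / 50,000 / 100,000 | USD/QALY | conservative, classic, and upper US willingness-to-pay benchmarks |
| `ProfessionalFeeModel.ratio` | required input | — | published ratio of professional to hospital charges; institution-specific |
| `CohortGeneratorConfig.n_probands` | 38 | probands | study cohort size |
| `p_diagnosis` | 0.45 | — | diagnostic yield |
| `p_management_change_given_dx` | 0.76 | — | management-change rate among diagnosed |
| `p_modelable_given_change` | 8/13 | — | fraction of changes quantifiable |
| `savings_distribution` | lognormal(μ=10.2, σ=1.1) | log-USD | median ≈ $27k with a heavy right tail spanning the observed $8k–$135k |
| `p_incurred_item`, `incurred_distribution` | 0.3, lognormal(9.6, 0.7) | — | incurred costs are rarer and smaller than savings |
| `p_qaly_gain` | 2/7 | — | QALY gains concentrated in a minority of modeled patients |
| `p_question_agree` | 7/8 | — | questions whose true effect sits in the agreement region |
| `panel_size`, `delphi_agreement_concentration` | 10, 2.5 | — | panel scores ~ Normal(true effect, 1/concentration), discretized to 1–5 |

## The synthetic generator and what passing tests show

`generate_cohort` draws diagnosis → management-change → modelable flags as a
Bernoulli chain, log-normal savings and (rarer) incurred items per modeled
patient, with/without outcome-tree pairs within configured ranges whose
mortality and morbidity components become the QALY table, and panel
responses by discretizing a normal distribution centered on each question's
true effect (round two, when needed, re-centers between the round-one group
mean and the true effect with doubled concentration, emulating convergence).
One seed drives everything through deterministically split per-table
streams, so identical seeds give byte-identical cohorts and partial
regeneration is reproducible.

The generator emulates the *statistical shape* of a real cohort, not its
substance: no phenotypes, no variants, no correlation between disease
severity and cost, independence across patients, single-item cost
structures, and panel responses that are honest noisy measurements of a true
effect (real panelists can be biased or bimodal). Tests passing on synthetic
cohorts therefore demonstrate the pipeline's accounting, gating and
statistical correctness — not that any particular real-world cohort is
cost-effective.

The packaged study fixture carries the published per-patient values
directly. Three elements are synthesized and flagged as such: panelist-level
responses (constrained only to reproduce the published per-question
outcomes), the gated-out placeholder ledger amount for the no-consensus
patient, and the uniform $6,300 per-family allocation of the published
$239,400 sequencing total (the per-trio reference price of $7,400 × 38
families does not reconcile with that total — family configurations were
mixed and never itemized — so the summed total is treated as authoritative
and the pipeline records a reconciliation note). The illustrative
Factor XIII outcome-tree pair uses the published risk inputs (12% mortality
on a second CNS bleed; 72.6% neurologic complications among survivors) but
placeholder QOL weights and durations, since the parameterization behind the
published 9.08/2.90 components was not released; its outputs are never
asserted against those components.

## Numerical choices

- Money: `decimal.Decimal` quantized to the cent; whole-dollar reporting
  rounds half away from zero. QALY components likewise decimal; tree
  expectations are floats.
- Consensus threshold comparisons: inclusive with 1e-9 absolute tolerance.
- Tree probability validation: 1e-9 absolute on each node's branch sum.
- Degenerate inputs: an all-"unable to comment" round has an undefined mean
  and cannot reach consensus; an empty ledger nets to zero; a cohort with no
  modeled patients reports net cost = sequencing total with no finite ICER;
  a question with consensus in round one ignores any round-two content.
- Ties/order: ledger aggregation is permutation-invariant by construction
  (exact decimal sums); per-patient output is sorted by patient id.

## Limitations

- No probabilistic sensitivity analysis, acceptability curves, payer- vs
  societal-perspective accounting, or cascade-testing economics.
- No utility elicitation or EQ-5D mapping: QOL weights are inputs.
- The cohort-level hospital/professional savings split is verified only as a
  sum-consistency check; it is not available per patient.
- Problem sizes used by the test suite and acceptance script — the
  38-proband packaged cohort, 200 random trees for the expectation oracle,
  and a 10,000-proband synthetic cohort for parameter recovery — were chosen
  as the smallest sizes at which the binomial standard-error bounds are
  meaningful.
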