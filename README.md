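# rwgscea

Cost-utility analysis of rapid whole genome sequencing (rWGS) programs in
pediatric intensive care.

When a critically ill child with a suspected monogenic disorder receives a
rapid genomic diagnosis, clinical management often changes: procedures are
cancelled, stays shortened, or new treatments started. Because these
children have ultra-rare diseases, matched historical controls rarely exist,
so the economic effect is estimated from *counterfactual trajectories* — what
care would have looked like without the diagnosis — validated by a modified
Delphi panel of independent clinicians. This package implements that whole
analysis chain for health-economics researchers evaluating sequencing
programs:

1. **Delphi engine** — Likert responses scored 1–5 ("unable to comment"
   excluded), round means compared against inclusive consensus thresholds
   (mean ≥ 4 agreement, ≤ 2 disagreement), at most two rounds; questions
   unresolved after round two are discarded and gate out their line items.
2. **Cost ledger** — per-patient avoided and incurred cost line items
   (nominal USD, exact to the cent), daily-cost estimation from the mean of
   the last three non-procedure inpatient days, professional fees as a
   published ratio of hospital charges, and conservation-checked cohort
   totals.
3. **QALY model** — one-shot probability-weighted outcome trees with
   leaves QALY = Q × years (Q ∈ [0, 1] a quality-of-life weight), expected
   values over root-to-leaf paths, optional annual discounting, and exact
   decimal sums of per-patient QALY components.
4. **CEA pipeline** — net cost ΔC = C_seq − S, incremental
   cost-effectiveness ratio ICER = ΔC / ΔQALY, willingness-to-pay
   classification ($20k / $50k / $100k per QALY brackets), diagnostic and
   management-change yields, and a deterministic structured report.
5. **Synthetic data** — a seeded cohort generator with the study's
   statistical structure (fixed diagnostic yield, heavy-tailed log-normal
   cost effects, sparse QALY gains, concentration-controlled panel
   responses) plus a packaged fixture of the published 38-proband PICU
   cohort, so everything runs offline.

## Worked example

```python
from rwgscea import paper_fixture, run_from_frames
from rwgscea.cea_pipeline import summary_markdown

fx = paper_fixture()
result, report = run_from_frames(
    fx.cohort, fx.ledger, fx.responses, fx.qaly_components, fx.sequencing
)
print(summary_markdown(result, report))
```

prints

```
| Patient | Cost savings / (costs incurred) | QALY savings |
|---------|--------------------------------:|-------------:|
| 6007 | $9,795 | - |
| 6147 | $74,556 | - |
| 6153 | - | 0.12 |
| 6159 | $8,108 | - |
| 6180 | -$9,856 (incurred cost) | - |
| 6193 | $134,538 | - |
| 6207 | -$32,295 (incurred cost) | 11.98 |
| **Total** | **$184,846** | **12.10** |

- Sequencing total: $239,400
- Net cost: $54,554
- QALYs gained: 12.10
- ICER: $4,509 per QALY (high_value_conservative)
- Diagnostic yield: 45%; management change among diagnosed: 76%
```

Reading: seven of eight panel-reviewed counterfactuals reached consensus
(patient 6052's did not, so its items are gated out). Their cost effects net
to $184,846 saved; sequencing the full 38-family cohort cost $239,400, a net
loss of $54,554 — but 12.1 quality-adjusted life years were gained, so the
program cost $4,509 per QALY, well under even the conservative $20,000/QALY
willingness-to-pay threshold.

The same pipeline runs from the shell:

```bash
rwgscea fixtures paper --out-dir fixture/
rwgscea cea run --in-dir fixture/ --out-dir results/
rwgscea simulate --out-dir synth/ --seed 7 --n 38   # synthetic cohort
```

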