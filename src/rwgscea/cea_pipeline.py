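"""End-to-end cost-utility analysis pipeline.

Orchestrates the full analysis of a rapid-genome-sequencing program:

1. adjudicate Delphi questions and build the consensus gate;
2. aggregate the counterfactual cost ledger to per-patient and cohort totals;
3. sum per-patient QALY components for consensus-gated patients;
4. total sequencing costs across the cohort;
5. compute net cost (sequencing minus savings), the incremental
   cost-effectiveness ratio (ICER, dollars per QALY gained), classify it
   against willingness-to-pay thresholds, and report diagnostic and
   management-change yields.

Conventions: positive net cost means the program cost more than it saved;
a negative net cost with positive QALY gain is *dominant* (cheaper and
better) and no finite ICER is reported.  Dollars are reported rounded half
away from zero; yield percentages to the nearest integer.
"""

from __future__ import annotations

import enum
import json
import logging
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from . import cost_ledger, delphi_engine, qaly_model
from .cost_ledger import CostLineItem, round_whole_dollars, to_usd
from .delphi_engine import ConsensusStatus, DelphiQuestion
from .qaly_model import PatientQalyResult

logger = logging.getLogger(__name__)


class SequencingConfiguration(str, enum.Enum):
    SINGLETON = "singleton"
    DUO = "duo"
    TRIO = "trio"
    OTHER = "other"


class SequencingCostEntry(BaseModel):
    """Sequencing cost for one proband family (family members priced jointly)."""

    patient_id: str
    configuration: SequencingConfiguration = SequencingConfiguration.TRIO
    cost_usd: Decimal = Field(ge=0)

    @field_validator("cost_usd", mode="before")
    @classmethod
    def _usd(cls, v):
        return to_usd(v)


class IcerFlag(str, enum.Enum):
    """Non-finite ICER outcomes."""

    #: Negative or zero net cost with QALYs gained: cheaper and better.
    DOMINANT = "dominant"
    #: Positive net cost with zero QALYs gained: no finite ratio exists.
    NO_QALY_GAIN = "no_qaly_gain"


IcerValue = Union[Decimal, IcerFlag]


class ValueClass(str, enum.Enum):
    DOMINANT = "dominant"
    HIGH_VALUE_CONSERVATIVE = "high_value_conservative"
    HIGH_VALUE = "high_value"
    BORDERLINE = "borderline"
    LOW_VALUE = "low_value"


class WtpThresholds(BaseModel):
    """Willingness-to-pay brackets in dollars per QALY.

    Defaults follow common US practice: $20,000 per QALY satisfies even
    conservative analysts, $50,000 is the classic benchmark, and funders'
    thresholds range up to $100,000.
    """

    conservative_usd_per_qaly: Decimal = Decimal("20000")
    standard_usd_per_qaly: Decimal = Decimal("50000")
    upper_usd_per_qaly: Decimal = Decimal("100000")

    @field_validator(
        "conservative_usd_per_qaly",
        "standard_usd_per_qaly",
        "upper_usd_per_qaly",
        mode="before",
    )
    @classmethod
    def _dec(cls, v):
        return v if isinstance(v, Decimal) else Decimal(str(v))

    @model_validator(mode="after")
    def _ordered(self) -> "WtpThresholds":
        if not (
            self.conservative_usd_per_qaly
            <= self.standard_usd_per_qaly
            <= self.upper_usd_per_qaly
        ):
            raise ValueError("thresholds must satisfy conservative <= standard <= upper")
        return self


class CohortRecord(BaseModel):
    """One proband's cohort-level flags.

    A management change implies a diagnosis; being modeled (entering
    quantitative cost/QALY analysis) implies a management change.
    """

    patient_id: str
    diagnosed: bool = False
    management_change: bool = False
    modeled: bool = False

    @model_validator(mode="after")
    def _flags_consistent(self) -> "CohortRecord":
        if self.management_change and not self.diagnosed:
            raise ValueError(
                f"patient {self.patient_id}: management_change without diagnosis"
            )
        if self.modeled and not self.management_change:
            raise ValueError(
                f"patient {self.patient_id}: modeled without management change"
            )
        return self


class CohortSummary(BaseModel):
    n_probands: int
    n_diagnosed: int
    n_management_change: int
    n_modeled: int
    yield_diagnosed_pct: int
    yield_management_change_pct: int


class CeaResult(BaseModel):
    """Cohort-level result of the cost-utility analysis."""

    total_savings_usd: Decimal
    total_incurred_usd: Decimal
    sequencing_total_usd: Decimal
    net_cost_usd: Decimal
    total_qalys: Decimal
    icer_usd_per_qaly: Decimal | None
    icer_flag: IcerFlag | None
    value_class: ValueClass
    yield_diagnosed_pct: int
    yield_management_change_pct: int

    @model_validator(mode="after")
    def _identity(self) -> "CeaResult":
        if self.net_cost_usd != self.sequencing_total_usd - self.total_savings_usd:
            raise ValueError("net_cost must equal sequencing_total - total_savings")
        return self


def sequencing_total(entries: Sequence[SequencingCostEntry]) -> Decimal:
    """Total sequencing cost across proband families; duplicates rejected."""
    ids = [e.patient_id for e in entries]
    if len(ids) != len(set(ids)):
        dupes = sorted({p for p in ids if ids.count(p) > 1})
        raise ValueError(f"duplicate proband(s) in sequencing entries: {dupes}")
    return sum((e.cost_usd for e in entries), Decimal("0.00"))


def net_cost(sequencing_total_usd, total_savings_usd) -> Decimal:
    """Sequencing cost minus savings: positive = net loss, negative = net saving."""
    seq = to_usd(sequencing_total_usd)
    sav = to_usd(total_savings_usd)
    return seq - sav


def icer(net_cost_usd, total_qalys) -> IcerValue:
    """Incremental cost-effectiveness ratio in dollars per QALY gained.

    Positive net cost over positive QALYs gives the ratio, rounded to whole
    dollars half away from zero.  Non-positive net cost with QALYs gained is
    dominant (no finite ICER); positive net cost with zero QALYs has no
    finite ICER either.
    """
    nc = net_cost_usd if isinstance(net_cost_usd, Decimal) else Decimal(str(net_cost_usd))
    q = total_qalys if isinstance(total_qalys, Decimal) else Decimal(str(total_qalys))
    if q < 0:
        raise ValueError("total_qalys must be non-negative")
    if q > 0 and nc > 0:
        return round_whole_dollars(nc / q)
    if q > 0:
        return IcerFlag.DOMINANT
    if nc > 0:
        return IcerFlag.NO_QALY_GAIN
    # Zero cost and zero QALYs: nothing happened; treat as dominant-direction.
    return IcerFlag.DOMINANT


def classify_value(
    icer_value: IcerValue, thresholds: WtpThresholds | None = None
) -> ValueClass:
    """Classify an ICER against willingness-to-pay brackets.

    Strict inequality below the conservative and standard thresholds;
    values at or below the upper threshold are borderline, above it low
    value.  A program with positive cost and no QALY gain is low value.
    """
    t = thresholds or WtpThresholds()
    if icer_value is IcerFlag.DOMINANT:
        return ValueClass.DOMINANT
    if icer_value is IcerFlag.NO_QALY_GAIN:
        return ValueClass.LOW_VALUE
    v = icer_value if isinstance(icer_value, Decimal) else Decimal(str(icer_value))
    if v < t.conservative_usd_per_qaly:
        return ValueClass.HIGH_VALUE_CONSERVATIVE
    if v < t.standard_usd_per_qaly:
        return ValueClass.HIGH_VALUE
    if v <= t.upper_usd_per_qaly:
        return ValueClass.BORDERLINE
    return ValueClass.LOW_VALUE


def _pct(numerator: int, denominator: int) -> int:
    """Percentage rounded to the nearest integer (half away from zero)."""
    if denominator == 0:
        return 0
    frac = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return int(frac.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def cohort_summary(cohort: Sequence[CohortRecord]) -> CohortSummary:
    """Cohort counts and yields: % diagnosed of tested, % changed of diagnosed."""
    ids = [r.patient_id for r in cohort]
    if len(ids) != len(set(ids)):
        dupes = sorted({p for p in ids if ids.count(p) > 1})
        raise ValueError(f"duplicate patient_id(s) in cohort: {dupes}")
    n = len(cohort)
    n_dx = sum(r.diagnosed for r in cohort)
    n_change = sum(r.management_change for r in cohort)
    n_modeled = sum(r.modeled for r in cohort)
    return CohortSummary(
        n_probands=n,
        n_diagnosed=n_dx,
        n_management_change=n_change,
        n_modeled=n_modeled,
        yield_diagnosed_pct=_pct(n_dx, n),
        yield_management_change_pct=_pct(n_change, n_dx),
    )


class RunConfig(BaseModel):
    """Run-wide configuration for the analysis pipeline."""

    thresholds: WtpThresholds = Field(default_factory=WtpThresholds)
    discount_rate: float = Field(default=0.0, ge=0.0)
    professional_fee_ratio: Decimal | None = None
    #: Optional cohort-level split of total savings used as a consistency
    #: check when supplied (hospital + professional must equal total savings).
    hospital_savings_usd: Decimal | None = None
    professional_savings_usd: Decimal | None = None
    #: Reference per-family sequencing price for the reconciliation note.
    reference_cost_per_trio_usd: Decimal | None = None

    @field_validator(
        "professional_fee_ratio",
        "hospital_savings_usd",
        "professional_savings_usd",
        "reference_cost_per_trio_usd",
        mode="before",
    )
    @classmethod
    def _dec(cls, v):
        if v is None:
            return v
        return v if isinstance(v, Decimal) else Decimal(str(v))


def run_analysis(
    cohort: Sequence[CohortRecord],
    items: Iterable[CostLineItem],
    questions: Sequence[DelphiQuestion],
    qaly_components: pd.DataFrame | Sequence[PatientQalyResult],
    sequencing_entries: Sequence[SequencingCostEntry],
    config: RunConfig | None = None,
) -> tuple[CeaResult, dict]:
    """Run the full pipeline and return the result plus a structured report.

    Stages run in order (Delphi gating, cost ledger, QALY totals, sequencing,
    ICER, classification, yields); a validation failure in any stage aborts
    with a stage-tagged message.  The report records a per-stage audit,
    including every patient excluded from modeling and why.
    """
    config = config or RunConfig()

    # --- stage 1: Delphi adjudication -> consensus gate -------------------
    try:
        adjudicated = [
            q if q.final_status is not ConsensusStatus.PENDING else
            delphi_engine.run_question(q)
            for q in questions
        ]
        consensus = delphi_engine.consensus_map(adjudicated)
    except ValueError as e:
        raise ValueError(f"[delphi] {e}") from e

    patient_has_consensus: dict[str, bool] = {}
    for q in adjudicated:
        prev = patient_has_consensus.get(q.patient_id, False)
        patient_has_consensus[q.patient_id] = prev or q.final_status.is_consensus

    # --- stage 2: cost ledger ---------------------------------------------
    try:
        effects = cost_ledger.ledger_net_effects(items, consensus)
        # Patients gated out entirely contribute a zero effect; drop them from
        # the modeled set but keep them in the audit.
        modeled_effects = [
            e
            for e in effects
            if patient_has_consensus.get(e.patient_id, True)
        ]
        cost_summary = cost_ledger.cohort_cost_totals(modeled_effects)
    except ValueError as e:
        raise ValueError(f"[ledger] {e}") from e

    # --- stage 3: QALY totals (consensus-gated patients only) -------------
    try:
        if isinstance(qaly_components, pd.DataFrame):
            qaly_results = qaly_model.results_from_components_table(
                qaly_components, patient_has_consensus
            )
        else:
            qaly_results = [
                r
                for r in qaly_components
                if patient_has_consensus.get(r.patient_id, True)
            ]
        total_qalys = qaly_model.cohort_qaly_total(qaly_results)
    except ValueError as e:
        raise ValueError(f"[qaly] {e}") from e

    # --- stage 4: sequencing, net cost, ICER, classification, yields ------
    try:
        seq_total = sequencing_total(sequencing_entries)
        nc = net_cost(seq_total, cost_summary.total_net_usd)
        icer_value = icer(nc, total_qalys)
        vclass = classify_value(icer_value, config.thresholds)
        summary = cohort_summary(cohort)
    except ValueError as e:
        raise ValueError(f"[cea] {e}") from e

    result = CeaResult(
        total_savings_usd=cost_summary.total_net_usd,
        total_incurred_usd=cost_summary.total_incurred_usd,
        sequencing_total_usd=seq_total,
        net_cost_usd=nc,
        total_qalys=total_qalys,
        icer_usd_per_qaly=icer_value if isinstance(icer_value, Decimal) else None,
        icer_flag=icer_value if isinstance(icer_value, IcerFlag) else None,
        value_class=vclass,
        yield_diagnosed_pct=summary.yield_diagnosed_pct,
        yield_management_change_pct=summary.yield_management_change_pct,
    )

    report = _build_report(
        result, summary, adjudicated, effects, modeled_effects,
        qaly_results, cohort, config,
    )
    return result, report


def _build_report(
    result: CeaResult,
    summary: CohortSummary,
    questions: Sequence[DelphiQuestion],
    effects,
    modeled_effects,
    qaly_results: Sequence[PatientQalyResult],
    cohort: Sequence[CohortRecord],
    config: RunConfig,
) -> dict:
    modeled_ids = {e.patient_id for e in modeled_effects} | {
        r.patient_id for r in qaly_results
    }
    exclusions = []
    for rec in cohort:
        if rec.management_change and not rec.modeled:
            exclusions.append(
                {"patient_id": rec.patient_id, "reason": "not_quantitatively_modelable"}
            )
    for q in questions:
        if not q.final_status.is_consensus:
            exclusions.append(
                {
                    "patient_id": q.patient_id,
                    "reason": f"delphi_{q.final_status.value}",
                    "question_id": q.question_id,
                }
            )

    notes = []
    if config.hospital_savings_usd is not None and config.professional_savings_usd is not None:
        split_sum = config.hospital_savings_usd + config.professional_savings_usd
        ok = split_sum == result.total_savings_usd
        notes.append(
            {
                "check": "hospital_plus_professional_split",
                "hospital_usd": str(config.hospital_savings_usd),
                "professional_usd": str(config.professional_savings_usd),
                "sum_usd": str(split_sum),
                "total_savings_usd": str(result.total_savings_usd),
                "consistent": ok,
            }
        )
        if not ok:
            logger.warning(
                "hospital + professional savings split (%s) does not equal "
                "total savings (%s)", split_sum, result.total_savings_usd,
            )
    if config.reference_cost_per_trio_usd is not None:
        implied = config.reference_cost_per_trio_usd * summary.n_probands
        notes.append(
            {
                "check": "per_family_price_reconciliation",
                "reference_cost_per_trio_usd": str(config.reference_cost_per_trio_usd),
                "n_probands": summary.n_probands,
                "implied_total_usd": str(implied),
                "actual_sequencing_total_usd": str(result.sequencing_total_usd),
                "consistent": implied == result.sequencing_total_usd,
                "note": "mixed family configurations make the per-family "
                "price a reference figure; the summed entries are authoritative",
            }
        )

    return {
        "result": {
            "total_savings_usd": str(result.total_savings_usd),
            "total_incurred_usd": str(result.total_incurred_usd),
            "sequencing_total_usd": str(result.sequencing_total_usd),
            "net_cost_usd": str(result.net_cost_usd),
            "total_qalys": str(result.total_qalys),
            "icer_usd_per_qaly": (
                str(result.icer_usd_per_qaly)
                if result.icer_usd_per_qaly is not None
                else result.icer_flag.value
            ),
            "value_class": result.value_class.value,
            "yield_diagnosed_pct": result.yield_diagnosed_pct,
            "yield_management_change_pct": result.yield_management_change_pct,
        },
        "cohort": summary.model_dump(),
        "delphi": [
            {
                "question_id": q.question_id,
                "patient_id": q.patient_id,
                "final_status": q.final_status.value,
                "round_means": [
                    rs.mean_score for rs in q.round_scores
                ],
            }
            for q in questions
        ],
        "per_patient_costs": [
            {
                "patient_id": e.patient_id,
                "savings_usd": str(e.savings_usd),
                "incurred_usd": str(e.incurred_usd),
                "net_usd": str(e.net_usd),
                "modeled": e.patient_id in modeled_ids,
            }
            for e in effects
        ],
        "per_patient_qalys": [
            {
                "patient_id": r.patient_id,
                "components": {k: str(v) for k, v in r.components.items()},
                "total_qalys": str(r.total_qalys),
            }
            for r in qaly_results
        ],
        "exclusions": exclusions,
        "reconciliation_notes": notes,
    }


def report_to_json(report: dict) -> str:
    """Serialize a report deterministically (sorted keys, stable formatting)."""
    return json.dumps(report, indent=2, sort_keys=True)


def summary_markdown(result: CeaResult, report: dict) -> str:
    """Human-readable summary: a per-patient table plus the headline totals."""
    lines = [
        "| Patient | Cost savings / (costs incurred) | QALY savings |",
        "|---------|--------------------------------:|-------------:|",
    ]
    qalys = {r["patient_id"]: r["total_qalys"] for r in report["per_patient_qalys"]}
    cost_rows = {r["patient_id"]: r for r in report["per_patient_costs"]}
    shown = sorted(
        {p for p, r in cost_rows.items() if r["modeled"]} | set(qalys)
    )
    for pid in shown:
        row = cost_rows.get(pid)
        if row is None:
            money = "-"
        else:
            net = Decimal(row["net_usd"])
            money = (
                f"${round_whole_dollars(net):,}"
                if net >= 0
                else f"-${round_whole_dollars(-net):,} (incurred cost)"
            )
        lines.append(f"| {pid} | {money} | {qalys.get(pid, '-')} |")
    lines.append(
        f"| **Total** | **${round_whole_dollars(result.total_savings_usd):,}** "
        f"| **{result.total_qalys}** |"
    )
    icer_txt = (
        f"${result.icer_usd_per_qaly:,} per QALY"
        if result.icer_usd_per_qaly is not None
        else result.icer_flag.value
    )
    lines += [
        "",
        f"- Sequencing total: ${round_whole_dollars(result.sequencing_total_usd):,}",
        f"- Net cost: ${round_whole_dollars(result.net_cost_usd):,}",
        f"- QALYs gained: {result.total_qalys}",
        f"- ICER: {icer_txt} ({result.value_class.value})",
        f"- Diagnostic yield: {result.yield_diagnosed_pct}%; "
        f"management change among diagnosed: {result.yield_management_change_pct}%",
    ]
    return "\n".join(lines)


def plot_summary(result: CeaResult, path: str) -> None:
    """Bar chart of savings vs sequencing cost, with QALYs on a second axis."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.bar(
        ["Cost savings", "Sequencing cost"],
        [float(result.total_savings_usd), float(result.sequencing_total_usd)],
        color=["#2a9d8f", "#e76f51"],
    )
    ax.set_ylabel("USD")
    ax2 = ax.twinx()
    ax2.bar(["QALYs gained"], [float(result.total_qalys)], color="#264653", width=0.4)
    ax2.set_ylabel("QALYs")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
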