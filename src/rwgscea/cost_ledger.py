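"""Counterfactual cost-ledger accounting.

Each monetary effect of a genomic diagnosis is one line item: an *avoided*
cost (e.g. an inpatient day or procedure that would have happened under the
counterfactual trajectory) or an *incurred* cost (e.g. additional treatment
started because of the diagnosis).  Amounts are stored unsigned with an
explicit direction so the sign convention lives in one place: savings are
positive, incurred costs negative in a patient's net effect.

Line items may reference the Delphi question that asserted their
counterfactual; such items enter the totals only if that question reached
consensus.  Items tied to a discarded (no-consensus) question are excluded
and logged.

All amounts are nominal USD carried as exact decimals to the cent; no
inflation adjustment or cost-to-charge conversion is applied.
"""

from __future__ import annotations

import enum
import logging
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

from pydantic import BaseModel, Field, field_validator, model_validator

from .delphi_engine import ConsensusStatus

logger = logging.getLogger(__name__)

CENT = Decimal("0.01")


def to_usd(value) -> Decimal:
    """Coerce a number to an exact USD Decimal quantized to the cent."""
    d = value if isinstance(value, Decimal) else Decimal(str(value))
    return d.quantize(CENT, rounding=ROUND_HALF_UP)


def round_whole_dollars(value: Decimal | float) -> Decimal:
    """Round to whole dollars, half away from zero (reporting convention)."""
    d = value if isinstance(value, Decimal) else Decimal(str(value))
    return d.quantize(Decimal("1"), rounding=ROUND_HALF_UP)


class CostCategory(str, enum.Enum):
    HOSPITAL_DAY = "hospital_day"
    PROCEDURE = "procedure"
    MEDICATION = "medication"
    PROFESSIONAL_FEE = "professional_fee"
    OTHER = "other"


class CostDirection(str, enum.Enum):
    AVOIDED = "avoided"
    INCURRED = "incurred"


class CostLineItem(BaseModel):
    """One avoided or incurred monetary effect attributable to the diagnosis."""

    item_id: str
    patient_id: str
    category: CostCategory
    direction: CostDirection
    amount_usd: Decimal = Field(ge=0)
    source_question_id: str | None = None
    description: str = ""

    @field_validator("amount_usd", mode="before")
    @classmethod
    def _quantize(cls, v):
        return to_usd(v)


class DailyCostEstimate(BaseModel):
    """Daily hospitalization cost proxied by the mean of the patient's last
    three inpatient days, procedure charges excluded."""

    patient_id: str
    last_three_day_charges_usd: list[Decimal]
    daily_cost_usd: Decimal = Field(ge=0)

    @field_validator("last_three_day_charges_usd", mode="before")
    @classmethod
    def _quantize_each(cls, v):
        return [to_usd(x) for x in v]

    @model_validator(mode="after")
    def _check(self) -> "DailyCostEstimate":
        if len(self.last_three_day_charges_usd) != 3:
            raise ValueError("exactly three daily charges are required")
        if any(c < 0 for c in self.last_three_day_charges_usd):
            raise ValueError("daily charges must be non-negative")
        mean = sum(self.last_three_day_charges_usd) / 3
        if self.daily_cost_usd != to_usd(mean):
            raise ValueError(
                "daily_cost_usd must equal the mean of the three charges"
            )
        return self


class ProfessionalFeeModel(BaseModel):
    """Professional (physician-service) fees as a published fixed ratio of
    accrued hospital charges.  The ratio is configuration, never a constant."""

    ratio: Decimal = Field(ge=0)

    @field_validator("ratio", mode="before")
    @classmethod
    def _dec(cls, v):
        return v if isinstance(v, Decimal) else Decimal(str(v))


class PatientNetEffect(BaseModel):
    """Per-patient totals: savings, incurred costs, and their signed net."""

    patient_id: str
    savings_usd: Decimal = Field(ge=0)
    incurred_usd: Decimal = Field(ge=0)
    net_usd: Decimal

    @model_validator(mode="after")
    def _net_identity(self) -> "PatientNetEffect":
        if self.net_usd != self.savings_usd - self.incurred_usd:
            raise ValueError("net_usd must equal savings_usd - incurred_usd")
        return self


class CohortCostSummary(BaseModel):
    """Cohort-level monetary totals across all modeled patients."""

    total_savings_usd: Decimal
    total_incurred_usd: Decimal
    total_net_usd: Decimal
    n_patients: int


def estimate_daily_cost(
    patient_id: str, charges: Sequence
) -> DailyCostEstimate:
    """Estimate the daily cost of hospitalization from the last three
    inpatient days' charges (procedures excluded).

    The three-day rule is deliberate: fewer or more values are rejected.
    """
    charges = [to_usd(c) for c in charges]
    if len(charges) != 3:
        raise ValueError(
            f"expected exactly 3 daily charges, got {len(charges)}"
        )
    if any(c < 0 for c in charges):
        raise ValueError("daily charges must be non-negative")
    return DailyCostEstimate(
        patient_id=patient_id,
        last_three_day_charges_usd=charges,
        daily_cost_usd=to_usd(sum(charges) / 3),
    )


def avoided_stay_value(days, daily_cost) -> Decimal:
    """Value of an avoided length-of-stay reduction: days x daily cost."""
    days_d = days if isinstance(days, Decimal) else Decimal(str(days))
    cost_d = daily_cost if isinstance(daily_cost, Decimal) else Decimal(str(daily_cost))
    if days_d < 0:
        raise ValueError("days must be non-negative")
    if cost_d < 0:
        raise ValueError("daily_cost must be non-negative")
    return to_usd(days_d * cost_d)


def professional_fee(hospital_amount, model: ProfessionalFeeModel) -> Decimal:
    """Professional fee accrued on a hospital amount: amount x ratio."""
    amt = hospital_amount if isinstance(hospital_amount, Decimal) else Decimal(str(hospital_amount))
    if amt < 0:
        raise ValueError("hospital_amount must be non-negative")
    return to_usd(amt * model.ratio)


def _item_included(
    item: CostLineItem, consensus: Mapping[str, ConsensusStatus]
) -> bool:
    """Whether an item passes the Delphi gate.

    Items without a source question always pass.  Items whose question was
    discarded (or is still pending) are excluded and logged; referencing an
    unknown question is an error.
    """
    qid = item.source_question_id
    if qid is None or qid == "":
        return True
    if qid not in consensus:
        raise ValueError(
            f"item {item.item_id!r} references unknown question {qid!r}"
        )
    status = consensus[qid]
    if isinstance(status, str):
        status = ConsensusStatus(status)
    if status is ConsensusStatus.PENDING:
        raise ValueError(
            f"item {item.item_id!r} references question {qid!r} "
            "whose status is still pending"
        )
    if not status.is_consensus:
        logger.info(
            "excluding item %s (patient %s, %s %s): question %s ended %s",
            item.item_id,
            item.patient_id,
            item.direction.value,
            item.amount_usd,
            qid,
            status.value,
        )
        return False
    return True


def patient_net_effect(
    items: Iterable[CostLineItem],
    consensus: Mapping[str, ConsensusStatus] | None = None,
) -> PatientNetEffect:
    """Aggregate one patient's line items into savings, incurred, and net.

    ``consensus`` maps question ids to final Delphi statuses; items gated by
    a non-consensus question are excluded.  All items must belong to the same
    patient.
    """
    consensus = consensus or {}
    items = list(items)
    patients = {it.patient_id for it in items}
    if len(patients) > 1:
        raise ValueError(
            f"items span multiple patients: {sorted(patients)}"
        )
    patient_id = patients.pop() if patients else ""
    savings = Decimal("0.00")
    incurred = Decimal("0.00")
    for it in items:
        if not _item_included(it, consensus):
            continue
        if it.direction is CostDirection.AVOIDED:
            savings += it.amount_usd
        else:
            incurred += it.amount_usd
    return PatientNetEffect(
        patient_id=patient_id,
        savings_usd=savings,
        incurred_usd=incurred,
        net_usd=savings - incurred,
    )


def ledger_net_effects(
    items: Iterable[CostLineItem],
    consensus: Mapping[str, ConsensusStatus] | None = None,
) -> list[PatientNetEffect]:
    """Group a full ledger by patient and compute each patient's net effect,
    ordered by patient id."""
    by_patient: dict[str, list[CostLineItem]] = {}
    for it in items:
        by_patient.setdefault(it.patient_id, []).append(it)
    return [
        patient_net_effect(group, consensus)
        for _, group in sorted(by_patient.items())
    ]


def cohort_cost_totals(
    effects: Sequence[PatientNetEffect],
) -> CohortCostSummary:
    """Sum per-patient net effects to cohort totals.

    Conserves the identity total net = total savings - total incurred
    exactly; duplicate patients are rejected.
    """
    ids = [e.patient_id for e in effects]
    if len(ids) != len(set(ids)):
        dupes = sorted({p for p in ids if ids.count(p) > 1})
        raise ValueError(f"duplicate patient_id(s) in effects: {dupes}")
    savings = sum((e.savings_usd for e in effects), Decimal("0.00"))
    incurred = sum((e.incurred_usd for e in effects), Decimal("0.00"))
    return CohortCostSummary(
        total_savings_usd=savings,
        total_incurred_usd=incurred,
        total_net_usd=savings - incurred,
        n_patients=len(effects),
    )
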