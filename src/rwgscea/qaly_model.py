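"""Quality-adjusted life year (QALY) evaluation on one-shot decision trees.

The outcome of an intervention (or its counterfactual) is a finite
probability-weighted tree whose leaves are health states: a quality-of-life
weight Q in [0, 1] (0 = death, 1 = perfect health) and a duration in years.
A leaf contributes Q x years; a tree's expected QALYs is the sum over
root-to-leaf paths of the path probability times the leaf value.  The QALY
gain of an intervention is the difference of the expected QALYs of its
with- and without-intervention trees.

Discounting defaults to 0 (undiscounted QALYs, matching the printed
arithmetic of the study this models); an optional annual discount rate is
available for standard health-technology-assessment practice, with the
fractional final year prorated linearly.

Per-patient QALY components (e.g. avoided-mortality and avoided-morbidity
QALYs) are bookkept exactly as decimals so that two-decimal published
components sum without binary-float drift.
"""

from __future__ import annotations

import math
from decimal import Decimal
from typing import Mapping, Sequence, Union

import pandas as pd
from pydantic import BaseModel, Field, model_validator

#: Tolerance on branch probabilities summing to one at each internal node.
PROB_TOL = 1e-9


class OutcomeLeaf(BaseModel):
    """A terminal health state: QOL weight and remaining years in that state."""

    label: str = ""
    qol_weight: float = Field(ge=0.0, le=1.0)
    duration_years: float = Field(ge=0.0)


class Branch(BaseModel):
    probability: float = Field(ge=0.0, le=1.0)
    child: Union["OutcomeNode", OutcomeLeaf]


class OutcomeNode(BaseModel):
    """An internal chance node; child branch probabilities must sum to one."""

    label: str = ""
    branches: list[Branch] = Field(min_length=1)


Branch.model_rebuild()

OutcomeTree = Union[OutcomeNode, OutcomeLeaf]


class LifeExpectancyRow(BaseModel):
    sex: str
    age_years: float = Field(ge=0)
    remaining_years: float = Field(ge=0)


class LifeExpectancyTable(BaseModel):
    """Sex-specific remaining life expectancy by age.

    Lookup interpolates linearly between bracketing ages and clamps outside
    the tabulated range.
    """

    rows: list[LifeExpectancyRow]

    @model_validator(mode="after")
    def _sorted_within_sex(self) -> "LifeExpectancyTable":
        seen: dict[str, set[float]] = {}
        for r in self.rows:
            ages = seen.setdefault(r.sex, set())
            if r.age_years in ages:
                raise ValueError(
                    f"duplicate age {r.age_years} for sex {r.sex!r}"
                )
            ages.add(r.age_years)
        return self

    def remaining_years(self, sex: str, age_years: float) -> float:
        rows = sorted(
            (r for r in self.rows if r.sex == sex), key=lambda r: r.age_years
        )
        if not rows:
            raise KeyError(f"no life-expectancy rows for sex {sex!r}")
        if age_years <= rows[0].age_years:
            return rows[0].remaining_years
        if age_years >= rows[-1].age_years:
            return rows[-1].remaining_years
        for lo, hi in zip(rows, rows[1:]):
            if lo.age_years <= age_years <= hi.age_years:
                span = hi.age_years - lo.age_years
                frac = (age_years - lo.age_years) / span
                return lo.remaining_years + frac * (
                    hi.remaining_years - lo.remaining_years
                )
        raise AssertionError("unreachable")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LifeExpectancyTable":
        return cls(
            rows=[
                LifeExpectancyRow(
                    sex=str(r.sex),
                    age_years=float(r.age_years),
                    remaining_years=float(r.remaining_years),
                )
                for r in df.itertuples()
            ]
        )


def discount_factor_years(duration_years: float, discount_rate: float) -> float:
    """Present-value year count for a duration at an annual discount rate.

    With rate 0 this is the duration itself; otherwise each whole year t
    contributes (1+r)^-t and the fractional final year is prorated linearly
    at the next year's factor, so the limit r -> 0 is continuous.
    """
    if discount_rate < 0:
        raise ValueError("discount rate must be non-negative")
    if discount_rate == 0:
        return duration_years
    whole = int(math.floor(duration_years))
    frac = duration_years - whole
    total = sum((1 + discount_rate) ** (-t) for t in range(1, whole + 1))
    if frac > 0:
        total += frac * (1 + discount_rate) ** (-(whole + 1))
    return total


def leaf_qaly(leaf: OutcomeLeaf, discount_rate: float = 0.0) -> float:
    """QALYs accrued in a terminal state: QOL weight x (discounted) years."""
    return leaf.qol_weight * discount_factor_years(
        leaf.duration_years, discount_rate
    )


def _validate_node(node: OutcomeNode, path: str) -> None:
    total = sum(b.probability for b in node.branches)
    if abs(total - 1.0) > PROB_TOL:
        name = node.label or path
        raise ValueError(
            f"branch probabilities at node {name!r} sum to {total!r}, not 1"
        )


def expected_qalys(tree: OutcomeTree, discount_rate: float = 0.0) -> float:
    """Expected QALYs of an outcome tree.

    Equals the sum over root-to-leaf paths of the product of branch
    probabilities times the leaf QALYs.  Raises if any internal node's
    branch probabilities do not sum to one, naming the node.
    """
    return sum(
        prob * value
        for _, prob, value in enumerate_paths(tree, discount_rate)
    )


def enumerate_paths(
    tree: OutcomeTree, discount_rate: float = 0.0
) -> list[tuple[str, float, float]]:
    """Audit trail of every root-to-leaf path.

    Returns (path label, path probability, leaf QALYs) triples; the expected
    value is the probability-weighted sum of leaf QALYs.
    """
    out: list[tuple[str, float, float]] = []

    def walk(node: OutcomeTree, prob: float, path: str) -> None:
        if isinstance(node, OutcomeLeaf):
            label = f"{path}/{node.label or 'leaf'}"
            out.append((label, prob, leaf_qaly(node, discount_rate)))
            return
        _validate_node(node, path)
        for i, b in enumerate(node.branches):
            child_path = f"{path}/{node.label or 'node'}[{i}]"
            walk(b.child, prob * b.probability, child_path)

    walk(tree, 1.0, "")
    return out


def qaly_gain(
    with_intervention: OutcomeTree,
    without_intervention: OutcomeTree,
    discount_rate: float = 0.0,
) -> float:
    """QALY gain of the intervention: E[with] - E[without]; may be negative."""
    return expected_qalys(with_intervention, discount_rate) - expected_qalys(
        without_intervention, discount_rate
    )


def tree_from_dict(data: Mapping) -> OutcomeTree:
    """Parse a nested mapping (e.g. loaded from YAML/JSON) into a tree.

    A node mapping has ``branches`` (each with ``probability`` and ``child``);
    a leaf mapping has ``qol_weight`` and ``duration_years``.
    """
    if "branches" in data:
        return OutcomeNode.model_validate(data)
    return OutcomeLeaf.model_validate(data)


def _to_decimal(value) -> Decimal:
    return value if isinstance(value, Decimal) else Decimal(str(value))


class PatientQalyResult(BaseModel):
    """Named QALY components for one patient and their exact total."""

    patient_id: str
    components: dict[str, Decimal]
    total_qalys: Decimal

    @model_validator(mode="before")
    @classmethod
    def _coerce(cls, data):
        if isinstance(data, dict) and "components" in data:
            data = dict(data)
            data["components"] = {
                k: _to_decimal(v) for k, v in data["components"].items()
            }
            if "total_qalys" in data:
                data["total_qalys"] = _to_decimal(data["total_qalys"])
        return data

    @model_validator(mode="after")
    def _total_is_sum(self) -> "PatientQalyResult":
        if self.total_qalys != sum(
            self.components.values(), Decimal("0")
        ):
            raise ValueError("total_qalys must equal the sum of components")
        return self


def patient_qaly_total(
    patient_id: str, components: Mapping[str, float | Decimal]
) -> PatientQalyResult:
    """Sum a patient's named QALY components exactly (decimal arithmetic)."""
    comps = {k: _to_decimal(v) for k, v in components.items()}
    for k, v in comps.items():
        if not v.is_finite():
            raise ValueError(f"component {k!r} is not finite")
    return PatientQalyResult(
        patient_id=patient_id,
        components=comps,
        total_qalys=sum(comps.values(), Decimal("0")),
    )


def cohort_qaly_total(results: Sequence[PatientQalyResult]) -> Decimal:
    """Total QALYs gained across the cohort; duplicate patients rejected."""
    ids = [r.patient_id for r in results]
    if len(ids) != len(set(ids)):
        dupes = sorted({p for p in ids if ids.count(p) > 1})
        raise ValueError(f"duplicate patient_id(s): {dupes}")
    return sum((r.total_qalys for r in results), Decimal("0"))


def results_from_components_table(
    df: pd.DataFrame,
    consensus_by_patient: Mapping[str, bool] | None = None,
) -> list[PatientQalyResult]:
    """Build per-patient results from a long table
    (``patient_id, component, value``), optionally dropping patients whose
    counterfactual failed the Delphi gate."""
    required = {"patient_id", "component", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"components table missing column(s): {sorted(missing)}")
    results = []
    for pid, group in df.groupby("patient_id", sort=True):
        pid = str(pid)
        if consensus_by_patient is not None and not consensus_by_patient.get(
            pid, True
        ):
            continue
        comps = {
            str(r.component): _to_decimal(r.value) for r in group.itertuples()
        }
        results.append(patient_qaly_total(pid, comps))
    return results
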