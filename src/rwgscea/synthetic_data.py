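"""Synthetic cohorts and the packaged study fixture.

Two sources of test data, both producing the same table shapes the pipeline
reads:

* :func:`generate_cohort` draws a synthetic PICU sequencing cohort with the
  statistical structure the analysis assumes — a fixed diagnostic yield, a
  management-change rate among diagnosed patients, heavy-tailed (log-normal)
  per-patient cost effects with occasional incurred costs, sparse QALY gains
  concentrated in a few patients, and Likert panel responses concentrated
  around each question's true effect.  The generating truth is returned
  alongside the tables so parameter-recovery tests can compare empirical
  rates against it.

* :func:`paper_fixture` packages the published 38-proband cohort: 17
  diagnosed, 13 with management changes, 8 modeled by the Delphi panel, 7
  reaching consensus, with the published per-patient cost effects and QALY
  components.  Panelist-level responses were not published; the fixture's
  response sets are synthesized to be consistent with the published
  per-question consensus statuses only, and are flagged non-authoritative.

All tables are plain pandas DataFrames writable as CSV, so every pipeline
stage is testable without any download.
"""

from __future__ import annotations

import dataclasses
from decimal import Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .delphi_engine import SCORE_LABELS
from .qaly_model import OutcomeLeaf, OutcomeNode, Branch, OutcomeTree

_TABLE_NAMES = ("cohort", "ledger", "responses", "qaly_components", "sequencing")


class LogNormalParams(BaseModel):
    """Location/scale of a log-normal draw on the USD scale."""

    mu: float
    sigma: float = Field(gt=0)


class QalyTreeParams(BaseModel):
    """Ranges for the randomly built with/without outcome-tree pairs."""

    p_death_range: tuple[float, float] = (0.05, 0.30)
    p_complication_range: tuple[float, float] = (0.30, 0.80)
    qol_impaired_range: tuple[float, float] = (0.40, 0.80)
    duration_years_range: tuple[float, float] = (20.0, 75.0)


class CohortGeneratorConfig(BaseModel):
    """Generator configuration.

    Defaults reproduce the study conditions: 38 probands, a 45% diagnostic
    yield, a 76% management-change rate among diagnosed patients, and most
    changed patients quantitatively modelable (8 of 13).  Cost effects are
    log-normal with a heavy right tail spanning roughly $5k-$150k; incurred
    costs are a rarer, smaller log-normal.  QALY gains occur in a minority of
    modeled patients (2 of 7 in the study).  Panels have ten members whose
    scores concentrate around each question's true effect.
    """

    n_probands: int = Field(default=38, gt=0)
    p_diagnosis: float = Field(default=0.45, ge=0, le=1)
    p_management_change_given_dx: float = Field(default=0.76, ge=0, le=1)
    p_modelable_given_change: float = Field(default=8 / 13, ge=0, le=1)
    savings_distribution: LogNormalParams = LogNormalParams(mu=10.2, sigma=1.1)
    p_incurred_item: float = Field(default=0.3, ge=0, le=1)
    incurred_distribution: LogNormalParams = LogNormalParams(mu=9.6, sigma=0.7)
    p_qaly_gain: float = Field(default=2 / 7, ge=0, le=1)
    qaly_tree_params: QalyTreeParams = QalyTreeParams()
    #: Probability a modeled question's true effect is in the agreement
    #: region (7 of 8 questions reached consensus in the study).
    p_question_agree: float = Field(default=7 / 8, ge=0, le=1)
    sequencing_cost_by_configuration: dict[str, float] = {
        "trio": 7400.0,
        "duo": 6000.0,
        "singleton": 4500.0,
    }
    configuration_probabilities: dict[str, float] = {
        "trio": 0.8,
        "duo": 0.1,
        "singleton": 0.1,
    }
    panel_size: int = Field(default=10, gt=0)
    delphi_agreement_concentration: float = Field(default=2.5, gt=0)
    seed: int = 0

    @model_validator(mode="after")
    def _config_probs(self) -> "CohortGeneratorConfig":
        total = sum(self.configuration_probabilities.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("configuration probabilities must sum to 1")
        missing = set(self.configuration_probabilities) - set(
            self.sequencing_cost_by_configuration
        )
        if missing:
            raise ValueError(f"no sequencing cost for configuration(s): {missing}")
        return self


@dataclasses.dataclass
class SyntheticCohort:
    """The five pipeline input tables plus the generating truth."""

    cohort: pd.DataFrame
    ledger: pd.DataFrame
    responses: pd.DataFrame
    qaly_components: pd.DataFrame
    sequencing: pd.DataFrame
    truth: dict

    def to_dir(self, out_dir: str | Path) -> None:
        """Write all tables as CSV (the dialect the pipeline reads)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in _TABLE_NAMES:
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)

    @classmethod
    def from_dir(cls, in_dir: str | Path) -> "SyntheticCohort":
        p = Path(in_dir)
        frames = {
            name: pd.read_csv(
                p / f"{name}.csv",
                dtype={
                    c: str
                    for c in (
                        "patient_id", "item_id", "question_id",
                        "panelist_id", "source_question_id",
                    )
                },
                keep_default_na=False,
            )
            for name in _TABLE_NAMES
        }
        return cls(truth={}, **frames)


def generate_delphi_responses(
    true_effect: float,
    panel_size: int,
    concentration: float,
    rng: np.random.Generator,
) -> list[str]:
    """Draw panel labels from a discretized normal around a true effect.

    Scores are normal(true_effect, 1/concentration), rounded to the nearest
    integer and clipped to 1..5, then mapped back to labels.  High
    concentration drives every panelist to the integer nearest the true
    effect, so consensus probability approaches one when the true effect is
    in the agreement (>= 4) or disagreement (<= 2) region.
    """
    if panel_size < 1:
        raise ValueError("panel_size must be >= 1")
    if not 1.0 <= true_effect <= 5.0:
        raise ValueError("true_effect must lie in [1, 5]")
    raw = rng.normal(loc=true_effect, scale=1.0 / concentration, size=panel_size)
    scores = np.clip(np.rint(raw), 1, 5).astype(int)
    return [SCORE_LABELS[int(s)] for s in scores]


def _question_rows(
    question_id: str,
    patient_id: str,
    round_index: int,
    labels: list[str],
    panel_prefix: str = "P",
) -> list[dict]:
    return [
        {
            "question_id": question_id,
            "patient_id": patient_id,
            "panelist_id": f"{panel_prefix}{i + 1:02d}",
            "round": round_index,
            "label": lab,
        }
        for i, lab in enumerate(labels)
    ]


def _round_mean(labels: list[str]) -> float | None:
    from .delphi_engine import score_round

    return score_round(labels).mean_score


def generate_cohort(config: CohortGeneratorConfig) -> SyntheticCohort:
    """Draw a full synthetic cohort; identical seeds give identical cohorts.

    One global seed governs all randomness: the seed sequence is split
    deterministically into per-table streams (flags, costs, QALY trees,
    Delphi responses, sequencing), so each table is reproducible on its own.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_flags, rng_cost, rng_qaly, rng_delphi, rng_seq = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    cohort_rows, ledger_rows, response_rows, qaly_rows, seq_rows = [], [], [], [], []
    truth_patients: dict[str, dict] = {}

    configs = list(config.configuration_probabilities)
    cfg_probs = [config.configuration_probabilities[c] for c in configs]

    for i in range(config.n_probands):
        pid = f"S{i + 1:05d}"
        diagnosed = bool(rng_flags.random() < config.p_diagnosis)
        change = diagnosed and bool(
            rng_flags.random() < config.p_management_change_given_dx
        )
        modelable = change and bool(
            rng_flags.random() < config.p_modelable_given_change
        )
        cohort_rows.append(
            {
                "patient_id": pid,
                "diagnosed": diagnosed,
                "management_change": change,
                "modeled": modelable,
            }
        )

        cfg_name = configs[rng_seq.choice(len(configs), p=cfg_probs)]
        seq_rows.append(
            {
                "patient_id": pid,
                "configuration": cfg_name,
                "cost_usd": round(
                    config.sequencing_cost_by_configuration[cfg_name], 2
                ),
            }
        )

        if not modelable:
            continue

        qid = f"Q-{pid}"
        agree = bool(rng_delphi.random() < config.p_question_agree)
        true_effect = 4.6 if agree else 3.2
        conc = config.delphi_agreement_concentration
        r1 = generate_delphi_responses(
            true_effect, config.panel_size, conc, rng_delphi
        )
        response_rows += _question_rows(qid, pid, 1, r1)
        m1 = _round_mean(r1)
        reached = m1 is not None and (m1 >= 4 - 1e-9 or m1 <= 2 + 1e-9)
        if not reached:
            # Round 2: panelists see the group mean and converge toward it
            # and the underlying effect; concentration doubles.
            center = float(np.clip((true_effect + (m1 or 3.0)) / 2, 1.0, 5.0))
            r2 = generate_delphi_responses(
                center, config.panel_size, 2 * conc, rng_delphi
            )
            response_rows += _question_rows(qid, pid, 2, r2)
            m2 = _round_mean(r2)
            reached = m2 is not None and (m2 >= 4 - 1e-9 or m2 <= 2 + 1e-9)

        savings = float(
            np.round(
                rng_cost.lognormal(
                    config.savings_distribution.mu,
                    config.savings_distribution.sigma,
                ),
                2,
            )
        )
        ledger_rows.append(
            {
                "item_id": f"I-{pid}-sav",
                "patient_id": pid,
                "category": "hospital_day",
                "direction": "avoided",
                "amount_usd": savings,
                "source_question_id": qid,
                "description": "avoided counterfactual hospital stay",
            }
        )
        incurred = 0.0
        if rng_cost.random() < config.p_incurred_item:
            incurred = float(
                np.round(
                    rng_cost.lognormal(
                        config.incurred_distribution.mu,
                        config.incurred_distribution.sigma,
                    ),
                    2,
                )
            )
            ledger_rows.append(
                {
                    "item_id": f"I-{pid}-inc",
                    "patient_id": pid,
                    "category": "medication",
                    "direction": "incurred",
                    "amount_usd": incurred,
                    "source_question_id": qid,
                    "description": "treatment started because of the diagnosis",
                }
            )

        mortality_q = morbidity_q = 0.0
        if rng_qaly.random() < config.p_qaly_gain:
            tp = config.qaly_tree_params
            p_death = rng_qaly.uniform(*tp.p_death_range)
            p_comp = rng_qaly.uniform(*tp.p_complication_range)
            qol_imp = rng_qaly.uniform(*tp.qol_impaired_range)
            dur = rng_qaly.uniform(*tp.duration_years_range)
            mortality_q = round(p_death * dur, 2)
            morbidity_q = round((1 - p_death) * p_comp * (1 - qol_imp) * dur, 2)
            qaly_rows += [
                {
                    "patient_id": pid,
                    "component": "avoided_mortality",
                    "value": mortality_q,
                },
                {
                    "patient_id": pid,
                    "component": "avoided_morbidity",
                    "value": morbidity_q,
                },
            ]

        truth_patients[pid] = {
            "true_effect": true_effect,
            "reached_consensus": reached,
            "savings_usd": savings,
            "incurred_usd": incurred,
            "qaly_mortality": mortality_q,
            "qaly_morbidity": morbidity_q,
        }

    cohort = pd.DataFrame(
        cohort_rows,
        columns=["patient_id", "diagnosed", "management_change", "modeled"],
    )
    ledger = pd.DataFrame(
        ledger_rows,
        columns=[
            "item_id", "patient_id", "category", "direction",
            "amount_usd", "source_question_id", "description",
        ],
    )
    responses = pd.DataFrame(
        response_rows,
        columns=["question_id", "patient_id", "panelist_id", "round", "label"],
    )
    qaly_components = pd.DataFrame(
        qaly_rows, columns=["patient_id", "component", "value"]
    )
    sequencing = pd.DataFrame(
        seq_rows, columns=["patient_id", "configuration", "cost_usd"]
    )
    truth = {
        "config": config.model_dump(),
        "patients": truth_patients,
    }
    return SyntheticCohort(
        cohort=cohort,
        ledger=ledger,
        responses=responses,
        qaly_components=qaly_components,
        sequencing=sequencing,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Packaged study fixture
# ---------------------------------------------------------------------------

#: Per-patient net cost effects of the seven consensus-modeled patients
#: (positive = savings, negative = incurred cost), nominal USD.
FIXTURE_NET_EFFECTS: dict[str, int] = {
    "6007": 9795,
    "6147": 74556,
    "6159": 8108,
    "6180": -9856,
    "6193": 134538,
    "6207": -32295,
}

#: Published per-patient QALY components (two-decimal precision).
FIXTURE_QALY_COMPONENTS: dict[str, dict[str, Decimal]] = {
    "6153": {"avoided_mortality": Decimal("0.12")},
    "6207": {
        "avoided_mortality": Decimal("9.08"),
        "avoided_morbidity": Decimal("2.90"),
    },
}

#: Published cohort-level sequencing total (authoritative; the per-trio
#: price below is reference metadata, since 38 x $7,400 != $239,400 —
#: family configurations were mixed and not itemized).
FIXTURE_SEQUENCING_TOTAL = Decimal("239400")
FIXTURE_COST_PER_TRIO = Decimal("7400")

#: Cohort-level split of total savings (not available per patient).
FIXTURE_HOSPITAL_SAVINGS = Decimal("156575")
FIXTURE_PROFESSIONAL_SAVINGS = Decimal("28271")

_MODELED = ["6007", "6052", "6147", "6153", "6159", "6180", "6193", "6207"]
#: Patients with management changes that could not be quantitatively modeled.
_CHANGED_UNMODELABLE = ["6031", "6118", "7002", "6183", "7039"]

_FIXTURE_LEDGER = [
    # (item_id, patient, category, direction, amount, description)
    ("L-6007", "6007", "hospital_day", "avoided", 9795,
     "pulse steroids instead of ICU transfer for midazolam infusion"),
    ("L-6052", "6052", "hospital_day", "avoided", 21000,
     "synthetic placeholder: counterfactual stay reduction; gated out "
     "because the panel did not reach consensus"),
    ("L-6147", "6147", "hospital_day", "avoided", 74556,
     "goals-of-care change avoided a hospitalization, skin biopsy, and "
     "EGD/intestinal biopsies"),
    ("L-6159", "6159", "procedure", "avoided", 8108,
     "avoided renal biopsy"),
    ("L-6180", "6180", "medication", "incurred", 9856,
     "six additional IVIG doses"),
    ("L-6193", "6193", "hospital_day", "avoided", 134538,
     "transition to home NPPV on hospice instead of hospitalization"),
    ("L-6207", "6207", "medication", "incurred", 32295,
     "earlier initiation of prophylactic Factor XIII replacement"),
]

# Synthesized panel response sets consistent with the published per-question
# outcomes: seven questions reach agreement consensus, patient 6052's does
# not (in either round).  Individual panelist scores were not published;
# these are NOT the real responses.
_FIXTURE_RESPONSES: dict[str, dict] = {
    "Q-6007": {"rounds": [["agree"] * 6 + ["strongly_agree"] * 4]},
    "Q-6052": {
        "rounds": [
            ["agree"] * 3 + ["neutral"] * 7,            # mean 3.3
            ["agree"] * 4 + ["neutral"] * 6,            # mean 3.4 -> discarded
        ]
    },
    "Q-6147": {"rounds": [["strongly_agree"] * 5 + ["agree"] * 5]},
    "Q-6153": {"rounds": [["agree"] * 7 + ["strongly_agree"] * 3]},
    # Mean exactly 4.0 with one excluded response: inclusive boundary.
    "Q-6159": {"rounds": [["agree"] * 9 + ["unable_to_comment"]]},
    "Q-6180": {"rounds": [["agree"] * 8 + ["strongly_agree"] * 2]},
    # Consensus reached only in round 2.
    "Q-6193": {
        "rounds": [
            ["agree"] * 8 + ["neutral"] * 2,            # mean 3.8
            ["agree"] * 9 + ["strongly_agree"],         # mean 4.1
        ]
    },
    # Five-member hematology panel for the Factor XIII question.
    "Q-6207": {
        "rounds": [["strongly_agree"] * 3 + ["agree"] * 2],
        "panel_prefix": "H",
    },
}


def factor_xiii_trees() -> tuple[OutcomeTree, OutcomeTree]:
    """Illustrative with/without outcome trees for the Factor XIII case.

    Built from the published risk inputs (12% mortality on a second CNS
    bleed; 72.6% neurologic complications among survivors); the QOL weights
    and durations are synthetic placeholders, since the parameterization
    that produced the published 9.08/2.9 QALY components was not released.
    The trees are illustrative only and their outputs are not asserted
    against the published components.
    """
    without = OutcomeNode(
        label="no_prophylaxis_second_cns_bleed",
        branches=[
            Branch(
                probability=0.12,
                child=OutcomeLeaf(label="death", qol_weight=0.0, duration_years=0.0),
            ),
            Branch(
                probability=0.88,
                child=OutcomeNode(
                    label="survives_bleed",
                    branches=[
                        Branch(
                            probability=0.726,
                            child=OutcomeLeaf(
                                label="neurologic_complications",
                                qol_weight=0.5,
                                duration_years=70.0,
                            ),
                        ),
                        Branch(
                            probability=0.274,
                            child=OutcomeLeaf(
                                label="intact",
                                qol_weight=1.0,
                                duration_years=70.0,
                            ),
                        ),
                    ],
                ),
            ),
        ],
    )
    with_tx = OutcomeLeaf(label="prophylaxis_intact", qol_weight=1.0, duration_years=70.0)
    return with_tx, without


def paper_fixture() -> SyntheticCohort:
    """The packaged 38-proband study cohort.

    17 probands diagnosed (45%), 13 with management changes (76% of
    diagnosed), 8 modeled by Delphi panels, 7 reaching consensus.  Cost and
    QALY values are the published per-patient figures; panel responses are
    synthesized to match the published consensus outcomes (the individual
    scores were not released).  Probands outside the modeled eight carry
    synthetic identifiers.
    """
    diagnosed_no_change = [f"DX{i:02d}" for i in range(1, 5)]       # 4 synthetic ids
    undiagnosed = [f"UD{i:02d}" for i in range(1, 22)]              # 21 synthetic ids
    cohort_rows = []
    for pid in _MODELED:
        cohort_rows.append((pid, True, True, True))
    for pid in _CHANGED_UNMODELABLE:
        cohort_rows.append((pid, True, True, False))
    for pid in diagnosed_no_change:
        cohort_rows.append((pid, True, False, False))
    for pid in undiagnosed:
        cohort_rows.append((pid, False, False, False))
    cohort = pd.DataFrame(
        cohort_rows,
        columns=["patient_id", "diagnosed", "management_change", "modeled"],
    )

    ledger = pd.DataFrame(
        [
            {
                "item_id": iid,
                "patient_id": pid,
                "category": cat,
                "direction": direction,
                "amount_usd": amount,
                "source_question_id": f"Q-{pid}",
                "description": desc,
            }
            for iid, pid, cat, direction, amount, desc in _FIXTURE_LEDGER
        ]
    )

    response_rows: list[dict] = []
    for qid, spec_ in _FIXTURE_RESPONSES.items():
        pid = qid.split("-", 1)[1]
        prefix = spec_.get("panel_prefix", "P")
        for rnd, labels in enumerate(spec_["rounds"], start=1):
            response_rows += _question_rows(qid, pid, rnd, labels, prefix)
    responses = pd.DataFrame(
        response_rows,
        columns=["question_id", "patient_id", "panelist_id", "round", "label"],
    )

    qaly_components = pd.DataFrame(
        [
            {"patient_id": pid, "component": comp, "value": str(val)}
            for pid, comps in FIXTURE_QALY_COMPONENTS.items()
            for comp, val in comps.items()
        ],
        columns=["patient_id", "component", "value"],
    )

    # The published total is authoritative; allocate it uniformly across the
    # 38 proband families (synthetic split — the real per-family breakdown
    # was not itemized).  239,400 / 38 = 6,300 exactly.
    per_family = FIXTURE_SEQUENCING_TOTAL / 38
    sequencing = pd.DataFrame(
        [
            {
                "patient_id": pid,
                "configuration": "trio",
                "cost_usd": float(per_family),
            }
            for pid in cohort["patient_id"]
        ],
        columns=["patient_id", "configuration", "cost_usd"],
    )

    truth = {
        "published": {
            "net_effects_usd": dict(FIXTURE_NET_EFFECTS),
            "total_savings_usd": 184846,
            "sequencing_total_usd": int(FIXTURE_SEQUENCING_TOTAL),
            "net_cost_usd": 54554,
            "total_qalys": "12.1",
            "icer_usd_per_qaly": 4509,
            "yield_diagnosed_pct": 45,
            "yield_management_change_pct": 76,
            "hospital_savings_usd": int(FIXTURE_HOSPITAL_SAVINGS),
            "professional_savings_usd": int(FIXTURE_PROFESSIONAL_SAVINGS),
            "reference_cost_per_trio_usd": int(FIXTURE_COST_PER_TRIO),
        },
        "risk_inputs": {
            # Recorded inputs for the Factor XIII case (metadata only; the
            # parameterization behind 9.08/2.9 was not released).
            "p_death_second_cns_bleed": 0.12,
            "p_neurologic_complication_survivors": 0.726,
            "mean_age_of_death_years": 1.5,
            "sd_age_of_death_years": 2.0,
        },
        "synthetic_elements": [
            "panel responses (consistent with published statuses only)",
            "patient 6052 ledger amount (gated out of totals)",
            "uniform per-family sequencing allocation",
            "identifiers DXnn/UDnn for probands outside the modeled eight",
        ],
    }
    return SyntheticCohort(
        cohort=cohort,
        ledger=ledger,
        responses=responses,
        qaly_components=qaly_components,
        sequencing=sequencing,
        truth=truth,
    )
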