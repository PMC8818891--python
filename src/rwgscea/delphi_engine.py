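"""Modified-Delphi consensus scoring for counterfactual care trajectories.

A panel of clinicians rates counterfactual statements ("absent the genomic
diagnosis, this patient would have ...") on a five-point Likert scale over at
most two rounds.  Responses are encoded 1-5 (strongly disagree .. strongly
agree); "unable to comment" responses are excluded from the mean.  A question
reaches consensus when the round mean is >= 4 (agreement) or <= 2
(disagreement), both bounds inclusive.  Questions that fail to reach consensus
in round one are returned to the panel with the group mean attached; questions
still unresolved after round two are discarded and contribute nothing to
downstream cost or QALY modeling.

The per-question final status produced here is the gate used by
:mod:`rwgscea.cost_ledger` and :mod:`rwgscea.cea_pipeline` to decide which
counterfactual line items enter the analysis.
"""

from __future__ import annotations

import enum
import logging
import re
from typing import Iterable, Literal, Sequence

import pandas as pd
from pydantic import BaseModel, Field, model_validator

logger = logging.getLogger(__name__)

#: Inclusive mean threshold above which a question is consensus agreement.
AGREE_THRESHOLD = 4.0
#: Inclusive mean threshold below which a question is consensus disagreement.
DISAGREE_THRESHOLD = 2.0
#: Absolute tolerance guarding the inclusive comparisons against binary
#: floating-point artifacts (e.g. a mean stored as 3.9999999999999996).
THRESHOLD_TOL = 1e-9

#: Maximum number of survey rounds; the stop criterion is completion of the
#: second round, after which unresolved questions are discarded.
MAX_ROUNDS = 2

LIKERT_SCORES: dict[str, int] = {
    "strongly_disagree": 1,
    "disagree": 2,
    "neutral": 3,
    "agree": 4,
    "strongly_agree": 5,
}

SCORE_LABELS: dict[int, str] = {v: k for k, v in LIKERT_SCORES.items()}

UNABLE_TO_COMMENT = "unable_to_comment"


class _Excluded:
    """Sentinel marking a response excluded from scoring (not a number)."""

    __slots__ = ()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "EXCLUDED"


EXCLUDED = _Excluded()

LikertLabel = Literal[
    "strongly_disagree",
    "disagree",
    "neutral",
    "agree",
    "strongly_agree",
    "unable_to_comment",
]


class ConsensusStatus(str, enum.Enum):
    """Final adjudication of a Delphi question."""

    CONSENSUS_AGREE = "consensus_agree"
    CONSENSUS_DISAGREE = "consensus_disagree"
    NO_CONSENSUS_DISCARDED = "no_consensus_discarded"
    PENDING = "pending"

    @property
    def is_consensus(self) -> bool:
        return self in (
            ConsensusStatus.CONSENSUS_AGREE,
            ConsensusStatus.CONSENSUS_DISAGREE,
        )


class RoundOutcome(str, enum.Enum):
    """Consensus classification of a single round's mean score."""

    CONSENSUS_AGREE = "consensus_agree"
    CONSENSUS_DISAGREE = "consensus_disagree"
    NONE = "none"


def normalize_label(label: str) -> str:
    """Canonicalize a Likert label: case-insensitive, spaces and underscores
    interchangeable, surrounding whitespace ignored."""
    return re.sub(r"[\s_]+", "_", str(label).strip().lower())


def encode_likert(label: str) -> int | _Excluded:
    """Encode a Likert label to its numeric score (1-5).

    ``unable_to_comment`` returns the :data:`EXCLUDED` sentinel rather than a
    number, so it can never be summed by accident.

    Raises
    ------
    ValueError
        If the label is not in the closed response vocabulary.
    """
    canonical = normalize_label(label)
    if canonical == UNABLE_TO_COMMENT:
        return EXCLUDED
    try:
        return LIKERT_SCORES[canonical]
    except KeyError:
        raise ValueError(
            f"unknown Likert label {label!r}; expected one of "
            f"{sorted(LIKERT_SCORES) + [UNABLE_TO_COMMENT]}"
        ) from None


class LikertResponse(BaseModel):
    """One panelist's response to one question in one round."""

    panelist_id: str
    round_index: int = Field(ge=1, le=MAX_ROUNDS)
    label: LikertLabel

    @model_validator(mode="before")
    @classmethod
    def _canonicalize(cls, data):
        if isinstance(data, dict) and "label" in data:
            data = dict(data)
            data["label"] = normalize_label(data["label"])
        return data

    @property
    def score(self) -> int | _Excluded:
        return encode_likert(self.label)


class RoundScore(BaseModel):
    """Summary of one scored round: the mean over valid responses and counts.

    ``mean_score`` is ``None`` (undefined) when every response was
    ``unable_to_comment``; such a round cannot reach consensus.
    """

    mean_score: float | None = Field(default=None, ge=1.0, le=5.0)
    n_valid: int = Field(ge=0)
    n_excluded: int = Field(ge=0)

    @model_validator(mode="after")
    def _mean_defined_iff_valid(self) -> "RoundScore":
        if (self.mean_score is None) != (self.n_valid == 0):
            raise ValueError("mean_score must be defined iff n_valid >= 1")
        return self


def score_round(responses: Iterable[LikertResponse | str]) -> RoundScore:
    """Compute the mean consensus score for one question-round.

    Accepts :class:`LikertResponse` objects or bare labels.  ``unable to
    comment`` responses are excluded from the mean but counted.  All
    responses must come from the same round, and no panelist may respond
    twice.
    """
    labels: list[str] = []
    rounds: set[int] = set()
    panelists: list[str] = []
    for r in responses:
        if isinstance(r, LikertResponse):
            labels.append(r.label)
            rounds.add(r.round_index)
            panelists.append(r.panelist_id)
        else:
            labels.append(normalize_label(r))
    if len(rounds) > 1:
        raise ValueError(f"responses span multiple rounds: {sorted(rounds)}")
    if len(panelists) != len(set(panelists)):
        dupes = sorted({p for p in panelists if panelists.count(p) > 1})
        raise ValueError(f"panelist(s) responded more than once: {dupes}")

    scores = [encode_likert(lab) for lab in labels]
    valid = [s for s in scores if not isinstance(s, _Excluded)]
    n_excluded = len(scores) - len(valid)
    if not valid:
        logger.warning(
            "round has no valid responses (%d excluded); "
            "question cannot reach consensus this round",
            n_excluded,
        )
        return RoundScore(mean_score=None, n_valid=0, n_excluded=n_excluded)
    return RoundScore(
        mean_score=sum(valid) / len(valid),
        n_valid=len(valid),
        n_excluded=n_excluded,
    )


def classify_consensus(score: RoundScore) -> RoundOutcome:
    """Classify a round mean against the inclusive 4.0 / 2.0 thresholds.

    An undefined mean (no valid responses) classifies as no consensus.
    """
    m = score.mean_score
    if m is None:
        return RoundOutcome.NONE
    if m >= AGREE_THRESHOLD - THRESHOLD_TOL:
        return RoundOutcome.CONSENSUS_AGREE
    if m <= DISAGREE_THRESHOLD + THRESHOLD_TOL:
        return RoundOutcome.CONSENSUS_DISAGREE
    return RoundOutcome.NONE


class DelphiQuestion(BaseModel):
    """A counterfactual statement with its per-round responses.

    ``rounds`` holds at most two ordered response sets.  ``final_status`` is
    ``pending`` until :func:`run_question` adjudicates it.
    """

    question_id: str
    patient_id: str
    statement: str = ""
    rounds: list[list[LikertResponse]] = Field(default_factory=list)
    final_status: ConsensusStatus = ConsensusStatus.PENDING
    round_scores: list[RoundScore] = Field(default_factory=list)

    @model_validator(mode="after")
    def _at_most_two_rounds(self) -> "DelphiQuestion":
        if len(self.rounds) > MAX_ROUNDS:
            raise ValueError(
                f"question {self.question_id!r} has {len(self.rounds)} rounds; "
                f"the stop criterion is completion of {MAX_ROUNDS} rounds"
            )
        return self


def run_question(question: DelphiQuestion) -> DelphiQuestion:
    """Adjudicate a question through its (at most two) rounds.

    Consensus in round one finalizes immediately; any supplied round-two
    responses are then ignored with a warning.  Otherwise round two decides,
    and failure to reach consensus there discards the question.  A question
    whose round one did not reach consensus and which has no round two is left
    ``pending`` and flagged incomplete.

    Returns a new :class:`DelphiQuestion` carrying ``final_status`` and the
    per-round :class:`RoundScore` objects; the input is not mutated.
    """
    if not question.rounds or not question.rounds[0]:
        raise ValueError(
            f"question {question.question_id!r}: round 1 responses are required"
        )
    scores: list[RoundScore] = []
    r1 = score_round(question.rounds[0])
    scores.append(r1)
    outcome = classify_consensus(r1)
    if outcome is not RoundOutcome.NONE:
        if len(question.rounds) > 1 and question.rounds[1]:
            logger.warning(
                "question %s reached consensus in round 1; ignoring the "
                "supplied round-2 responses",
                question.question_id,
            )
        status = ConsensusStatus(outcome.value)
    elif len(question.rounds) < 2 or not question.rounds[1]:
        logger.warning(
            "question %s did not reach consensus in round 1 and has no "
            "round 2; status left pending (incomplete)",
            question.question_id,
        )
        status = ConsensusStatus.PENDING
    else:
        r2 = score_round(question.rounds[1])
        scores.append(r2)
        outcome2 = classify_consensus(r2)
        if outcome2 is RoundOutcome.NONE:
            status = ConsensusStatus.NO_CONSENSUS_DISCARDED
        else:
            status = ConsensusStatus(outcome2.value)
    return question.model_copy(
        update={"final_status": status, "round_scores": scores}
    )


def questions_from_table(responses: pd.DataFrame) -> list[DelphiQuestion]:
    """Build questions from a long-format response table.

    Expected columns: ``question_id, patient_id, panelist_id, round, label``.
    Label matching is case-insensitive with spaces and underscores
    interchangeable.
    """
    required = {"question_id", "patient_id", "panelist_id", "round", "label"}
    missing = required - set(responses.columns)
    if missing:
        raise ValueError(f"response table missing column(s): {sorted(missing)}")
    questions: list[DelphiQuestion] = []
    for qid, group in responses.groupby("question_id", sort=True):
        patients = group["patient_id"].unique()
        if len(patients) > 1:
            raise ValueError(
                f"question {qid!r} maps to multiple patients: {list(patients)}"
            )
        rounds: list[list[LikertResponse]] = []
        for rnd in sorted(group["round"].unique()):
            sub = group[group["round"] == rnd]
            rounds.append(
                [
                    LikertResponse(
                        panelist_id=str(row.panelist_id),
                        round_index=int(rnd),
                        label=str(row.label),
                    )
                    for row in sub.itertuples()
                ]
            )
        questions.append(
            DelphiQuestion(
                question_id=str(qid),
                patient_id=str(patients[0]),
                rounds=rounds,
            )
        )
    return questions


def score_response_table(responses: pd.DataFrame) -> pd.DataFrame:
    """Score every question in a long-format response table.

    Returns one row per question-round with columns
    ``question_id, patient_id, round, mean_score, n_valid, n_excluded,
    panel_size, status`` where ``status`` is the question's final status
    (repeated on each of its rounds).
    """
    rows = []
    for q in questions_from_table(responses):
        done = run_question(q)
        for i, rs in enumerate(done.round_scores, start=1):
            rows.append(
                {
                    "question_id": done.question_id,
                    "patient_id": done.patient_id,
                    "round": i,
                    "mean_score": rs.mean_score,
                    "n_valid": rs.n_valid,
                    "n_excluded": rs.n_excluded,
                    "panel_size": rs.n_valid + rs.n_excluded,
                    "status": done.final_status.value,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "question_id",
            "patient_id",
            "round",
            "mean_score",
            "n_valid",
            "n_excluded",
            "panel_size",
            "status",
        ],
    )


def consensus_map(
    questions: Sequence[DelphiQuestion],
) -> dict[str, ConsensusStatus]:
    """Map ``question_id`` to final status for a set of adjudicated questions."""
    out: dict[str, ConsensusStatus] = {}
    for q in questions:
        if q.question_id in out:
            raise ValueError(f"duplicate question_id {q.question_id!r}")
        out[q.question_id] = q.final_status
    return out


def format_mean_for_panel(mean_score: float | None) -> str:
    """Format a round mean for display to round-2 panelists (two decimals).

    Full precision is retained internally; only the display is rounded.
    """
    return "n/a" if mean_score is None else f"{mean_score:.2f}"
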