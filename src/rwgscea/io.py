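"""Readers for the delimited-text tables the pipeline consumes.

All inputs are headered CSV; identifiers are read as strings so numeric-
looking patient ids survive round-trips.  YAML is used for the run
configuration and for outcome-tree documents.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .cea_pipeline import (
    CeaResult,
    CohortRecord,
    RunConfig,
    SequencingCostEntry,
    run_analysis,
)
from .cost_ledger import CostLineItem
from .delphi_engine import questions_from_table
from .qaly_model import OutcomeTree, tree_from_dict

_ID_COLUMNS = (
    "patient_id",
    "item_id",
    "question_id",
    "panelist_id",
    "source_question_id",
)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a headered CSV, keeping identifier columns as strings."""
    df = pd.read_csv(path, keep_default_na=False)
    for col in _ID_COLUMNS:
        if col in df.columns:
            df[col] = df[col].astype(str)
    return df


def _to_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    return str(v).strip().lower() in ("true", "1", "yes", "y")


def cohort_from_frame(df: pd.DataFrame) -> list[CohortRecord]:
    return [
        CohortRecord(
            patient_id=str(r.patient_id),
            diagnosed=_to_bool(r.diagnosed),
            management_change=_to_bool(r.management_change),
            modeled=_to_bool(r.modeled),
        )
        for r in df.itertuples()
    ]


def items_from_frame(df: pd.DataFrame) -> list[CostLineItem]:
    items = []
    for r in df.itertuples():
        qid = getattr(r, "source_question_id", "") or None
        items.append(
            CostLineItem(
                item_id=str(r.item_id),
                patient_id=str(r.patient_id),
                category=str(r.category),
                direction=str(r.direction),
                amount_usd=r.amount_usd,
                source_question_id=qid,
                description=str(getattr(r, "description", "")),
            )
        )
    return items


def sequencing_from_frame(df: pd.DataFrame) -> list[SequencingCostEntry]:
    return [
        SequencingCostEntry(
            patient_id=str(r.patient_id),
            configuration=str(getattr(r, "configuration", "other")),
            cost_usd=r.cost_usd,
        )
        for r in df.itertuples()
    ]


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)


def load_tree(path: str | Path) -> OutcomeTree:
    with open(path) as fh:
        return tree_from_dict(yaml.safe_load(fh))


def run_from_frames(
    cohort: pd.DataFrame,
    ledger: pd.DataFrame,
    responses: pd.DataFrame,
    qaly_components: pd.DataFrame,
    sequencing: pd.DataFrame,
    config: RunConfig | None = None,
) -> tuple[CeaResult, dict]:
    """Run the full analysis directly from the five input tables."""
    from . import delphi_engine

    questions = [
        delphi_engine.run_question(q)
        for q in questions_from_table(responses)
    ]
    return run_analysis(
        cohort=cohort_from_frame(cohort),
        items=items_from_frame(ledger),
        questions=questions,
        qaly_components=qaly_components,
        sequencing_entries=sequencing_from_frame(sequencing),
        config=config,
    )
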