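"""Net cost, ICER, value classification, yields, and the end-to-end run."""

from decimal import Decimal

import pytest

from rwgscea import cost_ledger, qaly_model
from rwgscea.cea_pipeline import (
    CohortRecord,
    IcerFlag,
    RunConfig,
    SequencingCostEntry,
    ValueClass,
    WtpThresholds,
    classify_value,
    cohort_summary,
    icer,
    net_cost,
    report_to_json,
    sequencing_total,
    summary_markdown,
)
from rwgscea.delphi_engine import questions_from_table, run_question
from rwgscea.io import items_from_frame, run_from_frames


def entry(pid, cost=7400, cfg="trio"):
    return SequencingCostEntry(patient_id=pid, configuration=cfg, cost_usd=cost)


class TestSequencingTotal:
    def test_single_trio_and_empty(self):
        assert sequencing_total([entry("a")]) == Decimal("7400.00")
        assert sequencing_total([]) == Decimal("0.00")

    def test_duplicate_proband_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            sequencing_total([entry("a"), entry("a")])


class TestNetCost:
    @pytest.mark.parametrize(
        "seq,savings,expected",
        [
            (239400, 184846, Decimal("54554.00")),
            (1000, 1000, Decimal("0.00")),
            (100000, 150000, Decimal("-50000.00")),
        ],
    )
    def test_sequencing_minus_savings(self, seq, savings, expected):
        assert net_cost(seq, savings) == expected


class TestIcer:
    def test_published_ratio_rounds_half_away_from_zero(self):
        # 54554 / 12.1 = 4508.595... -> 4509
        assert icer(Decimal("54554"), Decimal("12.1")) == Decimal("4509")

    def test_division_oracle(self):
        assert icer(10000, 4) == Decimal("2500")

    def test_negative_net_cost_is_dominant(self):
        assert icer(-10000, 5) is IcerFlag.DOMINANT

    def test_positive_cost_without_qalys_has_no_finite_icer(self):
        assert icer(10000, 0) is IcerFlag.NO_QALY_GAIN

    def test_negative_qalys_rejected(self):
        with pytest.raises(ValueError):
            icer(100, -1)

    def test_rounding_identity(self):
        """icer(net_cost(s, v), q) x q recovers s - v within 0.5*q dollars."""
        cases = [(239400, 184846, Decimal("12.1")), (50000, 10000, Decimal("3.7"))]
        for s, v, q in cases:
            nc = net_cost(s, v)
            ratio = icer(nc, q)
            assert abs(ratio * q - nc) <= Decimal("0.5") * q


class TestValueClassification:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (Decimal("4509"), ValueClass.HIGH_VALUE_CONSERVATIVE),
            (Decimal("19999"), ValueClass.HIGH_VALUE_CONSERVATIVE),
            (Decimal("20000"), ValueClass.HIGH_VALUE),   # strict < conservative
            (Decimal("49999"), ValueClass.HIGH_VALUE),
            (Decimal("50000"), ValueClass.BORDERLINE),   # strict < standard
            (Decimal("100000"), ValueClass.BORDERLINE),  # inclusive upper
            (Decimal("250000"), ValueClass.LOW_VALUE),
            (IcerFlag.DOMINANT, ValueClass.DOMINANT),
            (IcerFlag.NO_QALY_GAIN, ValueClass.LOW_VALUE),
        ],
    )
    def test_default_brackets(self, value, expected):
        assert classify_value(value) is expected

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            WtpThresholds(
                conservative_usd_per_qaly=50000,
                standard_usd_per_qaly=20000,
                upper_usd_per_qaly=100000,
            )


class TestCohortSummary:
    def make_cohort(self, n, n_dx, n_change):
        recs = []
        for i in range(n):
            dx = i < n_dx
            ch = i < n_change
            recs.append(
                CohortRecord(
                    patient_id=f"p{i}", diagnosed=dx, management_change=ch
                )
            )
        return recs

    @pytest.mark.parametrize(
        "n,n_dx,n_change,pct_dx,pct_change",
        [(38, 17, 13, 45, 76), (10, 10, 10, 100, 100), (8, 3, 1, 38, 33)],
    )
    def test_nearest_integer_yields(self, n, n_dx, n_change, pct_dx, pct_change):
        s = cohort_summary(self.make_cohort(n, n_dx, n_change))
        assert s.yield_diagnosed_pct == pct_dx
        assert s.yield_management_change_pct == pct_change

    def test_inconsistent_flags_rejected(self):
        with pytest.raises(ValueError, match="without diagnosis"):
            CohortRecord(patient_id="x", diagnosed=False, management_change=True)
        with pytest.raises(ValueError, match="without management change"):
            CohortRecord(
                patient_id="x",
                diagnosed=True,
                management_change=False,
                modeled=True,
            )

    def test_duplicate_patient_rejected(self):
        recs = self.make_cohort(2, 0, 0)
        recs[1] = recs[0]
        with pytest.raises(ValueError, match="duplicate"):
            cohort_summary(recs)


class TestEndToEnd:
    def test_study_cohort_headline_numbers(self, study_result):
        result, _ = study_result
        assert result.total_savings_usd == Decimal("184846.00")
        assert result.sequencing_total_usd == Decimal("239400.00")
        assert result.net_cost_usd == Decimal("54554.00")
        assert result.total_qalys == Decimal("12.1")
        assert result.icer_usd_per_qaly == Decimal("4509")
        assert result.value_class is ValueClass.HIGH_VALUE_CONSERVATIVE
        assert result.yield_diagnosed_pct == 45
        assert result.yield_management_change_pct == 76

    def test_report_is_byte_identical_across_runs(self, study_fixture):
        fx = study_fixture
        runs = [
            report_to_json(
                run_from_frames(
                    fx.cohort, fx.ledger, fx.responses,
                    fx.qaly_components, fx.sequencing,
                )[1]
            )
            for _ in range(2)
        ]
        assert runs[0] == runs[1]

    def test_gating_idempotence_removing_discarded_items(self, study_fixture):
        """Dropping the no-consensus patient's items changes nothing."""
        fx = study_fixture
        pruned = fx.ledger[fx.ledger["patient_id"] != "6052"]
        full = run_from_frames(
            fx.cohort, fx.ledger, fx.responses, fx.qaly_components, fx.sequencing
        )[0]
        without = run_from_frames(
            fx.cohort, pruned, fx.responses, fx.qaly_components, fx.sequencing
        )[0]
        assert full.total_savings_usd == without.total_savings_usd
        assert full.net_cost_usd == without.net_cost_usd
        assert full.icer_usd_per_qaly == without.icer_usd_per_qaly

    def test_pipeline_totals_equal_isolated_module_totals(self, study_fixture):
        """No hidden state: stage-by-stage recomputation matches the run."""
        fx = study_fixture
        result, _ = run_from_frames(
            fx.cohort, fx.ledger, fx.responses, fx.qaly_components, fx.sequencing
        )
        questions = [
            run_question(q) for q in questions_from_table(fx.responses)
        ]
        consensus = {q.question_id: q.final_status for q in questions}
        effects = cost_ledger.ledger_net_effects(
            items_from_frame(fx.ledger), consensus
        )
        gated = [
            e
            for e in effects
            if any(
                q.patient_id == e.patient_id and q.final_status.is_consensus
                for q in questions
            )
        ]
        totals = cost_ledger.cohort_cost_totals(gated)
        assert totals.total_net_usd == result.total_savings_usd
        qaly_results = qaly_model.results_from_components_table(
            fx.qaly_components
        )
        assert qaly_model.cohort_qaly_total(qaly_results) == result.total_qalys

    def test_zero_modeled_patients_degenerate_cohort(self):
        import pandas as pd

        cohort = pd.DataFrame(
            [{"patient_id": "a", "diagnosed": False,
              "management_change": False, "modeled": False}]
        )
        empty_ledger = pd.DataFrame(
            columns=["item_id", "patient_id", "category", "direction",
                     "amount_usd", "source_question_id", "description"]
        )
        empty_q = pd.DataFrame(
            columns=["question_id", "patient_id", "panelist_id", "round", "label"]
        )
        empty_qaly = pd.DataFrame(columns=["patient_id", "component", "value"])
        seq = pd.DataFrame(
            [{"patient_id": "a", "configuration": "trio", "cost_usd": 7400}]
        )
        result, _ = run_from_frames(cohort, empty_ledger, empty_q, empty_qaly, seq)
        assert result.total_savings_usd == Decimal("0.00")
        assert result.net_cost_usd == result.sequencing_total_usd
        assert result.icer_usd_per_qaly is None
        assert result.icer_flag is IcerFlag.NO_QALY_GAIN

    def test_split_consistency_note_in_report(self, study_fixture):
        fx = study_fixture
        cfg = RunConfig(
            hospital_savings_usd=156575,
            professional_savings_usd=28271,
            reference_cost_per_trio_usd=7400,
        )
        _, report = run_from_frames(
            fx.cohort, fx.ledger, fx.responses,
            fx.qaly_components, fx.sequencing, cfg,
        )
        notes = {n["check"]: n for n in report["reconciliation_notes"]}
        assert notes["hospital_plus_professional_split"]["consistent"] is True
        # 38 x 7,400 = 281,200 != 239,400: mixed family configurations
        assert notes["per_family_price_reconciliation"]["consistent"] is False

    def test_summary_markdown_lists_all_modeled_patients(self, study_result):
        result, report = study_result
        text = summary_markdown(result, report)
        for pid in ("6007", "6147", "6153", "6159", "6180", "6193", "6207"):
            assert pid in text
        assert "$184,846" in text
        assert "$4,509 per QALY" in text
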