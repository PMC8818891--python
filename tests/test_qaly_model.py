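"""QALY leaf/tree evaluation, discounting, gains, and exact component sums."""

import math
from decimal import Decimal

import numpy as np
import pytest

from rwgscea.qaly_model import (
    Branch,
    LifeExpectancyTable,
    OutcomeLeaf,
    OutcomeNode,
    cohort_qaly_total,
    discount_factor_years,
    enumerate_paths,
    expected_qalys,
    leaf_qaly,
    patient_qaly_total,
    qaly_gain,
)


def random_tree(rng, depth=0, max_depth=3):
    """Random valid outcome tree: depth <= 4, modest branching."""
    if depth >= max_depth or rng.random() < 0.35:
        return OutcomeLeaf(
            qol_weight=float(rng.uniform(0, 1)),
            duration_years=float(rng.uniform(0, 80)),
        )
    k = int(rng.integers(2, 4))
    probs = rng.dirichlet(np.ones(k))
    probs = probs / probs.sum()
    return OutcomeNode(
        branches=[
            Branch(
                probability=float(p),
                child=random_tree(rng, depth + 1, max_depth),
            )
            for p in probs
        ]
    )


def recursive_expectation(tree, r=0.0):
    """Independent oracle: direct recursion E = sum_i p_i * E(child_i)."""
    if isinstance(tree, OutcomeLeaf):
        return leaf_qaly(tree, r)
    return sum(
        b.probability * recursive_expectation(b.child, r) for b in tree.branches
    )


class TestLeafQaly:
    @pytest.mark.parametrize(
        "qol,years,expected",
        [(1.0, 10, 10.0), (0.0, 50, 0.0), (0.5, 70, 35.0)],
    )
    def test_undiscounted_product(self, qol, years, expected):
        leaf = OutcomeLeaf(qol_weight=qol, duration_years=years)
        assert leaf_qaly(leaf, 0.0) == pytest.approx(expected)

    def test_negative_discount_rate_rejected(self):
        leaf = OutcomeLeaf(qol_weight=1.0, duration_years=10)
        with pytest.raises(ValueError):
            leaf_qaly(leaf, -0.01)

    def test_discounting_shrinks_value_and_prorates_fraction(self):
        r = 0.03
        # annuity closed form for whole years
        assert discount_factor_years(10, r) == pytest.approx(
            sum((1 + r) ** -t for t in range(1, 11))
        )
        # 2.5 years: two whole years plus half of year three's factor
        assert discount_factor_years(2.5, r) == pytest.approx(
            (1 + r) ** -1 + (1 + r) ** -2 + 0.5 * (1 + r) ** -3
        )
        assert discount_factor_years(10, r) < 10

    def test_zero_rate_limit_is_continuous(self):
        for years in (7.0, 2.5, 0.3):
            assert discount_factor_years(years, 1e-10) == pytest.approx(
                years, rel=1e-6
            )


class TestExpectedQalys:
    def test_degenerate_single_leaf(self):
        leaf = OutcomeLeaf(qol_weight=1.0, duration_years=10)
        assert expected_qalys(leaf) == pytest.approx(10.0)

    def test_two_level_risk_weighted_tree(self):
        # 12% death; among the 88% survivors, 72.6% impaired at QOL 0.5 for
        # 70 years, 27.4% intact:  0.88 * (0.726*35 + 0.274*70) = 39.2392
        tree = OutcomeNode(
            branches=[
                Branch(
                    probability=0.12,
                    child=OutcomeLeaf(qol_weight=0.0, duration_years=0.0),
                ),
                Branch(
                    probability=0.88,
                    child=OutcomeNode(
                        branches=[
                            Branch(
                                probability=0.726,
                                child=OutcomeLeaf(
                                    qol_weight=0.5, duration_years=70
                                ),
                            ),
                            Branch(
                                probability=0.274,
                                child=OutcomeLeaf(
                                    qol_weight=1.0, duration_years=70
                                ),
                            ),
                        ]
                    ),
                ),
            ]
        )
        assert expected_qalys(tree) == pytest.approx(39.2392, abs=1e-9)

    def test_invalid_probabilities_name_the_node(self):
        bad = OutcomeNode(
            label="survivors",
            branches=[
                Branch(probability=0.5, child=OutcomeLeaf(qol_weight=1, duration_years=1)),
                Branch(probability=0.4, child=OutcomeLeaf(qol_weight=1, duration_years=1)),
            ],
        )
        with pytest.raises(ValueError, match="survivors"):
            expected_qalys(bad)

    def test_matches_independent_recursion_on_random_trees(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            tree = random_tree(rng)
            r = float(rng.choice([0.0, 0.015, 0.03]))
            assert expected_qalys(tree, r) == pytest.approx(
                recursive_expectation(tree, r), abs=1e-9
            )

    def test_bounded_by_max_duration(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            tree = random_tree(rng)
            max_dur = max(d for _, _, d in _leaves(tree))
            assert expected_qalys(tree) <= max_dur + 1e-9

    def test_raising_a_leaf_qol_never_lowers_the_expectation(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            tree = random_tree(rng)
            before = expected_qalys(tree)
            bumped = _bump_first_leaf(tree)
            assert expected_qalys(bumped) >= before - 1e-12

    def test_path_enumeration_probabilities_sum_to_one(self):
        rng = np.random.default_rng(11)
        tree = random_tree(rng)
        paths = enumerate_paths(tree)
        assert sum(p for _, p, _ in paths) == pytest.approx(1.0, abs=1e-9)


def _leaves(tree):
    if isinstance(tree, OutcomeLeaf):
        yield (tree, tree.qol_weight, tree.duration_years)
        return
    for b in tree.branches:
        yield from _leaves(b.child)


def _bump_first_leaf(tree):
    if isinstance(tree, OutcomeLeaf):
        return tree.model_copy(
            update={"qol_weight": min(1.0, tree.qol_weight + 0.1)}
        )
    new_branches = list(tree.branches)
    new_branches[0] = Branch(
        probability=new_branches[0].probability,
        child=_bump_first_leaf(new_branches[0].child),
    )
    return OutcomeNode(label=tree.label, branches=new_branches)


class TestQalyGain:
    def test_identical_trees_have_zero_gain(self):
        rng = np.random.default_rng(5)
        tree = random_tree(rng)
        assert qaly_gain(tree, tree) == pytest.approx(0.0)

    def test_certain_survival_vs_certain_death(self):
        alive = OutcomeLeaf(qol_weight=1.0, duration_years=20)
        dead = OutcomeLeaf(qol_weight=0.0, duration_years=0)
        assert qaly_gain(alive, dead) == pytest.approx(20.0)

    def test_gain_equals_removed_death_branch_loss(self):
        survive = OutcomeLeaf(qol_weight=0.9, duration_years=60)
        without = OutcomeNode(
            branches=[
                Branch(probability=0.12, child=OutcomeLeaf(qol_weight=0, duration_years=0)),
                Branch(probability=0.88, child=survive),
            ]
        )
        gain = qaly_gain(survive, without)
        assert gain == pytest.approx(0.12 * leaf_qaly(survive), abs=1e-9)

    def test_antisymmetry(self):
        rng = np.random.default_rng(17)
        a, b = random_tree(rng), random_tree(rng)
        assert qaly_gain(a, b) == pytest.approx(-qaly_gain(b, a), abs=1e-12)


class TestComponentSums:
    def test_published_factor_xiii_components_sum_exactly(self):
        result = patient_qaly_total(
            "6207", {"mortality": "9.08", "morbidity": "2.90"}
        )
        assert result.total_qalys == Decimal("11.98")

    def test_empty_and_singleton_components(self):
        assert patient_qaly_total("x", {}).total_qalys == Decimal("0")
        assert patient_qaly_total("6153", {"a": "0.12"}).total_qalys == Decimal(
            "0.12"
        )

    def test_non_finite_component_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            patient_qaly_total("x", {"a": float("nan")})

    def test_cohort_total_is_exact_decimal_sum(self):
        results = [
            patient_qaly_total("6153", {"a": "0.12"}),
            patient_qaly_total("6207", {"m": "9.08", "n": "2.90"}),
        ]
        assert cohort_qaly_total(results) == Decimal("12.1")

    def test_cohort_sum_oracle(self):
        results = [
            patient_qaly_total(p, {"c": v})
            for p, v in [("a", "1.5"), ("b", "2.5"), ("c", "3.0")]
        ]
        assert cohort_qaly_total(results) == Decimal("7.0")

    def test_duplicate_patient_rejected(self):
        r = patient_qaly_total("a", {"c": 1})
        with pytest.raises(ValueError, match="duplicate"):
            cohort_qaly_total([r, r])


class TestLifeExpectancy:
    def make_table(self):
        return LifeExpectancyTable(
            rows=[
                {"sex": "female", "age_years": 0, "remaining_years": 81},
                {"sex": "female", "age_years": 10, "remaining_years": 72},
                {"sex": "male", "age_years": 0, "remaining_years": 76},
                {"sex": "male", "age_years": 10, "remaining_years": 67},
            ]
        )

    def test_exact_and_interpolated_lookup(self):
        t = self.make_table()
        assert t.remaining_years("female", 10) == pytest.approx(72)
        assert t.remaining_years("male", 5) == pytest.approx(71.5)

    def test_clamped_outside_range_and_sex_specific(self):
        t = self.make_table()
        assert t.remaining_years("male", 40) == pytest.approx(67)
        assert t.remaining_years("female", 0) != t.remaining_years("male", 0)
        with pytest.raises(KeyError):
            t.remaining_years("unknown", 5)
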