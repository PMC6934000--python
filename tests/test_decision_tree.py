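"""Tree structure, probability estimation, roll-back vs path enumeration."""

import numpy as np
import pytest

from conftest import random_tree
from glaucoma_cea.cohort import ControlThresholds
from glaucoma_cea.synthetic import CohortConfig, generate_cohort
from glaucoma_cea.tree import (
    Branch,
    ChanceNode,
    DecisionTree,
    EffectMeasure,
    ProbabilityError,
    StrategyNode,
    TerminalNode,
    TreeValidationError,
    build_tree_from_cohort,
    estimate_probability,
    load_tree,
    path_enumeration_oracle,
    rollback,
    save_tree,
    validate_tree,
)


@pytest.mark.parametrize(
    "n_event,n_total,expected",
    [(20, 64, 0.3125), (0, 64, 0.0), (64, 64, 1.0), (14, 20, 0.70)],
)
def test_probability_is_exact_count_ratio(n_event, n_total, expected):
    assert estimate_probability(n_event, n_total) == expected


def test_probability_errors():
    with pytest.raises(ProbabilityError, match="undefined"):
        estimate_probability(0, 0)
    with pytest.raises(ProbabilityError):
        estimate_probability(5, 4)


def two_leaf_tree(costs=(100.0, 200.0), effects=(0.0, 1.0), p=0.5):
    chance = ChanceNode(
        label="c",
        branches=[
            Branch(p, TerminalNode("x", costs[0], effects[0])),
            Branch(1 - p, TerminalNode("y", costs[1], effects[1])),
        ],
    )
    return DecisionTree(
        strategies=[
            StrategyNode("A", chance),
            StrategyNode("B", TerminalNode("z", 100.0, 1.0)),
        ]
    )


def test_rollback_single_leaf_and_midpoint():
    values = {v.strategy: v for v in rollback(two_leaf_tree())}
    assert (values["B"].expected_cost, values["B"].expected_effect) == (100.0, 1.0)
    assert (values["A"].expected_cost, values["A"].expected_effect) == (150.0, 0.5)


def test_validate_tree_findings():
    assert validate_tree(two_leaf_tree()) == []
    bad = two_leaf_tree()
    bad.strategies[0].root.branches[0].probability = 0.6
    bad.strategies[0].root.branches[1].probability = 0.6
    findings = validate_tree(bad)
    assert len(findings) == 1 and "sum" in findings[0]
    neg = two_leaf_tree(costs=(-1.0, 200.0))
    assert any("negative cost" in f for f in validate_tree(neg))
    with pytest.raises(TreeValidationError):
        rollback(bad)


def test_rollback_equals_path_enumeration_on_random_trees():
    rng = np.random.default_rng(7)
    for _ in range(100):
        tree = random_tree(rng)
        rolled = rollback(tree)
        enumerated = path_enumeration_oracle(tree)
        for a, b in zip(rolled, enumerated):
            assert a.strategy == b.strategy
            assert a.expected_cost == pytest.approx(b.expected_cost, abs=1e-9)
            assert a.expected_effect == pytest.approx(b.expected_effect, abs=1e-9)


def test_expected_values_within_leaf_bounds():
    rng = np.random.default_rng(8)
    for _ in range(50):
        tree = random_tree(rng)
        for strategy, value in zip(tree.strategies, rollback(tree)):
            leaves = []
            stack = [strategy.root]
            while stack:
                node = stack.pop()
                if isinstance(node, TerminalNode):
                    leaves.append(node)
                else:
                    stack.extend(b.child for b in node.branches)
            costs = [l.cost for l in leaves]
            effects = [l.effect for l in leaves]
            assert min(costs) - 1e-9 <= value.expected_cost <= max(costs) + 1e-9
            assert min(effects) - 1e-9 <= value.expected_effect <= max(effects) + 1e-9


def test_rollback_linear_in_costs():
    rng = np.random.default_rng(9)
    tree = random_tree(rng)
    base = rollback(tree)
    for strategy in tree.strategies:
        stack = [strategy.root]
        while stack:
            node = stack.pop()
            if isinstance(node, TerminalNode):
                node.cost *= 3.0
            else:
                stack.extend(b.child for b in node.branches)
    scaled = rollback(tree)
    for a, b in zip(base, scaled):
        assert b.expected_cost == pytest.approx(3.0 * a.expected_cost, rel=1e-12)
        assert b.expected_effect == a.expected_effect


def test_serialization_round_trip(tmp_path):
    tree = two_leaf_tree()
    path = tmp_path / "tree.json"
    save_tree(tree, path)
    again = load_tree(path)
    assert rollback(again) == rollback(tree)
    path.write_text(path.read_text().replace('"chance"', '"mystery"'))
    with pytest.raises(TreeValidationError, match="mystery"):
        load_tree(path)


def test_cohort_tree_level1_probability(reference_records, prices):
    tree = build_tree_from_cohort(reference_records, ControlThresholds(), prices)
    assert validate_tree(tree) == []
    by_label = {s.label: s for s in tree.strategies}
    free = by_label["preservative-free"].root
    probs = {b.child.label: b.probability for b in free.branches}
    assert probs["mono"] == 14 / 20  # 0.70 exactly
    assert probs["combination"] == 6 / 20


def test_cohort_tree_rollback_equals_cohort_average(reference_records, prices):
    """Mean leaf payoffs make the rolled-back cost the arm's average cost."""
    from glaucoma_cea.costing import eye_yearly_cost

    tree = build_tree_from_cohort(reference_records, ControlThresholds(), prices)
    values = {v.strategy: v for v in rollback(tree)}
    for label, pf in (("preservative-free", True), ("preservative non-free", False)):
        eyes = [r for r in reference_records if r.preservative_free == pf]
        mean_cost = np.mean([sum(eye_yearly_cost(r, prices)) for r in eyes])
        assert values[label].expected_cost == pytest.approx(mean_cost, rel=1e-12)


def test_degenerate_cohort_collapses_to_single_path(make_record, prices):
    records = [
        make_record(classes=("PG",), preservative_free=True),
        make_record(classes=("PG",), preservative_free=False),
    ]
    with pytest.warns(UserWarning, match="empty stratum"):
        tree = build_tree_from_cohort(records, ControlThresholds(), prices)
    for strategy in tree.strategies:
        assert len(strategy.root.branches) == 1
        assert strategy.root.branches[0].probability == 1.0


def test_missing_strategy_arm_rejected(make_record, prices):
    records = [make_record(classes=("PG",), preservative_free=True)]
    with pytest.raises(ValueError, match="preservative non-free"):
        build_tree_from_cohort(records, ControlThresholds(), prices)


def test_effect_measure_changes_payoffs_not_probabilities(reference_records, prices):
    t_st = build_tree_from_cohort(
        reference_records, ControlThresholds(), prices, EffectMeasure.ST
    )
    t_nibut = build_tree_from_cohort(
        reference_records, ControlThresholds(), prices, EffectMeasure.NIBUT
    )
    v_st = {v.strategy: v for v in rollback(t_st)}
    v_nibut = {v.strategy: v for v in rollback(t_nibut)}
    for label in v_st:
        assert v_st[label].expected_cost == v_nibut[label].expected_cost
    assert v_st != v_nibut
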