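"""One-way DSA: null perturbations, oracle endpoints, tornado ordering, sign flips."""

import copy
import math

import numpy as np
import pytest

from glaucoma_cea.cea import icer
from glaucoma_cea.sensitivity import (
    ComparisonSpec,
    ParameterError,
    Perturbation,
    default_parameters,
    one_way_dsa,
    sign_flip_scan,
    tornado,
)
from glaucoma_cea.tree import (
    Branch,
    ChanceNode,
    DecisionTree,
    StrategyNode,
    StrategyValue,
    TerminalNode,
    path_enumeration_oracle,
)

SPEC = ComparisonSpec(reference="ref", comparator="comp")


def four_leaf_tree():
    """Two strategies x two leaves with distinct costs and effects."""

    def strat(label, p, costs, effects):
        return StrategyNode(
            label,
            ChanceNode(
                label="mix",
                branches=[
                    Branch(p, TerminalNode("hi", costs[0], effects[0])),
                    Branch(1 - p, TerminalNode("lo", costs[1], effects[1])),
                ],
            ),
        )

    return DecisionTree(
        strategies=[
            strat("ref", 0.6, (400.0, 500.0), (0.30, 0.50)),
            strat("comp", 0.7, (480.0, 560.0), (0.45, 0.65)),
        ]
    )


def oracle_icer(tree):
    values = {v.strategy: v for v in path_enumeration_oracle(tree)}
    return icer(values["ref"], values["comp"]).icer


def test_null_perturbation_recovers_base():
    tree = four_leaf_tree()
    entry = one_way_dsa(tree, SPEC, Perturbation("comp/hi:cost", (0.0, 0.0)))
    assert entry.icer_low == entry.icer_high == entry.base_icer


def test_zero_weight_parameter_has_zero_width():
    tree = four_leaf_tree()
    tree.strategies[1].root.branches[0].probability = 0.0
    tree.strategies[1].root.branches[1].probability = 1.0
    entry = one_way_dsa(tree, SPEC, Perturbation("comp/hi:cost"))
    assert entry.width == 0.0


def test_endpoints_match_oracle_recomputation():
    """±30% on one leaf cost equals a from-scratch path-enumeration ICER."""
    tree = four_leaf_tree()
    entry = one_way_dsa(tree, SPEC, Perturbation("comp/hi:cost"))
    for rel, got in ((-0.30, entry.icer_low), (0.30, entry.icer_high)):
        manual = copy.deepcopy(tree)
        manual.strategies[1].root.branches[0].child.cost *= 1 + rel
        assert got == pytest.approx(oracle_icer(manual), abs=1e-9)
    assert entry.base_icer == pytest.approx(oracle_icer(tree), abs=1e-9)


def test_probability_perturbation_renormalizes_siblings():
    tree = four_leaf_tree()
    entry = one_way_dsa(tree, SPEC, Perturbation("comp/hi:prob"))
    manual = copy.deepcopy(tree)
    root = manual.strategies[1].root
    root.branches[0].probability = 0.7 * 1.3
    root.branches[1].probability = 1 - 0.7 * 1.3
    assert entry.icer_high == pytest.approx(oracle_icer(manual), abs=1e-9)


def test_dsa_does_not_mutate_base_model():
    tree = four_leaf_tree()
    snapshot = copy.deepcopy(tree)
    first = one_way_dsa(tree, SPEC, Perturbation("ref/lo:effect"))
    second = one_way_dsa(tree, SPEC, Perturbation("ref/lo:effect"))
    assert tree == snapshot
    assert first == second


def test_unresolvable_parameter_names_path():
    with pytest.raises(ParameterError, match="nope"):
        one_way_dsa(four_leaf_tree(), SPEC, Perturbation("comp/nope:cost"))
    with pytest.raises(ParameterError, match="field"):
        one_way_dsa(four_leaf_tree(), SPEC, Perturbation("comp/hi:price"))


def test_default_parameters_cover_leaf_costs_and_effects():
    params = default_parameters(four_leaf_tree())
    assert "ref/hi:cost" in params and "comp/lo:effect" in params
    assert len(params) == 8  # 4 leaves x (cost, effect); no probabilities
    assert all(":prob" not in p for p in params)
    with_probs = default_parameters(four_leaf_tree(), include_probabilities=True)
    assert "comp/hi:prob" in with_probs


def test_tornado_sorted_by_width_and_order_invariant():
    tree = four_leaf_tree()
    params = sorted(default_parameters(tree))
    entries = tornado(tree, SPEC, params)
    widths = [e.width for e in entries]
    assert widths == sorted(widths, reverse=True)
    reshuffled = tornado(tree, SPEC, list(reversed(params)))
    assert [e.parameter_id for e in reshuffled] == [e.parameter_id for e in entries]


def test_tornado_all_zero_weight_parameters():
    tree = four_leaf_tree()
    tree.strategies[1].root.branches[0].probability = 0.0
    tree.strategies[1].root.branches[1].probability = 1.0
    params = ["comp/hi:cost", "comp/hi:effect"]  # zero path probability
    entries = tornado(tree, SPEC, params)
    assert [e.parameter_id for e in entries] == params  # ties keep id order
    assert all(e.width == 0.0 for e in entries)


def test_duplicate_parameter_warns_and_repeats():
    with pytest.warns(UserWarning, match="duplicate"):
        entries = tornado(four_leaf_tree(), SPEC, ["comp/hi:cost", "comp/hi:cost"])
    assert entries[0] == entries[1]


def test_sign_flip_absent_for_zero_width_parameter():
    tree = four_leaf_tree()
    tree.strategies[1].root.branches[0].probability = 0.0
    tree.strategies[1].root.branches[1].probability = 1.0
    assert sign_flip_scan(tree, SPEC, "comp/hi:cost") is None


def test_sign_flip_absent_when_response_keeps_sign():
    # perturbing a reference effect leaves the positive ICER positive
    assert sign_flip_scan(four_leaf_tree(), SPEC, "ref/lo:effect") is None


def test_sign_flip_detected_at_smallest_grid_point():
    """Comparator effect dropping below the reference flips the ICER at −20%."""
    tree = DecisionTree(
        strategies=[
            StrategyNode("ref", TerminalNode("r", 400.0, 0.81)),
            StrategyNode("comp", TerminalNode("c", 500.0, 1.00)),
        ]
    )
    flip = sign_flip_scan(tree, SPEC, "comp:effect")
    assert flip == pytest.approx(-0.20)
    # direct recomputation at the flagged grid point
    manual = copy.deepcopy(tree)
    manual.strategies[1].root.effect *= 1 - 0.20
    assert oracle_icer(manual) < 0 < oracle_icer(tree)
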