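"""Two-strategy decision tree: structure, cohort-driven construction, roll-back.

The model compares two prescribing strategies — preservative-free versus
preservative-containing ("non-free") glaucoma formulations — over a one-year
horizon with no discounting.  Under each strategy a first chance node splits
eyes into mono- versus combination therapy and a second into the therapeutic
class (monotherapy) or combination composition.  Terminal nodes carry a
yearly cost (BGN) and an effect payoff.  Branch probabilities are plain
maximum-likelihood proportions ``n(event)/n`` with no smoothing; strata with
zero observations are pruned and their siblings renormalized.

``rollback`` computes probability-weighted expected (cost, effect) per
strategy by leaf-to-root recursion; ``path_enumeration_oracle`` recomputes
the same quantities by explicit enumeration of every root-to-leaf path and
exists as an independent cross-check.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence, Union

from .cohort import ControlThresholds, EyeRecord, classify_control
from .costing import PriceList, default_price_list, eye_yearly_cost

__all__ = [
    "TerminalNode",
    "ChanceNode",
    "Branch",
    "StrategyNode",
    "DecisionTree",
    "StrategyValue",
    "EffectMeasure",
    "ProbabilityError",
    "TreeValidationError",
    "STRATEGY_FREE",
    "STRATEGY_NONFREE",
    "estimate_probability",
    "validate_tree",
    "rollback",
    "path_enumeration_oracle",
    "build_tree_from_cohort",
    "tree_to_dict",
    "tree_from_dict",
    "save_tree",
    "load_tree",
]

PROB_TOL = 1e-9

STRATEGY_FREE = "preservative-free"
STRATEGY_NONFREE = "preservative non-free"


class ProbabilityError(ValueError):
    pass


class TreeValidationError(ValueError):
    pass


class EffectMeasure(str, Enum):
    ST = "ST"
    TMS = "TMS"
    NIBUT = "NIBUT"


@dataclass
class TerminalNode:
    label: str
    cost: float
    effect: float


@dataclass
class Branch:
    probability: float
    child: "Node"


@dataclass
class ChanceNode:
    label: str
    branches: list[Branch]


Node = Union[ChanceNode, TerminalNode]


@dataclass
class StrategyNode:
    label: str
    root: Node


@dataclass
class DecisionTree:
    strategies: list[StrategyNode]


@dataclass(frozen=True)
class StrategyValue:
    strategy: str
    expected_cost: float
    expected_effect: float


def estimate_probability(n_event: int, n_total: int) -> float:
    """Maximum-likelihood event probability P(A) = n(A)/n, no smoothing."""
    if n_total <= 0:
        raise ProbabilityError("undefined probability: n_total must be > 0")
    if not (0 <= n_event <= n_total):
        raise ProbabilityError("n_event must satisfy 0 <= n_event <= n_total")
    return n_event / n_total


def validate_tree(tree: DecisionTree, tol: float = PROB_TOL) -> list[str]:
    """Structural findings: probability ranges and sums, non-negative costs.

    Returns an empty list for a well-formed tree rather than raising.
    """
    findings: list[str] = []
    if not tree.strategies:
        findings.append("tree has no strategies")

    def visit(node: Node, where: str) -> None:
        if isinstance(node, TerminalNode):
            if node.cost < 0:
                findings.append(f"{where}: negative cost {node.cost}")
            return
        if not node.branches:
            findings.append(f"{where}: chance node has no branches")
            return
        total = 0.0
        for branch in node.branches:
            p = branch.probability
            if not (0.0 <= p <= 1.0):
                findings.append(f"{where}: branch probability {p} outside [0, 1]")
            total += p
            visit(branch.child, f"{where}/{branch.child.label}")
        if abs(total - 1.0) > tol:
            findings.append(f"{where}: branch probabilities sum to {total!r}, not 1")

    for strategy in tree.strategies:
        visit(strategy.root, strategy.label)
    return findings


def _expected(node: Node) -> tuple[float, float]:
    if isinstance(node, TerminalNode):
        return node.cost, node.effect
    cost = 0.0
    effect = 0.0
    for branch in node.branches:
        c, e = _expected(branch.child)
        cost += branch.probability * c
        effect += branch.probability * e
    return cost, effect


def rollback(tree: DecisionTree) -> list[StrategyValue]:
    """Expected (cost, effect) per strategy by leaf-to-root recursion."""
    findings = validate_tree(tree)
    if findings:
        raise TreeValidationError("; ".join(findings))
    values = []
    for strategy in tree.strategies:
        cost, effect = _expected(strategy.root)
        values.append(StrategyValue(strategy.label, cost, effect))
    return values


def path_enumeration_oracle(tree: DecisionTree) -> list[StrategyValue]:
    """Same quantities as :func:`rollback` via explicit path enumeration.

    Iterates every root-to-leaf path, multiplying branch probabilities along
    the way and summing payoff x path-probability.  Kept deliberately
    independent of the recursive roll-back as a verification oracle.
    """
    findings = validate_tree(tree)
    if findings:
        raise TreeValidationError("; ".join(findings))
    values = []
    for strategy in tree.strategies:
        cost = 0.0
        effect = 0.0
        stack: list[tuple[Node, float]] = [(strategy.root, 1.0)]
        while stack:
            node, prob = stack.pop()
            if isinstance(node, TerminalNode):
                cost += prob * node.cost
                effect += prob * node.effect
            else:
                for branch in node.branches:
                    stack.append((branch.child, prob * branch.probability))
        values.append(StrategyValue(strategy.label, cost, effect))
    return values


# ---------------------------------------------------------------------------
# Cohort-driven construction
# ---------------------------------------------------------------------------


def _leaf_payoff(
    eyes: Sequence[EyeRecord],
    thresholds: ControlThresholds,
    prices: PriceList,
    measure: EffectMeasure,
) -> tuple[float, float]:
    """Mean yearly total cost and good-control proportion of the leaf's eyes.

    Leaf cost is the arithmetic mean of glaucoma + dry-eye yearly cost, so
    the rolled-back strategy cost equals the cohort-weighted average cost.
    The effect unit is the probability of good control on the chosen measure.
    """
    costs = []
    good = 0
    for eye in eyes:
        g, d = eye_yearly_cost(eye, prices)
        costs.append(g + d)
        status = classify_control(eye, thresholds)
        flag = {
            EffectMeasure.ST: status.st_good,
            EffectMeasure.TMS: status.tms_good,
            EffectMeasure.NIBUT: status.nibut_good,
        }[measure]
        good += flag
    return sum(costs) / len(costs), good / len(eyes)


def build_tree_from_cohort(
    records: Sequence[EyeRecord],
    thresholds: ControlThresholds | None = None,
    prices: PriceList | None = None,
    effect_measure: EffectMeasure = EffectMeasure.TMS,
) -> DecisionTree:
    """Build the two-strategy tree with probabilities estimated from the cohort.

    Level 1 under each strategy: mono versus combination therapy; level 2:
    therapeutic class (monotherapy) or combination composition.  Empty strata
    are pruned with a warning (probabilities then renormalize by construction
    since they are stratum counts over the arm size).
    """
    if not records:
        raise ValueError("empty cohort")
    thresholds = thresholds or ControlThresholds()
    prices = prices if prices is not None else default_price_list()

    arms = {
        STRATEGY_FREE: [r for r in records if r.preservative_free],
        STRATEGY_NONFREE: [r for r in records if not r.preservative_free],
    }
    for label, eyes in arms.items():
        if not eyes:
            raise ValueError(f"strategy {label!r} has no eyes in the cohort")

    strategies = []
    for label, eyes in arms.items():
        n_arm = len(eyes)
        level1: list[Branch] = []
        for kind, members in (
            ("mono", [e for e in eyes if e.is_monotherapy]),
            ("combination", [e for e in eyes if not e.is_monotherapy]),
        ):
            if not members:
                warnings.warn(f"{label}/{kind}: empty stratum pruned", stacklevel=2)
                continue
            p_kind = estimate_probability(len(members), n_arm)
            groups: dict[str, list[EyeRecord]] = {}
            for eye in members:
                key = eye.therapies[0].drug_class.value if kind == "mono" else eye.combo_label
                groups.setdefault(key, []).append(eye)
            level2 = []
            for key in sorted(groups):
                leaf_eyes = groups[key]
                cost, effect = _leaf_payoff(leaf_eyes, thresholds, prices, effect_measure)
                level2.append(
                    Branch(
                        probability=estimate_probability(len(leaf_eyes), len(members)),
                        child=TerminalNode(label=key, cost=cost, effect=effect),
                    )
                )
            level1.append(Branch(probability=p_kind, child=ChanceNode(label=kind, branches=level2)))
        # renormalize after pruning (counts already sum to the arm size, so
        # this only matters if a stratum was dropped)
        total = sum(b.probability for b in level1)
        if abs(total - 1.0) > PROB_TOL:
            for b in level1:
                b.probability /= total
        strategies.append(StrategyNode(label=label, root=ChanceNode(label="therapy", branches=level1)))
    return DecisionTree(strategies=strategies)


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------


def _node_to_dict(node: Node) -> dict:
    if isinstance(node, TerminalNode):
        return {"type": "terminal", "label": node.label, "cost": node.cost, "effect": node.effect}
    return {
        "type": "chance",
        "label": node.label,
        "branches": [
            {"probability": b.probability, "child": _node_to_dict(b.child)} for b in node.branches
        ],
    }


def _node_from_dict(data: dict) -> Node:
    kind = data.get("type")
    if kind == "terminal":
        return TerminalNode(label=data["label"], cost=float(data["cost"]), effect=float(data["effect"]))
    if kind == "chance":
        return ChanceNode(
            label=data["label"],
            branches=[
                Branch(probability=float(b["probability"]), child=_node_from_dict(b["child"]))
                for b in data["branches"]
            ],
        )
    raise TreeValidationError(f"unknown node type tag: {kind!r}")


def tree_to_dict(tree: DecisionTree) -> dict:
    return {
        "strategies": [
            {"label": s.label, "root": _node_to_dict(s.root)} for s in tree.strategies
        ]
    }


def tree_from_dict(data: dict) -> DecisionTree:
    try:
        tree = DecisionTree(
            strategies=[
                StrategyNode(label=s["label"], root=_node_from_dict(s["root"]))
                for s in data["strategies"]
            ]
        )
    except (KeyError, TypeError) as exc:
        raise TreeValidationError(f"malformed tree document: {exc}") from exc
    findings = validate_tree(tree)
    if findings:
        raise TreeValidationError("; ".join(findings))
    return tree


def save_tree(tree: DecisionTree, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(tree_to_dict(tree), fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_tree(path: str | Path) -> DecisionTree:
    with open(path, encoding="utf-8") as fh:
        return tree_from_dict(json.load(fh))
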