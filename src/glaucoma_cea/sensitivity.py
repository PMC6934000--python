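"""One-way deterministic sensitivity analysis with ±30% perturbation.

Each tree quantity — a leaf cost, a leaf effect or, optionally, a branch
probability — is moved to the low and high end of its relative range while
everything else stays at base value; strategy values are re-rolled-back and
the ICER recomputed at each endpoint.  The base model is never mutated.
Entries sorted by bar width (|ICER_high − ICER_low|) form the tornado
diagram.  ``sign_flip_scan`` walks a perturbation grid outwards from zero
and reports the smallest perturbation at which the ICER changes sign.

Parameters are addressed by path strings::

    "<strategy label>/<child label>/.../<leaf label>:cost"   (or :effect)
    "<strategy label>/<child label>/.../<child label>:prob"

``:prob`` perturbs the incoming branch probability of the addressed node,
clamps it to [0, 1] and rescales its sibling probabilities proportionally so
the chance node still sums to one.  Probability perturbation is off the
default parameter list (costs and effects only) but fully supported.
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from . import cea
from .tree import Branch, ChanceNode, DecisionTree, Node, TerminalNode, rollback

__all__ = [
    "ComparisonSpec",
    "Perturbation",
    "TornadoEntry",
    "ParameterError",
    "one_way_dsa",
    "tornado",
    "sign_flip_scan",
    "default_parameters",
    "default_grid",
]


class ParameterError(KeyError):
    pass


@dataclass(frozen=True)
class ComparisonSpec:
    """Which strategies form the incremental comparison (by label)."""

    reference: str
    comparator: str


@dataclass(frozen=True)
class Perturbation:
    parameter_id: str
    relative_range: tuple[float, float] = (-0.30, 0.30)


@dataclass(frozen=True)
class TornadoEntry:
    parameter_id: str
    icer_low: float | None
    icer_high: float | None
    base_icer: float
    undefined_low: bool = False
    undefined_high: bool = False

    @property
    def width(self) -> float:
        """Bar width |ICER_high − ICER_low|; NaN when an endpoint is undefined."""
        if self.icer_low is None or self.icer_high is None:
            return math.nan
        return abs(self.icer_high - self.icer_low)


def _split_parameter(parameter_id: str) -> tuple[list[str], str]:
    if ":" not in parameter_id:
        raise ParameterError(f"parameter {parameter_id!r}: missing ':cost', ':effect' or ':prob'")
    path, _, fieldname = parameter_id.rpartition(":")
    if fieldname not in ("cost", "effect", "prob"):
        raise ParameterError(f"parameter {parameter_id!r}: unknown field {fieldname!r}")
    segments = [s for s in path.split("/") if s]
    if not segments:
        raise ParameterError(f"parameter {parameter_id!r}: empty path")
    return segments, fieldname


def _walk(tree: DecisionTree, segments: Sequence[str], parameter_id: str):
    """Return (parent_chance_node_or_None, branch_or_None, node) for the path."""
    for strategy in tree.strategies:
        if strategy.label == segments[0]:
            node: Node = strategy.root
            parent: ChanceNode | None = None
            branch: Branch | None = None
            for segment in segments[1:]:
                if isinstance(node, TerminalNode):
                    raise ParameterError(
                        f"parameter {parameter_id!r}: {segment!r} descends past a terminal node"
                    )
                for b in node.branches:
                    if b.child.label == segment:
                        parent, branch, node = node, b, b.child
                        break
                else:
                    raise ParameterError(
                        f"parameter {parameter_id!r}: no branch labelled {segment!r} "
                        f"under {node.label!r}"
                    )
            return parent, branch, node
    raise ParameterError(f"parameter {parameter_id!r}: no strategy labelled {segments[0]!r}")


def _apply(tree: DecisionTree, parameter_id: str, relative: float) -> DecisionTree:
    """A deep copy of the tree with one parameter scaled by (1 + relative)."""
    perturbed = copy.deepcopy(tree)
    segments, fieldname = _split_parameter(parameter_id)
    parent, branch, node = _walk(perturbed, segments, parameter_id)
    if fieldname in ("cost", "effect"):
        if not isinstance(node, TerminalNode):
            raise ParameterError(f"parameter {parameter_id!r}: path does not end at a leaf")
        setattr(node, fieldname, getattr(node, fieldname) * (1.0 + relative))
        return perturbed
    if parent is None or branch is None:
        raise ParameterError(f"parameter {parameter_id!r}: ':prob' needs a branch, not a root")
    old = branch.probability
    new = min(1.0, max(0.0, old * (1.0 + relative)))
    branch.probability = new
    siblings = [b for b in parent.branches if b is not branch]
    rest_old = sum(b.probability for b in siblings)
    rest_new = 1.0 - new
    if siblings:
        if rest_old > 0:
            for b in siblings:
                b.probability *= rest_new / rest_old
        else:  # siblings all at zero: spread the remainder uniformly
            for b in siblings:
                b.probability = rest_new / len(siblings)
    return perturbed


def _icer_for(tree: DecisionTree, spec: ComparisonSpec) -> float | None:
    values = {v.strategy: v for v in rollback(tree)}
    for label in (spec.reference, spec.comparator):
        if label not in values:
            raise ParameterError(f"no strategy labelled {label!r} in the tree")
    result = cea.icer(values[spec.reference], values[spec.comparator])
    return result.icer


def one_way_dsa(
    tree: DecisionTree, spec: ComparisonSpec, perturbation: Perturbation
) -> TornadoEntry:
    """Low/high ICER endpoints for one parameter; the base tree is untouched."""
    base = _icer_for(tree, spec)
    if base is None:
        raise ValueError("base ICER undefined (zero effect difference)")
    lo_rel, hi_rel = perturbation.relative_range
    icer_lo = _icer_for(_apply(tree, perturbation.parameter_id, lo_rel), spec)
    icer_hi = _icer_for(_apply(tree, perturbation.parameter_id, hi_rel), spec)
    return TornadoEntry(
        parameter_id=perturbation.parameter_id,
        icer_low=icer_lo,
        icer_high=icer_hi,
        base_icer=base,
        undefined_low=icer_lo is None,
        undefined_high=icer_hi is None,
    )


def default_parameters(tree: DecisionTree, include_probabilities: bool = False) -> list[str]:
    """All leaf cost and effect paths (plus branch probabilities on request)."""
    params: list[str] = []

    def visit(node: Node, prefix: str) -> None:
        if isinstance(node, TerminalNode):
            params.append(f"{prefix}:cost")
            params.append(f"{prefix}:effect")
            return
        for b in node.branches:
            child_prefix = f"{prefix}/{b.child.label}"
            if include_probabilities:
                params.append(f"{child_prefix}:prob")
            visit(b.child, child_prefix)

    for strategy in tree.strategies:
        visit(strategy.root, strategy.label)
    return params


def tornado(
    tree: DecisionTree,
    spec: ComparisonSpec,
    parameters: Iterable[str] | None = None,
    relative_range: tuple[float, float] = (-0.30, 0.30),
) -> list[TornadoEntry]:
    """One-way DSA over all parameters, sorted by descending bar width.

    Ties (and NaN widths from undefined endpoints, which sort last) break on
    parameter_id so the ordering is deterministic.  Duplicate parameters are
    analysed as listed but flagged with a warning.
    """
    params = list(parameters) if parameters is not None else default_parameters(tree)
    if not params:
        raise ValueError("at least one parameter is required")
    seen = set()
    for p in params:
        if p in seen:
            warnings.warn(f"duplicate parameter {p!r} in tornado input", stacklevel=2)
        seen.add(p)
    entries = [
        one_way_dsa(tree, spec, Perturbation(parameter_id=p, relative_range=relative_range))
        for p in params
    ]

    def key(entry: TornadoEntry):
        width = entry.width
        return (-width if not math.isnan(width) else math.inf, entry.parameter_id)

    return sorted(entries, key=key)


def default_grid(n: int = 61, span: float = 0.30) -> np.ndarray:
    """Evenly spaced perturbation grid over [−span, +span] (1% steps by default)."""
    return np.linspace(-span, span, n)


def sign_flip_scan(
    tree: DecisionTree,
    spec: ComparisonSpec,
    parameter_id: str,
    grid: Sequence[float] | None = None,
) -> float | None:
    """Smallest perturbation at which the ICER changes sign, if any.

    The grid is scanned outwards from zero (ties: negative before positive);
    grid points with an undefined ICER are skipped with a warning.  Returns
    the perturbation (relative, e.g. −0.20) or ``None`` if the sign never
    flips within the grid.
    """
    base = _icer_for(tree, spec)
    if base is None:
        raise ValueError("base ICER undefined (zero effect difference)")
    base_sign = math.copysign(1.0, base)
    points = sorted(default_grid() if grid is None else grid, key=lambda r: (abs(r), r))
    for rel in points:
        if rel == 0:
            continue
        value = _icer_for(_apply(tree, parameter_id, rel), spec)
        if value is None:
            warnings.warn(
                f"ICER undefined at perturbation {rel:+.4f}; grid point skipped", stacklevel=2
            )
            continue
        if math.copysign(1.0, value) != base_sign and value != 0:
            return float(rel)
    return None
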