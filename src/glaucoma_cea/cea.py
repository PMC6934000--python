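"""Incremental cost-effectiveness: ICER, dominance quadrants, WTP verdicts.

Given two valued strategies the incremental cost-effectiveness ratio is
ICER = (C_comparator − C_reference) / (E_comparator − E_reference).  The
reference is the preservative-containing ("non-free") strategy, i.e. current
practice; the comparator is the preservative-free strategy.  The sign pair
(ΔE, ΔC) places the comparison in a cost-effectiveness-plane quadrant:

* NE — costlier and more effective: the ICER is a price per extra unit of
  effect, judged against a willingness-to-pay threshold;
* SE — cheaper and more effective: the comparator dominates;
* NW — costlier and less effective: the comparator is dominated;
* SW — cheaper and less effective: the threshold applies to the reversed
  comparison (the same ICER value read as savings per unit of effect lost).

The willingness-to-pay policy follows the WHO convention: below 1x GDP per
capita per unit of effect is highly cost-effective, between 1x and 3x
(upper bound closed) cost-effective, above 3x not cost-effective.  The
default GDP per capita is Bulgaria's 15,226 BGN.

A printed-values mode (:func:`icer` with ``delta_cost``/``delta_effect``
overrides) recomputes a published comparison directly from per-strategy
values and rounded printed deltas, for reproducing reported tables whose
leaf-level payoffs are not available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Sequence

from .tree import StrategyValue

__all__ = [
    "Quadrant",
    "Verdict",
    "ThresholdPolicy",
    "CEResult",
    "icer",
    "who_verdict",
    "apply_policy",
    "ce_plane",
    "results_to_rows",
]


class Quadrant(str, Enum):
    NE = "NE"  # costlier, more effective
    SE = "SE"  # cheaper, more effective (comparator dominant)
    NW = "NW"  # costlier, less effective (comparator dominated)
    SW = "SW"  # cheaper, less effective


class Verdict(str, Enum):
    HIGHLY_COST_EFFECTIVE = "highly_cost_effective"
    COST_EFFECTIVE = "cost_effective"
    NOT_COST_EFFECTIVE = "not_cost_effective"
    DOMINANT = "dominant"
    DOMINATED = "dominated"
    NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class ThresholdPolicy:
    """WHO-style willingness-to-pay thresholds as GDP multiples."""

    gdp_per_capita: float = 15226.0  # BGN
    multiplier_low: float = 1.0
    multiplier_high: float = 3.0

    def __post_init__(self) -> None:
        if self.gdp_per_capita <= 0:
            raise ValueError("gdp_per_capita must be > 0")

    @property
    def wtp_low(self) -> float:
        return self.multiplier_low * self.gdp_per_capita

    @property
    def wtp_high(self) -> float:
        return self.multiplier_high * self.gdp_per_capita


@dataclass(frozen=True)
class CEResult:
    """One paired strategy comparison (comparator minus reference).

    ``icer`` is absent when the effect difference is zero (no division is
    attempted).  In the dominance quadrants (SE, NW) the ICER value is still
    reported but is not interpretable as a price — check ``icer_is_price``.
    """

    reference: StrategyValue
    comparator: StrategyValue
    delta_cost: float
    delta_effect: float
    icer: float | None
    quadrant: Quadrant | None
    verdict: Verdict | None = None

    @property
    def icer_is_price(self) -> bool:
        return self.quadrant in (Quadrant.NE, Quadrant.SW)

    def to_dict(self) -> dict:
        return {
            "reference": self.reference.strategy,
            "cost_ref": self.reference.expected_cost,
            "effect_ref": self.reference.expected_effect,
            "comparator": self.comparator.strategy,
            "cost_comp": self.comparator.expected_cost,
            "effect_comp": self.comparator.expected_effect,
            "delta_cost": self.delta_cost,
            "delta_effect": self.delta_effect,
            "icer": self.icer,
            "quadrant": self.quadrant.value if self.quadrant else None,
            "verdict": self.verdict.value if self.verdict else None,
        }


def _quadrant(delta_cost: float, delta_effect: float) -> Quadrant | None:
    if delta_effect == 0:
        return None
    if delta_effect > 0:
        return Quadrant.NE if delta_cost > 0 else Quadrant.SE
    return Quadrant.NW if delta_cost >= 0 else Quadrant.SW


def icer(
    reference: StrategyValue,
    comparator: StrategyValue,
    *,
    delta_cost: float | None = None,
    delta_effect: float | None = None,
    policy: ThresholdPolicy | None = None,
) -> CEResult:
    """Incremental comparison of comparator against reference.

    Deltas default to comparator minus reference; passing ``delta_cost`` /
    ``delta_effect`` overrides them with externally printed (rounded) values,
    which is how published tables are reproduced when their inputs are only
    available at printed precision.  If ``policy`` is given the verdict is
    filled in, otherwise only the dominance cases are decided.
    """
    dc = comparator.expected_cost - reference.expected_cost if delta_cost is None else delta_cost
    de = (
        comparator.expected_effect - reference.expected_effect
        if delta_effect is None
        else delta_effect
    )
    quadrant = _quadrant(dc, de)
    ratio = dc / de if de != 0 else None
    result = CEResult(
        reference=reference,
        comparator=comparator,
        delta_cost=dc,
        delta_effect=de,
        icer=ratio,
        quadrant=quadrant,
    )
    verdict = who_verdict(result, policy) if policy is not None else _policy_free_verdict(result)
    return replace(result, verdict=verdict)


def _policy_free_verdict(result: CEResult) -> Verdict | None:
    if result.quadrant is None:
        return Verdict.NOT_APPLICABLE
    if result.quadrant is Quadrant.SE:
        return Verdict.DOMINANT
    if result.quadrant is Quadrant.NW:
        return Verdict.DOMINATED
    return None  # NE / SW need a threshold policy


def who_verdict(result: CEResult, policy: ThresholdPolicy | None = None) -> Verdict:
    """Classify a comparison against the WTP thresholds.

    NE: ICER below 1x GDP → highly cost-effective, up to and including
    3x GDP → cost-effective, above → not cost-effective.  SE → dominant,
    NW → dominated regardless of magnitude.  SW applies the same thresholds
    to the reversed comparison (identical ICER value), so the verdict there
    describes whether forgoing the comparator's savings buys the effect back
    at an acceptable price.  Zero effect difference → not applicable.
    """
    policy = policy or ThresholdPolicy()
    simple = _policy_free_verdict(result)
    if simple is not None:
        return simple
    assert result.icer is not None
    value = result.icer
    if value < policy.wtp_low:
        return Verdict.HIGHLY_COST_EFFECTIVE
    if value <= policy.wtp_high:
        return Verdict.COST_EFFECTIVE
    return Verdict.NOT_COST_EFFECTIVE


def apply_policy(result: CEResult, policy: ThresholdPolicy) -> CEResult:
    return replace(result, verdict=who_verdict(result, policy))


def ce_plane(
    results: Sequence[CEResult], policy: ThresholdPolicy | None = None
) -> dict:
    """Plot-ready cost-effectiveness-plane coordinates (no rendering).

    Points are (ΔE, ΔC) pairs; the threshold lines through the origin have
    slope 1x and 3x GDP per capita (BGN per effect unit).
    """
    if not results:
        raise ValueError("at least one comparison is required")
    policy = policy or ThresholdPolicy()
    return {
        "points": [
            {
                "delta_effect": r.delta_effect,
                "delta_cost": r.delta_cost,
                "quadrant": r.quadrant.value if r.quadrant else None,
            }
            for r in results
        ],
        "threshold_slopes": {"1x_gdp": policy.wtp_low, "3x_gdp": policy.wtp_high},
    }


def results_to_rows(results: Sequence[CEResult]) -> list[dict]:
    """One flat dict per comparison, mirroring the published table layout."""
    return [r.to_dict() for r in results]
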