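"""Synthetic patient-eye cohort generator.

Emulates a 64-eye POAG + dry-eye cohort with the observed categorical
structure: preservative-free share 20/64, monotherapy share 14/20 within the
free arm and 20/44 within the non-free arm, monotherapy classes 25 PG : 9 BB
(no CAI or A2A monotherapy), the five observed combination types at
6:8:5:2:9, marginal good-control rates 15/64 (ST), 23/64 (TMS), 2/64
(NIBUT), and yearly glaucoma cost distributions anchored to the reported
arm medians/SDs (320.97 (133.18) free, 322.14 (203.76) non-free, dry-eye
179.93 (9.36)).

Each eye is drawn hierarchically: strategy arm → mono/combination →
class/composition → per-test control status → measurements → costs.
Measurements are drawn uniformly from configurable intervals strictly on
the sampled side of each control threshold, so re-classifying a generated
eye reproduces its sampled control flags exactly.  Yearly costs are
log-normal (positive, right-skewed) with (mu, sigma) solved in closed form
from the configured median and SD; the dosing regimen of each therapy line
is back-solved against the price list so that the costing pipeline
reproduces the sampled cost to the cent.

The three tests are sampled independently (only marginal rates are
configured), and demographics are per-eye, so within-patient eye pairing is
not modelled; every eye gets its own patient identifier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .cohort import (
    DrugClass,
    DurationBand,
    EyeRecord,
    Sex,
    Side,
    TherapyLine,
    ValidationError,
)
from .costing import PriceList, default_price_list, product_for, round_bgn

__all__ = [
    "CohortConfig",
    "default_config",
    "generate_cohort",
    "lognormal_params",
    "save_config",
    "load_config",
]


def lognormal_params(median: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the log-normal with the given median and SD.

    median = exp(mu); SD^2 = (k − 1) k median^2 with k = exp(sigma^2), so
    k solves k^2 − k − (SD/median)^2 = 0 in closed form.
    """
    if median <= 0:
        raise ValidationError("median must be > 0")
    if sd < 0:
        raise ValidationError("sd must be >= 0")
    mu = math.log(median)
    ratio2 = (sd / median) ** 2
    k = (1.0 + math.sqrt(1.0 + 4.0 * ratio2)) / 2.0
    return mu, math.sqrt(math.log(k))


_AGE_BAND_RANGES = {
    "<50": (30, 49),
    "50-60": (50, 60),
    "61-70": (61, 70),
    "71-80": (71, 80),
    "80+": (81, 85),
}


@dataclass
class CohortConfig:
    """Generative parameters; the defaults are the observed study conditions."""

    n_eyes: int = 64
    seed: int = 0
    p_preservative_free: float = 20 / 64
    p_mono_given_free: float = 14 / 20
    p_mono_given_nonfree: float = 20 / 44
    mono_class_weights: dict[str, float] = field(
        default_factory=lambda: {"PG": 25.0, "BB": 9.0, "CAI": 0.0, "A2A": 0.0}
    )
    combo_weights: dict[str, float] = field(
        default_factory=lambda: {
            "PG+BB": 6.0,
            "BB+CAI": 8.0,
            "PG+CAI": 5.0,
            "CAI+A2A": 2.0,
            "PG+BB+CAI": 9.0,
        }
    )
    # marginal P(good control) per test; a single float applies to both arms,
    # a [free, nonfree] pair makes the rate arm-specific
    control_probs: dict[str, float | list[float]] = field(
        default_factory=lambda: {"st": 15 / 64, "tms": 23 / 64, "nibut": 2 / 64}
    )
    glaucoma_cost_free: dict[str, float] = field(
        default_factory=lambda: {"median": 320.97, "sd": 133.18}
    )
    glaucoma_cost_nonfree: dict[str, float] = field(
        default_factory=lambda: {"median": 322.14, "sd": 203.76}
    )
    dry_eye_cost: dict[str, float] = field(
        default_factory=lambda: {"median": 179.93, "sd": 9.36}
    )
    sex_weights: dict[str, float] = field(default_factory=lambda: {"male": 25.0, "female": 39.0})
    age_band_weights: dict[str, float] = field(
        default_factory=lambda: {"50-60": 10.0, "61-70": 28.0, "71-80": 21.0, "80+": 5.0}
    )
    duration_weights: dict[str, float] = field(
        default_factory=lambda: {"lt1y": 27.0, "1to5y": 27.0, "5to10y": 10.0}
    )
    side_weights: dict[str, float] = field(default_factory=lambda: {"left": 30.0, "right": 34.0})
    # measurement synthesis intervals, strictly on each side of the default
    # thresholds (ST 10 mm, TMS 3, NIBUT 14 s); TMS bounds are inclusive
    # integer score ranges
    st_good_interval: list[float] = field(default_factory=lambda: [10.5, 20.0])
    st_poor_interval: list[float] = field(default_factory=lambda: [0.0, 9.5])
    tms_good_scores: list[int] = field(default_factory=lambda: [0, 2])
    tms_poor_scores: list[int] = field(default_factory=lambda: [3, 6])
    nibut_good_interval: list[float] = field(default_factory=lambda: [14.5, 25.0])
    nibut_poor_interval: list[float] = field(default_factory=lambda: [2.0, 13.5])
    year_days: int = 365

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "CohortConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**dict(data))


def default_config() -> CohortConfig:
    return CohortConfig()


def _check_prob(name: str, p: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ValidationError(f"{name}: probability {p} outside [0, 1]")


def _check_weights(name: str, weights: Mapping[str, float]) -> None:
    if not weights:
        raise ValidationError(f"{name}: empty weights")
    if any(w < 0 for w in weights.values()):
        raise ValidationError(f"{name}: negative weight")
    if sum(weights.values()) <= 0:
        raise ValidationError(f"{name}: weights sum to zero")


def validate_config(config: CohortConfig) -> None:
    if config.n_eyes < 1:
        raise ValidationError("n_eyes: must be >= 1")
    _check_prob("p_preservative_free", config.p_preservative_free)
    _check_prob("p_mono_given_free", config.p_mono_given_free)
    _check_prob("p_mono_given_nonfree", config.p_mono_given_nonfree)
    _check_weights("mono_class_weights", config.mono_class_weights)
    _check_weights("combo_weights", config.combo_weights)
    _check_weights("sex_weights", config.sex_weights)
    _check_weights("age_band_weights", config.age_band_weights)
    _check_weights("duration_weights", config.duration_weights)
    _check_weights("side_weights", config.side_weights)
    for test, p in config.control_probs.items():
        if test not in ("st", "tms", "nibut"):
            raise ValidationError(f"control_probs: unknown test {test!r}")
        pair = p if isinstance(p, (list, tuple)) else (p, p)
        if len(pair) != 2:
            raise ValidationError(f"control_probs[{test}]: need a float or a [free, nonfree] pair")
        for v in pair:
            _check_prob(f"control_probs[{test}]", v)
    for name in ("glaucoma_cost_free", "glaucoma_cost_nonfree", "dry_eye_cost"):
        params = getattr(config, name)
        if params["median"] <= 0 or params["sd"] < 0:
            raise ValidationError(f"{name}: median must be > 0 and sd >= 0")
    for band in config.age_band_weights:
        if band not in _AGE_BAND_RANGES:
            raise ValidationError(f"age_band_weights: unknown band {band!r}")
    # measurement intervals must sit strictly on their side of the thresholds
    if not (config.st_good_interval[0] > 10 and config.st_poor_interval[1] < 10):
        raise ValidationError("st intervals must straddle the 10 mm threshold strictly")
    if not (config.tms_good_scores[1] < 3 and config.tms_poor_scores[0] > 3 - 1):
        raise ValidationError("tms score ranges must sit strictly below/at-or-above 3")
    if not (config.nibut_good_interval[0] > 14 and config.nibut_poor_interval[1] < 14):
        raise ValidationError("nibut intervals must straddle the 14 s threshold strictly")


def _control_pair(config: CohortConfig, test: str) -> tuple[float, float]:
    p = config.control_probs[test]
    if isinstance(p, (list, tuple)):
        return float(p[0]), float(p[1])
    return float(p), float(p)


def _lines_for_cost(
    classes: Sequence[DrugClass],
    pf: bool,
    total_cost: float,
    prices: PriceList,
    year_days: int,
) -> tuple[TherapyLine, ...]:
    """Back-solve dosing so the costed lines sum to the sampled yearly cost."""
    share = total_cost / len(classes)
    lines = []
    for cls in classes:
        product = product_for(prices, cls, pf)
        if product.pack_price_bgn <= 0:
            raise ValidationError(f"product {product.product_id!r} has zero price")
        doses = share * product.doses_per_pack / (year_days * product.pack_price_bgn)
        lines.append(
            TherapyLine(
                inn=product.inn,
                drug_class=cls,
                preservative_free=pf,
                doses_per_day=doses,
                product_ref=product.product_id,
            )
        )
    return tuple(lines)


def generate_cohort(
    config: CohortConfig | None = None, prices: PriceList | None = None
) -> list[EyeRecord]:
    """Draw a cohort; deterministic for a given config (seed included)."""
    config = config or default_config()
    validate_config(config)
    prices = prices if prices is not None else default_price_list()
    rng = np.random.default_rng(config.seed)
    n = config.n_eyes

    def choice(weights: Mapping[str, float]) -> tuple[list[str], np.ndarray]:
        labels = list(weights)
        w = np.array([weights[k] for k in labels], dtype=float)
        return labels, rng.choice(len(labels), size=n, p=w / w.sum())

    is_free = rng.random(n) < config.p_preservative_free
    p_mono = np.where(is_free, config.p_mono_given_free, config.p_mono_given_nonfree)
    is_mono = rng.random(n) < p_mono
    mono_labels, mono_idx = choice(config.mono_class_weights)
    combo_labels, combo_idx = choice(config.combo_weights)

    goods = {}
    for test in ("st", "tms", "nibut"):
        p_free_arm, p_nonfree_arm = _control_pair(config, test)
        goods[test] = rng.random(n) < np.where(is_free, p_free_arm, p_nonfree_arm)

    st_vals = np.where(
        goods["st"],
        rng.uniform(*config.st_good_interval, size=n),
        rng.uniform(*config.st_poor_interval, size=n),
    )
    tms_vals = np.where(
        goods["tms"],
        rng.integers(config.tms_good_scores[0], config.tms_good_scores[1] + 1, size=n),
        rng.integers(config.tms_poor_scores[0], config.tms_poor_scores[1] + 1, size=n),
    )
    nibut_vals = np.where(
        goods["nibut"],
        rng.uniform(*config.nibut_good_interval, size=n),
        rng.uniform(*config.nibut_poor_interval, size=n),
    )

    mu_f, sg_f = lognormal_params(**config.glaucoma_cost_free)
    mu_n, sg_n = lognormal_params(**config.glaucoma_cost_nonfree)
    mu_d, sg_d = lognormal_params(**config.dry_eye_cost)
    cost_free = rng.lognormal(mu_f, sg_f, size=n)
    cost_nonfree = rng.lognormal(mu_n, sg_n, size=n)
    glaucoma_cost = np.where(is_free, cost_free, cost_nonfree)
    tears_cost = rng.lognormal(mu_d, sg_d, size=n)

    sex_labels, sex_idx = choice(config.sex_weights)
    band_labels, band_idx = choice(config.age_band_weights)
    ages = np.empty(n, dtype=int)
    for i, band in enumerate(band_labels):
        lo, hi = _AGE_BAND_RANGES[band]
        mask = band_idx == i
        ages[mask] = rng.integers(lo, hi + 1, size=int(mask.sum()))
    duration_labels, duration_idx = choice(config.duration_weights)
    side_labels, side_idx = choice(config.side_weights)

    records: list[EyeRecord] = []
    for i in range(n):
        pf = bool(is_free[i])
        if is_mono[i]:
            classes = [DrugClass(mono_labels[mono_idx[i]])]
        else:
            classes = [DrugClass(c) for c in combo_labels[combo_idx[i]].split("+")]
        lines = _lines_for_cost(
            classes, pf, float(glaucoma_cost[i]), prices, config.year_days
        )
        records.append(
            EyeRecord(
                eye_id=f"eye{i:06d}",
                patient_id=f"pat{i:06d}",
                side=Side(side_labels[side_idx[i]]),
                sex=Sex(sex_labels[sex_idx[i]]),
                age_years=int(ages[i]),
                duration_band=DurationBand(duration_labels[duration_idx[i]]),
                therapies=lines,
                artificial_tears=True,
                artificial_tears_yearly_cost_bgn=round_bgn(float(tears_cost[i])),
                st_mm=float(st_vals[i]),
                tms_score=int(tms_vals[i]),
                nibut_s=float(nibut_vals[i]),
            )
        )
    return records


def save_config(config: CohortConfig, path: str | Path) -> None:
    validate_config(config)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True, default_flow_style=False)


def load_config(path: str | Path) -> CohortConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    config = CohortConfig.from_dict(data or {})
    validate_config(config)
    return config
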