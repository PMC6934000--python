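"""Patient-eye data model, validation, disease-control classification and cohort summaries.

The unit of analysis is the affected *eye*, not the patient: bilateral
patients contribute two independent records and ``patient_id`` is kept for
provenance only.  Each record carries the glaucoma therapy lines actually
prescribed to that eye, a flag plus yearly cost for supplemental artificial
tears, and the three tear-film measurements used as outcome measures:

* ST (Schirmer test, mm) — aqueous-phase tear volume; above threshold = good.
* TMS (total meiboscore, 0–6, summed over both eyelids) — meibomian-gland
  loss; *below* threshold = good.
* NIBUT (non-invasive tear break-up time, s) — lipid-phase stability; above
  threshold = good.

Values sitting exactly on a threshold are classified as poor control by
default (the conservative convention); set
``ControlThresholds(boundary_is_good=True)`` for the inclusive reading.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Side",
    "Sex",
    "DurationBand",
    "DrugClass",
    "TherapyLine",
    "EyeRecord",
    "ControlThresholds",
    "ControlStatus",
    "CohortSummary",
    "ValidationError",
    "CohortFormatError",
    "classify_control",
    "summarize_cohort",
    "read_cohort",
    "write_cohort",
    "round_percent",
    "COHORT_COLUMNS",
]


class Side(str, Enum):
    LEFT = "left"
    RIGHT = "right"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class DurationBand(str, Enum):
    """Disease duration: under 1 year, 1–5 years, 5–10 years."""

    LT1Y = "lt1y"
    Y1TO5 = "1to5y"
    Y5TO10 = "5to10y"


class DrugClass(str, Enum):
    PG = "PG"  # prostaglandin analogues
    BB = "BB"  # beta-blockers
    CAI = "CAI"  # carbonic anhydrase inhibitors
    A2A = "A2A"  # alpha-2 adrenergic agonists
    ARTIFICIAL_TEARS = "artificial_tears"


GLAUCOMA_CLASSES: tuple[DrugClass, ...] = (
    DrugClass.PG,
    DrugClass.BB,
    DrugClass.CAI,
    DrugClass.A2A,
)

# canonical ordering used for combination labels ("PG+BB+CAI" etc.)
_CLASS_ORDER = {DrugClass.PG: 0, DrugClass.BB: 1, DrugClass.CAI: 2, DrugClass.A2A: 3}

# age bands used in cohort summaries (per-eye tallies)
AGE_BANDS: tuple[tuple[str, int, int], ...] = (
    ("<50", 0, 49),
    ("50-60", 50, 60),
    ("61-70", 61, 70),
    ("71-80", 71, 80),
    (">80", 81, 200),
)


class ValidationError(ValueError):
    """A record or parameter violates a model invariant; names the field."""


class CohortFormatError(ValueError):
    """A cohort file row could not be parsed; carries row number and field."""

    def __init__(self, row: int, fieldname: str, message: str):
        self.row = row
        self.fieldname = fieldname
        super().__init__(f"row {row}, field '{fieldname}': {message}")


@dataclass(frozen=True)
class TherapyLine:
    """One prescribed product for one eye."""

    inn: str
    drug_class: DrugClass
    preservative_free: bool
    doses_per_day: float
    product_ref: str

    def __post_init__(self) -> None:
        if self.doses_per_day <= 0:
            raise ValidationError("doses_per_day must be > 0")


@dataclass(frozen=True)
class EyeRecord:
    """One affected eye: demographics, glaucoma therapy, tear-film measurements.

    ``therapies`` holds the glaucoma lines only (at least one); supplemental
    artificial tears are recorded separately as a flag plus yearly cost.
    ``preservative_free`` is derived: an eye counts as preservative-free only
    when *all* its glaucoma lines are preservative-free.
    """

    eye_id: str
    patient_id: str
    side: Side
    sex: Sex
    age_years: int
    duration_band: DurationBand
    therapies: tuple[TherapyLine, ...]
    artificial_tears: bool
    artificial_tears_yearly_cost_bgn: float
    st_mm: float
    tms_score: int
    nibut_s: float

    @property
    def preservative_free(self) -> bool:
        return all(line.preservative_free for line in self.therapies)

    @property
    def n_glaucoma_lines(self) -> int:
        return len(self.therapies)

    @property
    def is_monotherapy(self) -> bool:
        return self.n_glaucoma_lines == 1

    @property
    def combo_label(self) -> str:
        """Canonical '+'-joined class label, e.g. ``PG+BB+CAI``."""
        classes = sorted({line.drug_class for line in self.therapies}, key=_CLASS_ORDER.get)
        return "+".join(c.value for c in classes)


def validate_record(record: EyeRecord, study_mode: bool = False) -> None:
    """Raise :class:`ValidationError` naming the offending field.

    ``study_mode`` additionally enforces the study inclusion window of
    30–85 years of age.
    """
    if not record.therapies:
        raise ValidationError("therapies: at least one glaucoma line required")
    for line in record.therapies:
        if line.drug_class not in GLAUCOMA_CLASSES:
            raise ValidationError(
                f"therapies: drug_class {line.drug_class.value!r} is not a glaucoma class"
            )
    if record.age_years < 0:
        raise ValidationError("age_years: must be >= 0")
    if study_mode and not (30 <= record.age_years <= 85):
        raise ValidationError("age_years: outside study inclusion window 30-85")
    for name in ("st_mm", "nibut_s", "tms_score"):
        value = getattr(record, name)
        if value is None:
            raise ValidationError(f"{name}: missing measurement")
    if record.st_mm < 0:
        raise ValidationError("st_mm: must be >= 0")
    if record.nibut_s < 0:
        raise ValidationError("nibut_s: must be >= 0")
    if not (0 <= int(record.tms_score) <= 6):
        raise ValidationError("tms_score: must be in 0..6")
    if record.artificial_tears_yearly_cost_bgn < 0:
        raise ValidationError("artificial_tears_yearly_cost_bgn: must be >= 0")
    if not record.artificial_tears and record.artificial_tears_yearly_cost_bgn != 0:
        raise ValidationError(
            "artificial_tears_yearly_cost_bgn: must be 0 when artificial_tears is false"
        )


@dataclass(frozen=True)
class ControlThresholds:
    """Good-control cut-offs: ST > 10 mm, TMS < 3, NIBUT > 14 s by default."""

    st_threshold_mm: float = 10.0
    tms_threshold: float = 3.0
    nibut_threshold_s: float = 14.0
    boundary_is_good: bool = False

    def __post_init__(self) -> None:
        if min(self.st_threshold_mm, self.tms_threshold, self.nibut_threshold_s) <= 0:
            raise ValidationError("thresholds must all be > 0")


@dataclass(frozen=True)
class ControlStatus:
    st_good: bool
    tms_good: bool
    nibut_good: bool

    @property
    def overall_good(self) -> bool:
        """Effectiveness = good control on all three indicators at once."""
        return self.st_good and self.tms_good and self.nibut_good


def classify_control(
    record: EyeRecord, thresholds: ControlThresholds | None = None
) -> ControlStatus:
    """Dichotomize the three tear-film measurements against the thresholds.

    ST and NIBUT are good above their thresholds, TMS below its threshold;
    boundary values are poor unless ``thresholds.boundary_is_good``.
    """
    t = thresholds or ControlThresholds()
    validate_record(record)
    if t.boundary_is_good:
        return ControlStatus(
            st_good=record.st_mm >= t.st_threshold_mm,
            tms_good=record.tms_score <= t.tms_threshold,
            nibut_good=record.nibut_s >= t.nibut_threshold_s,
        )
    return ControlStatus(
        st_good=record.st_mm > t.st_threshold_mm,
        tms_good=record.tms_score < t.tms_threshold,
        nibut_good=record.nibut_s > t.nibut_threshold_s,
    )


def round_percent(count: int, denom: int) -> float:
    """100 × count/denom, half-up rounded to one decimal."""
    if denom <= 0:
        raise ValidationError("denominator must be positive")
    exact = Decimal(100 * count) / Decimal(denom)
    return float(exact.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class CohortSummary:
    """Counts (and derived percentages) for the standard cohort tabulations.

    ``indicators`` holds tallies that each partition ``n_eyes`` (sex, age
    band, side, duration, per-test control).  Therapy strata cross
    preservative status with mono/combination; ``mono_class_counts`` and
    ``combo_type_counts`` are conditional on the mono / combination subsets.
    """

    n_eyes: int
    indicators: dict[str, dict[str, int]]
    therapy_strata: dict[str, dict[str, int]]  # {"free"|"nonfree": {"mono": n, "combination": n}}
    mono_class_counts: dict[str, int]
    combo_type_counts: dict[str, int]

    # --- denominators -----------------------------------------------------
    @property
    def n_free(self) -> int:
        return sum(self.therapy_strata["free"].values())

    @property
    def n_nonfree(self) -> int:
        return sum(self.therapy_strata["nonfree"].values())

    @property
    def n_mono(self) -> int:
        return self.therapy_strata["free"]["mono"] + self.therapy_strata["nonfree"]["mono"]

    @property
    def n_combination(self) -> int:
        return (
            self.therapy_strata["free"]["combination"]
            + self.therapy_strata["nonfree"]["combination"]
        )

    # --- shares -----------------------------------------------------------
    def fraction(self, indicator: str, level: str) -> float:
        return self.indicators[indicator][level] / self.n_eyes

    def percent(self, indicator: str, level: str) -> float:
        return round_percent(self.indicators[indicator][level], self.n_eyes)

    def mono_share_within(self, arm: str) -> float:
        """Percent of the arm ('free' | 'nonfree') on monotherapy."""
        stratum = self.therapy_strata[arm]
        return round_percent(stratum["mono"], sum(stratum.values()))

    def mono_class_percent(self, drug_class: str) -> float:
        return round_percent(self.mono_class_counts.get(drug_class, 0), self.n_mono)

    def combo_type_percent(self, label: str) -> float:
        return round_percent(self.combo_type_counts.get(label, 0), self.n_combination)

    def percentages(self) -> dict[str, dict[str, float]]:
        """All indicator tallies as one-decimal percentages of n_eyes."""
        return {
            ind: {lvl: round_percent(c, self.n_eyes) for lvl, c in levels.items()}
            for ind, levels in self.indicators.items()
        }

    def to_dict(self) -> dict:
        return {
            "n_eyes": self.n_eyes,
            "indicators": self.indicators,
            "percentages": self.percentages(),
            "therapy_strata": self.therapy_strata,
            "mono_class_counts": self.mono_class_counts,
            "combo_type_counts": self.combo_type_counts,
        }


def _age_band(age: int) -> str:
    for label, lo, hi in AGE_BANDS:
        if lo <= age <= hi:
            return label
    raise ValidationError(f"age_years: {age} outside supported bands")


def summarize_cohort(
    records: Sequence[EyeRecord], thresholds: ControlThresholds | None = None
) -> CohortSummary:
    """Tally the cohort into the standard demographic/control/prescribing tables."""
    if not records:
        raise ValidationError("empty cohort")
    t = thresholds or ControlThresholds()

    indicators: dict[str, dict[str, int]] = {
        "sex": {s.value: 0 for s in Sex},
        "age_band": {label: 0 for label, _, _ in AGE_BANDS},
        "side": {s.value: 0 for s in Side},
        "duration": {d.value: 0 for d in DurationBand},
        "st_control": {"good": 0, "poor": 0},
        "tms_control": {"good": 0, "poor": 0},
        "nibut_control": {"good": 0, "poor": 0},
        "overall_control": {"good": 0, "poor": 0},
        "preservative": {"free": 0, "nonfree": 0},
        "therapy_type": {"mono": 0, "combination": 0},
    }
    strata = {
        "free": {"mono": 0, "combination": 0},
        "nonfree": {"mono": 0, "combination": 0},
    }
    mono_classes: dict[str, int] = {}
    combo_types: dict[str, int] = {}

    for rec in records:
        validate_record(rec)
        status = classify_control(rec, t)
        indicators["sex"][rec.sex.value] += 1
        indicators["age_band"][_age_band(rec.age_years)] += 1
        indicators["side"][rec.side.value] += 1
        indicators["duration"][rec.duration_band.value] += 1
        indicators["st_control"]["good" if status.st_good else "poor"] += 1
        indicators["tms_control"]["good" if status.tms_good else "poor"] += 1
        indicators["nibut_control"]["good" if status.nibut_good else "poor"] += 1
        indicators["overall_control"]["good" if status.overall_good else "poor"] += 1
        arm = "free" if rec.preservative_free else "nonfree"
        kind = "mono" if rec.is_monotherapy else "combination"
        indicators["preservative"][arm] += 1
        indicators["therapy_type"][kind] += 1
        strata[arm][kind] += 1
        if rec.is_monotherapy:
            cls = rec.therapies[0].drug_class.value
            mono_classes[cls] = mono_classes.get(cls, 0) + 1
        else:
            label = rec.combo_label
            combo_types[label] = combo_types.get(label, 0) + 1

    return CohortSummary(
        n_eyes=len(records),
        indicators=indicators,
        therapy_strata=strata,
        mono_class_counts=mono_classes,
        combo_type_counts=combo_types,
    )


# ---------------------------------------------------------------------------
# Cohort file I/O
#
# CSV, UTF-8, '.' decimal separator.  Therapy lines are packed into a single
# column as ';'-joined 'class:inn:doses_per_day:product_ref' entries.
# ---------------------------------------------------------------------------

COHORT_COLUMNS = [
    "eye_id",
    "patient_id",
    "side",
    "sex",
    "age_years",
    "duration_band",
    "st_mm",
    "tms_score",
    "nibut_s",
    "preservative_free",
    "artificial_tears",
    "artificial_tears_yearly_cost_bgn",
    "therapies",
]


def _parse_bool(raw: str) -> bool:
    low = raw.strip().lower()
    if low in ("true", "1", "yes"):
        return True
    if low in ("false", "0", "no"):
        return False
    raise ValueError(f"not a boolean: {raw!r}")


def _format_therapies(lines: Iterable[TherapyLine]) -> str:
    return ";".join(
        f"{l.drug_class.value}:{l.inn}:{l.doses_per_day!r}:{l.product_ref}" for l in lines
    )


def _parse_therapies(raw: str) -> tuple[TherapyLine, ...]:
    lines = []
    for part in raw.split(";"):
        if not part.strip():
            continue
        bits = part.split(":")
        if len(bits) != 4:
            raise ValueError(f"therapy entry {part!r} is not class:inn:doses:product_ref")
        cls, inn, doses, ref = (b.strip() for b in bits)
        lines.append(
            TherapyLine(
                inn=inn,
                drug_class=DrugClass(cls),
                preservative_free=True,  # placeholder, fixed up below
                doses_per_day=float(doses),
                product_ref=ref,
            )
        )
    return tuple(lines)


def read_cohort(path: str | Path, study_mode: bool = False) -> list[EyeRecord]:
    """Read a cohort CSV; malformed rows raise :class:`CohortFormatError`.

    The per-line preservative flag is taken from the price-list-facing
    ``preservative_free`` column applied uniformly: mixed-preservative eyes
    must encode the non-free status at eye level (an eye is preservative-free
    only if all its lines are).
    """
    records: list[EyeRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise CohortFormatError(1, "header", "file is empty")
        missing = set(COHORT_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise CohortFormatError(1, ",".join(sorted(missing)), "missing column(s)")
        for i, row in enumerate(reader, start=2):
            records.append(_record_from_row(row, i, study_mode))
    return records


def _record_from_row(row: dict, rownum: int, study_mode: bool) -> EyeRecord:
    def get(fieldname: str, conv):
        raw = row.get(fieldname)
        if raw is None or raw == "":
            raise CohortFormatError(rownum, fieldname, "missing value")
        try:
            return conv(raw)
        except (ValueError, KeyError) as exc:
            raise CohortFormatError(rownum, fieldname, str(exc)) from exc

    eye_pf = get("preservative_free", _parse_bool)
    raw_lines = get("therapies", _parse_therapies)
    if not raw_lines:
        raise CohortFormatError(rownum, "therapies", "at least one glaucoma line required")
    lines = tuple(
        TherapyLine(
            inn=l.inn,
            drug_class=l.drug_class,
            preservative_free=eye_pf,
            doses_per_day=l.doses_per_day,
            product_ref=l.product_ref,
        )
        for l in raw_lines
    )
    try:
        record = EyeRecord(
            eye_id=get("eye_id", str),
            patient_id=get("patient_id", str),
            side=get("side", Side),
            sex=get("sex", Sex),
            age_years=get("age_years", int),
            duration_band=get("duration_band", DurationBand),
            therapies=lines,
            artificial_tears=get("artificial_tears", _parse_bool),
            artificial_tears_yearly_cost_bgn=get("artificial_tears_yearly_cost_bgn", float),
            st_mm=get("st_mm", float),
            tms_score=get("tms_score", int),
            nibut_s=get("nibut_s", float),
        )
        validate_record(record, study_mode=study_mode)
    except ValidationError as exc:
        fieldname = str(exc).split(":", 1)[0]
        raise CohortFormatError(rownum, fieldname, str(exc)) from exc
    return record


def write_cohort(records: Sequence[EyeRecord], path: str | Path) -> None:
    """Write records in the cohort CSV schema (round-trips with read_cohort)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COHORT_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.eye_id,
                    rec.patient_id,
                    rec.side.value,
                    rec.sex.value,
                    rec.age_years,
                    rec.duration_band.value,
                    repr(rec.st_mm),
                    rec.tms_score,
                    repr(rec.nibut_s),
                    str(rec.preservative_free).lower(),
                    str(rec.artificial_tears).lower(),
                    repr(rec.artificial_tears_yearly_cost_bgn),
                    _format_therapies(rec.therapies),
                ]
            )
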