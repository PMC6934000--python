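"""Yearly pharmacotherapy costing, payer/patient split, and cost summaries.

The yearly cost of a therapy line is the prescribed regimen priced
continuously: ``doses_per_day x year_days / doses_per_pack x pack_price``,
rounded to 0.01 BGN ("prorated" dispensing).  Real dispensing rounds partial
packs up, so a "whole_packs" mode is also provided.  Glaucoma therapy is
reimbursed at a configurable rate (50% by default); artificial-tears therapy
for the dry eye is never reimbursed, so its full cost falls on the patient.

All computation is in BGN; euros are display-only at a fixed 1 BGN = 0.51 EUR.
"""

from __future__ import annotations

import csv
import importlib.resources
import math
import statistics
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

from .cohort import DrugClass, EyeRecord, TherapyLine, ValidationError

__all__ = [
    "DrugProduct",
    "PaymentSplit",
    "ArmStats",
    "CostSummary",
    "UnknownProductError",
    "round_bgn",
    "to_eur",
    "yearly_line_cost",
    "eye_yearly_cost",
    "split_payment",
    "summarize_costs",
    "read_price_list",
    "default_price_list",
    "EUR_PER_BGN",
]

EUR_PER_BGN = 0.51


def round_bgn(x: float) -> float:
    """Round money to 0.01 BGN, half-up (not banker's)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def to_eur(bgn: float) -> float:
    """Display-only conversion at the fixed study exchange rate."""
    return round_bgn(bgn * EUR_PER_BGN)


class UnknownProductError(KeyError):
    pass


@dataclass(frozen=True)
class DrugProduct:
    product_id: str
    inn: str
    drug_class: DrugClass
    preservative_free: bool
    pack_price_bgn: float
    doses_per_pack: int

    def __post_init__(self) -> None:
        if self.pack_price_bgn < 0:
            raise ValidationError("pack_price_bgn: must be >= 0")
        if self.doses_per_pack < 1:
            raise ValidationError("doses_per_pack: must be >= 1")


PriceList = Mapping[str, DrugProduct]


def yearly_line_cost(
    line: TherapyLine,
    product: DrugProduct,
    year_days: int = 365,
    dispensing: str = "prorated",
) -> float:
    """Yearly cost of one therapy line in BGN.

    prorated: doses/day x year_days / doses_per_pack x pack_price.
    whole_packs: packs started are paid in full (ceiling on pack count).
    """
    if line.product_ref != product.product_id:
        raise UnknownProductError(
            f"line {line.inn!r}: product_ref {line.product_ref!r} "
            f"does not match product {product.product_id!r}"
        )
    doses_per_year = line.doses_per_day * year_days
    if dispensing == "prorated":
        cost = doses_per_year / product.doses_per_pack * product.pack_price_bgn
    elif dispensing == "whole_packs":
        cost = math.ceil(doses_per_year / product.doses_per_pack) * product.pack_price_bgn
    else:
        raise ValidationError(f"dispensing: unknown mode {dispensing!r}")
    return round_bgn(cost)


def eye_yearly_cost(
    record: EyeRecord,
    prices: PriceList,
    year_days: int = 365,
    dispensing: str = "prorated",
) -> tuple[float, float]:
    """(glaucoma_cost, dry_eye_cost) for one eye, each rounded to 0.01 BGN.

    The glaucoma cost sums the per-line costs; the dry-eye cost is the
    recorded artificial-tears yearly cost (0 when the eye has none).
    """
    glaucoma = 0.0
    for line in record.therapies:
        product = prices.get(line.product_ref)
        if product is None:
            raise UnknownProductError(
                f"line {line.inn!r}: unknown product_ref {line.product_ref!r}"
            )
        glaucoma += yearly_line_cost(line, product, year_days, dispensing)
    dry_eye = record.artificial_tears_yearly_cost_bgn if record.artificial_tears else 0.0
    return round_bgn(glaucoma), round_bgn(dry_eye)


@dataclass(frozen=True)
class PaymentSplit:
    """Money conservation holds exactly: reimbursed + copay == total."""

    total: float
    reimbursed: float
    copay: float

    def __post_init__(self) -> None:
        if min(self.total, self.reimbursed, self.copay) < 0:
            raise ValidationError("payment components must be >= 0")
        if round_bgn(self.reimbursed + self.copay) != round_bgn(self.total):
            raise ValidationError("reimbursed + copay must equal total")


def split_payment(
    glaucoma_cost: float, dry_eye_cost: float, reimbursement_rate: float = 0.5
) -> PaymentSplit:
    """Split the yearly cost between payer and patient.

    Only glaucoma therapy is reimbursed (at ``reimbursement_rate``); the
    dry-eye cost is fully out of pocket.  Rounding is reconciled
    largest-remainder style: the reimbursed share is rounded half-up and the
    copay absorbs the remainder so the split sums exactly to the total.
    """
    if glaucoma_cost < 0 or dry_eye_cost < 0:
        raise ValidationError("costs must be >= 0")
    if not (0 <= reimbursement_rate <= 1):
        raise ValidationError("reimbursement_rate must be in [0, 1]")
    total = round_bgn(glaucoma_cost + dry_eye_cost)
    reimbursed = round_bgn(reimbursement_rate * glaucoma_cost)
    copay = round_bgn(total - reimbursed)
    return PaymentSplit(total=total, reimbursed=reimbursed, copay=copay)


@dataclass(frozen=True)
class ArmStats:
    n: int
    median: float
    sd: float | None  # sample SD (n-1 denominator); absent for n < 2


@dataclass(frozen=True)
class CostSummary:
    """Median/SD of yearly costs, overall and by preservative arm.

    Arms with no eyes are reported as ``None`` (absent), never as zero.
    ``dry_eye`` covers eyes with an artificial-tears line only.
    """

    glaucoma_overall: ArmStats | None
    glaucoma_free: ArmStats | None
    glaucoma_nonfree: ArmStats | None
    dry_eye: ArmStats | None

    def to_dict(self) -> dict:
        def enc(stats: ArmStats | None) -> dict | None:
            if stats is None:
                return None
            return {"n": stats.n, "median": stats.median, "sd": stats.sd}

        return {
            "glaucoma_overall": enc(self.glaucoma_overall),
            "glaucoma_free": enc(self.glaucoma_free),
            "glaucoma_nonfree": enc(self.glaucoma_nonfree),
            "dry_eye": enc(self.dry_eye),
        }


def _arm_stats(values: Sequence[float]) -> ArmStats | None:
    if not values:
        return None
    med = float(statistics.median(values))  # even n: midpoint mean
    sd = float(statistics.stdev(values)) if len(values) >= 2 else None
    return ArmStats(n=len(values), median=round_bgn(med), sd=None if sd is None else round_bgn(sd))


def summarize_costs(
    records: Sequence[EyeRecord],
    prices: PriceList,
    year_days: int = 365,
    dispensing: str = "prorated",
) -> CostSummary:
    if not records:
        raise ValidationError("empty cohort")
    glaucoma: list[float] = []
    free: list[float] = []
    nonfree: list[float] = []
    tears: list[float] = []
    for rec in records:
        g, d = eye_yearly_cost(rec, prices, year_days, dispensing)
        glaucoma.append(g)
        (free if rec.preservative_free else nonfree).append(g)
        if rec.artificial_tears:
            tears.append(d)
    return CostSummary(
        glaucoma_overall=_arm_stats(glaucoma),
        glaucoma_free=_arm_stats(free),
        glaucoma_nonfree=_arm_stats(nonfree),
        dry_eye=_arm_stats(tears),
    )


# ---------------------------------------------------------------------------
# Price list I/O
# ---------------------------------------------------------------------------

PRICE_COLUMNS = [
    "product_id",
    "inn",
    "drug_class",
    "preservative_free",
    "pack_price_bgn",
    "doses_per_pack",
]


def read_price_list(path: str | Path) -> dict[str, DrugProduct]:
    prices: dict[str, DrugProduct] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(PRICE_COLUMNS) - set(reader.fieldnames):
            raise ValidationError(f"price list {path}: missing columns {PRICE_COLUMNS}")
        for row in reader:
            product = DrugProduct(
                product_id=row["product_id"].strip(),
                inn=row["inn"].strip(),
                drug_class=DrugClass(row["drug_class"].strip()),
                preservative_free=row["preservative_free"].strip().lower() in ("true", "1", "yes"),
                pack_price_bgn=float(row["pack_price_bgn"]),
                doses_per_pack=int(row["doses_per_pack"]),
            )
            if product.product_id in prices:
                raise ValidationError(f"duplicate product_id {product.product_id!r}")
            prices[product.product_id] = product
    return prices


def product_for(
    prices: PriceList, drug_class: DrugClass, preservative_free: bool
) -> DrugProduct:
    """First product (by product_id) matching class and preservative status."""
    candidates = sorted(
        (
            p
            for p in prices.values()
            if p.drug_class is drug_class and p.preservative_free == preservative_free
        ),
        key=lambda p: p.product_id,
    )
    if not candidates:
        raise UnknownProductError(
            f"price list has no product for class {drug_class.value!r}, "
            f"preservative_free={preservative_free}"
        )
    return candidates[0]


def default_price_list() -> dict[str, DrugProduct]:
    """The bundled example price list.

    Latanoprost pack prices are the national register prices (50.40 BGN
    preservative-free, 23.50 BGN preserved); every other price and all pack
    sizes are illustrative fixture values, since registers list prices per
    pack, not per drop.
    """
    resource = importlib.resources.files("glaucoma_cea").joinpath("data/default_prices.csv")
    with importlib.resources.as_file(resource) as path:
        return read_price_list(path)
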