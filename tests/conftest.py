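import numpy as np
import pytest

from glaucoma_cea import calibration
from glaucoma_cea.cohort import (
    DrugClass,
    DurationBand,
    EyeRecord,
    Sex,
    Side,
    TherapyLine,
)
from glaucoma_cea.costing import default_price_list, product_for
from glaucoma_cea.tree import Branch, ChanceNode, DecisionTree, StrategyNode, TerminalNode


@pytest.fixture(scope="session")
def prices():
    return default_price_list()


@pytest.fixture(scope="session")
def reference_records(prices):
    return calibration.reference_cohort(prices)


@pytest.fixture
def make_record(prices):
    """Factory for a valid eye record with overridable measurements/therapy."""

    counter = {"i": 0}

    def build(
        st_mm=12.0,
        tms_score=2,
        nibut_s=15.0,
        classes=("PG",),
        preservative_free=True,
        doses_per_day=1.0,
        tears_cost=179.93,
        age_years=65,
    ):
        counter["i"] += 1
        lines = tuple(
            TherapyLine(
                inn=(p := product_for(prices, DrugClass(c), preservative_free)).inn,
                drug_class=DrugClass(c),
                preservative_free=preservative_free,
                doses_per_day=doses_per_day,
                product_ref=p.product_id,
            )
            for c in classes
        )
        return EyeRecord(
            eye_id=f"t{counter['i']:04d}",
            patient_id=f"tp{counter['i']:04d}",
            side=Side.LEFT,
            sex=Sex.FEMALE,
            age_years=age_years,
            duration_band=DurationBand.Y1TO5,
            therapies=lines,
            artificial_tears=tears_cost > 0,
            artificial_tears_yearly_cost_bgn=tears_cost,
            st_mm=st_mm,
            tms_score=tms_score,
            nibut_s=nibut_s,
        )

    return build


def random_tree(rng: np.random.Generator, max_depth: int = 4) -> DecisionTree:
    """A random two-strategy tree with valid probabilities and payoffs."""

    def node(depth: int):
        if depth >= max_depth or rng.random() < 0.35:
            return TerminalNode(
                label=f"leaf{rng.integers(1_000_000)}",
                cost=float(rng.uniform(0, 1000)),
                effect=float(rng.uniform(-2, 5)),
            )
        k = int(rng.integers(2, 4))
        weights = rng.uniform(0.05, 1.0, size=k)
        probs = weights / weights.sum()
        return ChanceNode(
            label=f"node{rng.integers(1_000_000)}",
            branches=[Branch(float(p), node(depth + 1)) for p in probs],
        )

    return DecisionTree(
        strategies=[
            StrategyNode(label="A", root=node(1)),
            StrategyNode(label="B", root=node(1)),
        ]
    )
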