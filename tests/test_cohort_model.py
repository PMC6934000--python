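"""Eye-record validation, control classification, cohort summaries, CSV I/O."""

import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from glaucoma_cea.cohort import (
    CohortFormatError,
    ControlThresholds,
    ValidationError,
    classify_control,
    read_cohort,
    round_percent,
    summarize_cohort,
    write_cohort,
)
from glaucoma_cea.synthetic import CohortConfig, generate_cohort


@pytest.mark.parametrize(
    "st_mm,tms,nibut,expect",
    [
        (12.0, 2, 15.0, (True, True, True)),  # strictly good on all three
        (9.0, 4, 10.0, (False, False, False)),  # strictly poor on all three
        (10.0, 3, 14.0, (False, False, False)),  # boundary values are poor
    ],
)
def test_classify_control_examples(make_record, st_mm, tms, nibut, expect):
    status = classify_control(make_record(st_mm=st_mm, tms_score=tms, nibut_s=nibut))
    assert (status.st_good, status.tms_good, status.nibut_good) == expect
    assert status.overall_good == all(expect)


def test_boundary_convention_is_configurable(make_record):
    rec = make_record(st_mm=10.0, tms_score=3, nibut_s=14.0)
    inclusive = classify_control(rec, ControlThresholds(boundary_is_good=True))
    assert inclusive.st_good and inclusive.tms_good and inclusive.nibut_good


def test_missing_measurement_names_field(make_record):
    rec = make_record()
    broken = rec.__class__(**{**rec.__dict__, "nibut_s": None})
    with pytest.raises(ValidationError, match="nibut_s"):
        classify_control(broken)


@settings(
    max_examples=100,
    deadline=None,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
@given(
    st_mm=st.floats(0, 30, allow_nan=False),
    tms=st.integers(0, 6),
    nibut=st.floats(0, 30, allow_nan=False),
    bump=st.floats(0.001, 10, allow_nan=False),
)
def test_classify_control_monotone(make_record, st_mm, tms, nibut, bump):
    """Raising ST or NIBUT, or lowering TMS, never flips a good flag to poor."""
    base = classify_control(make_record(st_mm=st_mm, tms_score=tms, nibut_s=nibut))
    better = classify_control(
        make_record(st_mm=st_mm + bump, tms_score=max(0, tms - 1), nibut_s=nibut + bump)
    )
    assert better.st_good >= base.st_good
    assert better.tms_good >= base.tms_good
    assert better.nibut_good >= base.nibut_good


def test_summary_reproduces_reported_counts(reference_records):
    summary = summarize_cohort(reference_records)
    assert summary.n_eyes == 64
    assert summary.therapy_strata == {
        "free": {"mono": 14, "combination": 6},
        "nonfree": {"mono": 20, "combination": 24},
    }
    assert summary.mono_share_within("free") == 70.0
    assert summary.mono_class_percent("PG") == 73.5
    assert summary.mono_class_percent("BB") == 26.5
    assert summary.combo_type_counts == {
        "PG+BB": 6,
        "BB+CAI": 8,
        "PG+CAI": 5,
        "CAI+A2A": 2,
        "PG+BB+CAI": 9,
    }
    assert summary.indicators["sex"] == {"male": 25, "female": 39}
    assert summary.indicators["side"] == {"left": 30, "right": 34}


@pytest.mark.parametrize("n_eyes,seed", [(50, 1), (200, 2), (1000, 3)])
def test_summary_counts_match_brute_force(n_eyes, seed):
    """summarize_cohort equals an independent filter-and-count tally."""
    records = generate_cohort(CohortConfig(n_eyes=n_eyes, seed=seed))
    summary = summarize_cohort(records)
    thresholds = ControlThresholds()
    # independent oracle: direct filters over the record list
    assert summary.indicators["sex"]["female"] == sum(
        r.sex.value == "female" for r in records
    )
    assert summary.indicators["st_control"]["good"] == sum(
        r.st_mm > thresholds.st_threshold_mm for r in records
    )
    assert summary.indicators["tms_control"]["good"] == sum(
        r.tms_score < thresholds.tms_threshold for r in records
    )
    assert summary.therapy_strata["free"]["mono"] == sum(
        r.preservative_free and len(r.therapies) == 1 for r in records
    )
    for indicator, levels in summary.indicators.items():
        assert sum(levels.values()) == n_eyes, indicator


def test_single_record_cohort_is_its_own_stratum(make_record):
    summary = summarize_cohort([make_record(classes=("PG",), preservative_free=True)])
    assert summary.n_eyes == 1
    assert summary.mono_share_within("free") == 100.0
    assert summary.mono_class_percent("PG") == 100.0


def test_empty_cohort_rejected():
    with pytest.raises(ValidationError, match="empty cohort"):
        summarize_cohort([])


def test_percent_rounding_is_half_up():
    assert round_percent(25, 34) == 73.5  # 73.529...
    assert round_percent(49, 64) == 76.6  # 76.5625
    assert round_percent(20, 64) == 31.3  # 31.25 rounds half up


def test_cohort_csv_round_trip(tmp_path, reference_records):
    path = tmp_path / "cohort.csv"
    write_cohort(reference_records, path)
    again = read_cohort(path)
    assert again == reference_records
    # write(read(f)) is stable byte-for-byte
    path2 = tmp_path / "cohort2.csv"
    write_cohort(again, path2)
    assert path.read_bytes() == path2.read_bytes()


def test_invalid_row_names_field_and_row(tmp_path, reference_records, make_record):
    path = tmp_path / "cohort.csv"
    bad = reference_records[:1] + [make_record(tms_score=5)]
    write_cohort(bad, path)
    text = path.read_text().replace(",5,", ",7,")  # tms_score 7 violates 0..6
    path.write_text(text)
    with pytest.raises(CohortFormatError, match="tms_score") as err:
        read_cohort(path)
    assert err.value.row == 3


def test_header_only_file_yields_empty_cohort(tmp_path, reference_records):
    path = tmp_path / "cohort.csv"
    write_cohort(reference_records[:0], path)
    assert read_cohort(path) == []
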