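"""Curation: test specs, filtering, imputation, normalisation, splits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import full_grid_subject, make_cohort_frame, make_sequence
from neurocast.curation import (
    HIGHER_IS_BETTER,
    LOWER_IS_BETTER,
    TEST_NAMES,
    build_diagnosis_dataset,
    build_forecast_dataset,
    default_test_specs,
    denormalize_scores,
    extract_sequences,
    impute_sequence,
    normalize_scores,
    spec_for,
)
from neurocast.errors import DataError
from neurocast.synthetic import GeneratorConfig, generate_cohort


def test_default_specs_match_published_cutoffs():
    specs = {s.name: s for s in default_test_specs()}
    assert len(specs) == 5
    mmse = specs["MMSE"]
    assert (mmse.min_score, mmse.max_score, mmse.normal_cutoff) == (0, 30, 28)
    assert mmse.direction == HIGHER_IS_BETTER and mmse.norm_divisor == 30
    adas13 = specs["ADAS13"]
    assert (adas13.min_score, adas13.max_score, adas13.normal_cutoff) == (0, 85, 13)
    assert adas13.direction == LOWER_IS_BETTER and adas13.norm_divisor == 85
    assert (specs["ADASQ4"].max_score, specs["ADASQ4"].normal_cutoff) == (10, 5)
    assert (specs["ADAS11"].max_score, specs["ADAS11"].normal_cutoff) == (70, 10)
    assert (specs["FAQ"].max_score, specs["FAQ"].normal_cutoff) == (30, 2)
    for s in specs.values():
        assert s.norm_divisor == s.max_score


@pytest.mark.parametrize(
    "test,raw,expected",
    [("MMSE", 30, 1.0), ("FAQ", 0, 0.0), ("ADAS13", 17, 0.2)],
)
def test_normalization_examples(test, raw, expected):
    assert normalize_scores([raw], spec_for(test))[0] == pytest.approx(expected)


def test_normalization_rejects_out_of_range():
    with pytest.raises(ValueError):
        normalize_scores([31], spec_for("MMSE"))


@given(st.lists(st.integers(0, 85), min_size=1, max_size=20))
@settings(deadline=None, derandomize=True)
def test_normalize_denormalize_round_trip(values):
    spec = spec_for("ADAS13")
    back = denormalize_scores(normalize_scores(values, spec), spec)
    assert np.allclose(back, values, rtol=1e-12, atol=0)


def test_extract_keeps_fully_observed_subject_at_all_lengths():
    recs = full_grid_subject("A", {t: [20] * 8 for t in TEST_NAMES})
    cohort = make_cohort_frame(recs)
    for length in (4, 6, 8):
        seqs = extract_sequences(cohort, "FAQ", length)
        assert [s.subject_id for s in seqs] == ["A"]
        assert seqs[0].length == length


def test_extract_drops_more_than_two_missing():
    vals = [20, None, None, None, 20, 20, 20, 20]
    cohort = make_cohort_frame(full_grid_subject("A", {"FAQ": vals}))
    assert extract_sequences(cohort, "FAQ", 6) == []


def test_extract_drops_missing_final_visit():
    vals = [20, 20, 20, None, 20, 20, 20, 20]
    cohort = make_cohort_frame(full_grid_subject("A", {"FAQ": vals}))
    assert extract_sequences(cohort, "FAQ", 4) == []  # month 24 is final
    assert len(extract_sequences(cohort, "FAQ", 6)) == 1


def test_extract_counts_absent_visits_as_missing():
    recs = [r for r in full_grid_subject("A", {"FAQ": [20] * 8}) if r["month"] != 12]
    cohort = make_cohort_frame(recs)
    seqs = extract_sequences(cohort, "FAQ", 4)
    assert len(seqs) == 1
    assert np.isnan(seqs[0].values[2])


def test_extract_require_final_dx():
    recs = full_grid_subject("A", {"FAQ": [20] * 8}, dx="CN")
    for r in recs:
        if r["month"] == 24:
            r["DX"] = np.nan
    cohort = make_cohort_frame(recs)
    assert extract_sequences(cohort, "FAQ", 4, require_final_dx=True) == []
    assert len(extract_sequences(cohort, "FAQ", 4, require_final_dx=False)) == 1


def test_extract_rejects_unknown_test():
    cohort = make_cohort_frame(full_grid_subject("A", {"FAQ": [1] * 8}))
    with pytest.raises(KeyError):
        extract_sequences(cohort, "CDRSB", 4)


@pytest.mark.parametrize(
    "values,expected",
    [
        ([10, 20, None, 30], [10, 20, 20, 30]),
        ([28, 29, 27], [28, 29, 27]),
        ([4, None, None, 8, 6, 2], [4, 5, 5, 8, 6, 2]),
    ],
)
def test_imputation_worked_examples(values, expected):
    out = impute_sequence(make_sequence(values))
    assert np.allclose(out.values, expected)


def test_two_gap_imputation_preserves_sequence_mean():
    out = impute_sequence(make_sequence([4, None, None, 8, 6, 2]))
    assert out.values.mean() == pytest.approx(np.mean([4, 8, 6, 2]), rel=1e-12)


@given(
    st.lists(st.integers(0, 30), min_size=2, max_size=8),
    st.integers(0, 2),
    st.randoms(use_true_random=False),
)
@settings(deadline=None, derandomize=True)
def test_imputation_preserves_mean_property(observed, n_gaps, rnd):
    values = list(observed)
    for _ in range(n_gaps):
        values.insert(rnd.randrange(len(values) + 1), None)
    if values[-1] is None:  # filtered sequences always end observed
        values[-1] = observed[-1]
    out = impute_sequence(make_sequence(values[:8]))
    kept = [v for v in values[:8] if v is not None]
    assert not np.isnan(out.values).any()
    assert out.values.mean() == pytest.approx(np.mean(kept), rel=1e-12)


def test_forecast_dataset_split_and_widths():
    seqs = [
        make_sequence(np.full(6, 10 + (i % 5)), test="FAQ", sid=f"S{i}")
        for i in range(100)
    ]
    ds = build_forecast_dataset(seqs, target_index=5, seed=3)
    assert (ds.split == "train").sum() == 80
    assert (ds.split == "validation").sum() == 20
    assert ds.inputs.shape == (100, 4)
    assert np.all((ds.inputs >= 0) & (ds.inputs <= 1))


def test_forecast_dataset_target8_width7():
    seqs = [make_sequence(np.full(8, 10), test="FAQ", sid=f"S{i}") for i in range(10)]
    ds = build_forecast_dataset(seqs, target_index=8, seed=0)
    assert ds.inputs.shape[1] == 7


def test_forecast_dataset_split_is_seeded():
    seqs = [
        make_sequence(np.arange(i, i + 6) % 30, sid=f"S{i}") for i in range(50)
    ]
    a = build_forecast_dataset(seqs, 5, seed=9)
    b = build_forecast_dataset(seqs, 5, seed=9)
    assert (a.subject_ids == b.subject_ids).all()
    assert (a.split == b.split).all()
    c = build_forecast_dataset(seqs, 5, seed=10)
    assert (a.subject_ids != c.subject_ids).any()


def test_forecast_dataset_rejects_short_sequences():
    seqs = [make_sequence([1, 2, 3, 4, 5, 6])]
    with pytest.raises(ValueError):
        build_forecast_dataset(seqs, target_index=7)


def _labelled_cohort(n_cn, n_noncn):
    recs = []
    for i in range(n_cn + n_noncn):
        dx = "CN" if i < n_cn else "MCI"
        recs += full_grid_subject(
            f"S{i:03d}", {t: [5] * 8 for t in TEST_NAMES}, dx=dx
        )
    return make_cohort_frame(recs)


def test_diagnosis_dataset_50_150_split():
    ds = build_diagnosis_dataset(_labelled_cohort(50, 150), 24, seed=1)
    tr_y = ds.y[ds.split == "train"]
    va_y = ds.y[ds.split == "validation"]
    assert (tr_y == 0).sum() == 40 and (tr_y == 1).sum() == 40
    assert (va_y == 0).sum() == 10 and (va_y == 1).sum() == 110


def test_diagnosis_dataset_balanced_input():
    ds = build_diagnosis_dataset(_labelled_cohort(100, 100), 48, seed=2)
    tr_y = ds.y[ds.split == "train"]
    assert (tr_y == 0).sum() == 80 and (tr_y == 1).sum() == 80
    assert (ds.split == "validation").sum() == 40


def test_diagnosis_dataset_training_always_balanced_across_cohorts():
    for seed in range(6):
        cohort = generate_cohort(GeneratorConfig(n_subjects=120, seed=seed))
        for month in (24, 48, 72):
            ds = build_diagnosis_dataset(cohort, month, seed=seed)
            tr_y = ds.y[ds.split == "train"]
            assert (tr_y == 0).sum() == (tr_y == 1).sum() > 0


def test_diagnosis_dataset_empty_class_raises():
    with pytest.raises(DataError):
        build_diagnosis_dataset(_labelled_cohort(0, 30), 24)


def test_diagnosis_dataset_drops_subject_failing_any_test_filter():
    cohort = _labelled_cohort(10, 10)
    # subject S000: FAQ has 3 missing values over the length-4 prefix window
    for m in (0, 6, 12):
        cohort.loc[
            (cohort["subject_id"] == "S000") & (cohort["month"] == m), "FAQ"
        ] = np.nan
    ds = build_diagnosis_dataset(cohort, 24, seed=0)
    assert "S000" not in set(ds.subject_ids)
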