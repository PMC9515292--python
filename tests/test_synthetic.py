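"""Synthetic cohort generator: determinism, bounds, trends, missingness."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from neurocast.curation import TEST_NAMES, VISIT_MONTHS, default_test_specs
from neurocast.errors import ConfigError
from neurocast.synthetic import (
    GeneratorConfig,
    generate_cohort,
    inject_missingness,
    read_cohort_csv,
    write_cohort_csv,
)


def noiseless_config(**kw):
    kw.setdefault("noise_sd", {t: 0.0 for t in TEST_NAMES})
    kw.setdefault("missing_score_rate", 0.0)
    kw.setdefault("missing_dx_rate", 0.0)
    return GeneratorConfig(**kw)


def test_zero_rates_give_no_missing_cells():
    cohort = generate_cohort(
        GeneratorConfig(n_subjects=40, missing_score_rate=0.0, missing_dx_rate=0.0, seed=2)
    )
    assert not cohort[list(TEST_NAMES)].isna().any().any()
    assert not cohort["DX"].isna().any()


def test_seeded_generation_is_bit_identical():
    a = generate_cohort(GeneratorConfig(n_subjects=60, seed=5))
    b = generate_cohort(GeneratorConfig(n_subjects=60, seed=5))
    pd.testing.assert_frame_equal(a, b)


def test_visit_grid_and_row_count():
    cohort = generate_cohort(GeneratorConfig(n_subjects=25, seed=0))
    assert len(cohort) == 25 * 8
    assert sorted(cohort["month"].unique()) == list(VISIT_MONTHS)
    assert not cohort.duplicated(["subject_id", "month"]).any()


def test_class_counts_within_99pct_binomial_interval():
    # 99% binomial interval around (1000, 500, 500), from the binomial CDF
    n = 2000
    cohort = generate_cohort(GeneratorConfig(n_subjects=n, seed=123))
    counts = (
        cohort.drop_duplicates("subject_id")["latent_class"].value_counts().to_dict()
    )
    for label, p in zip(("stable_cn", "converter", "decliner"), (0.5, 0.25, 0.25)):
        lo, hi = binom.ppf([0.005, 0.995], n, p)
        assert lo <= counts[label] <= hi


def test_scores_respect_table_ranges():
    cohort = generate_cohort(GeneratorConfig(n_subjects=300, seed=9))
    for spec in default_test_specs():
        vals = cohort[spec.name].dropna()
        assert vals.min() >= spec.min_score
        assert vals.max() <= spec.max_score
        assert (vals == vals.round()).all()  # integer scores


def test_noiseless_stable_subjects_are_constant():
    cohort = generate_cohort(noiseless_config(n_subjects=50, seed=3))
    stable = cohort[cohort["latent_class"] == "stable_cn"]
    for _, grp in stable.groupby("subject_id"):
        for t in TEST_NAMES:
            assert grp[t].nunique() == 1


def test_noiseless_decliner_trends_are_monotone():
    cohort = generate_cohort(noiseless_config(n_subjects=80, seed=4))
    decl = cohort[cohort["latent_class"] == "decliner"].sort_values("month")
    for _, grp in decl.groupby("subject_id"):
        assert (np.diff(grp["MMSE"]) <= 0).all()
        for t in ("ADASQ4", "ADAS11", "ADAS13", "FAQ"):
            assert (np.diff(grp[t]) >= 0).all()


def test_noiseless_dx_never_reverts_from_ad_to_cn():
    cohort = generate_cohort(noiseless_config(n_subjects=200, seed=6))
    rank = {"CN": 0, "MCI": 1, "AD": 2}
    for _, grp in cohort.sort_values("month").groupby("subject_id"):
        codes = grp["DX"].map(rank).to_numpy()
        assert (np.diff(codes) >= 0).all()


def test_converters_drift_only_after_conversion_month():
    cfg = noiseless_config(n_subjects=60, seed=8, conversion_month=24)
    cohort = generate_cohort(cfg)
    conv = cohort[cohort["latent_class"] == "converter"]
    for _, grp in conv.sort_values("month").groupby("subject_id"):
        pre = grp[grp["month"] <= 24]["MMSE"]
        assert pre.nunique() == 1


@pytest.mark.parametrize(
    "bad",
    [
        dict(n_subjects=0),
        dict(class_proportions=(0.6, 0.25, 0.25)),
        dict(missing_score_rate=1.0),
        dict(missing_dx_rate=-0.1),
        dict(cross_test_correlation=1.0),
    ],
)
def test_invalid_config_rejected(bad):
    with pytest.raises(ConfigError):
        generate_cohort(GeneratorConfig(**bad))


def test_inject_missingness_identity_at_zero_rates():
    cohort = generate_cohort(noiseless_config(n_subjects=30, seed=1))
    out = inject_missingness(cohort, 0.0, 0.0, seed=5)
    pd.testing.assert_frame_equal(out, cohort)


def test_inject_missingness_seeded_masks_identical():
    cohort = generate_cohort(noiseless_config(n_subjects=30, seed=1))
    a = inject_missingness(cohort, 0.97, 0.5, seed=42)
    b = inject_missingness(cohort, 0.97, 0.5, seed=42)
    pd.testing.assert_frame_equal(a, b)
    # non-missing cells unchanged
    for t in TEST_NAMES:
        kept = a[t].notna()
        assert (a.loc[kept, t] == cohort.loc[kept, t]).all()


def test_inject_missingness_count_within_99pct_binomial_interval():
    # 2000 rows x 5 score columns = 10,000 cells at rate 0.1
    cohort = generate_cohort(noiseless_config(n_subjects=250, seed=7))
    cells = len(cohort) * len(TEST_NAMES)
    assert cells == 10_000
    out = inject_missingness(cohort, 0.1, 0.0, seed=99)
    n_missing = int(out[list(TEST_NAMES)].isna().sum().sum())
    lo, hi = binom.ppf([0.005, 0.995], cells, 0.1)
    assert lo <= n_missing <= hi


def test_inject_missingness_rejects_bad_rates():
    cohort = generate_cohort(noiseless_config(n_subjects=5, seed=0))
    with pytest.raises(ConfigError):
        inject_missingness(cohort, 1.0, 0.0, seed=0)


def test_csv_round_trip_and_integer_dx_codes(tmp_path):
    cohort = generate_cohort(GeneratorConfig(n_subjects=20, seed=12))
    path = tmp_path / "cohort.csv"
    write_cohort_csv(cohort, path)
    back = read_cohort_csv(path)
    assert back["DX"].dropna().isin(["CN", "MCI", "AD"]).all()
    for t in TEST_NAMES:
        pd.testing.assert_series_equal(back[t], cohort.reset_index(drop=True)[t])
    # ADNI-style integer codes map onto the labels
    coded = path.read_text().replace(",CN,", ",1,").replace(",MCI,", ",2,").replace(",AD,", ",3,")
    path.write_text(coded)
    recoded = read_cohort_csv(path)
    assert recoded["DX"].dropna().isin(["CN", "MCI", "AD"]).all()
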