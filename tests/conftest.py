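import numpy as np
import pandas as pd
import pytest

from neurocast.curation import RawSequence, VISIT_MONTHS, TEST_NAMES
from neurocast.experiment import train_diagnoser_suite, train_forecaster_bank
from neurocast.forecaster import ForecasterConfig
from neurocast.synthetic import GeneratorConfig, generate_cohort


def make_cohort_frame(records):
    """Build a cohort table from (subject_id, month, scores..., dx) dicts."""
    base = {t: np.nan for t in TEST_NAMES}
    rows = []
    for rec in records:
        row = {"subject_id": rec["subject_id"], "month": rec["month"], **base}
        row.update({k: v for k, v in rec.items() if k not in ("subject_id", "month")})
        row.setdefault("DX", np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def full_grid_subject(sid, values_by_test, dx="CN"):
    """Rows for one subject observed at all 8 visits."""
    recs = []
    for i, m in enumerate(VISIT_MONTHS):
        rec = {"subject_id": sid, "month": m, "DX": dx}
        for t, vals in values_by_test.items():
            rec[t] = vals[i]
        recs.append(rec)
    return recs


def make_sequence(values, test="MMSE", sid="S1"):
    vals = np.array([np.nan if v is None else float(v) for v in values])
    months = VISIT_MONTHS[: len(vals)]
    return RawSequence(sid, test, months, vals)


@pytest.fixture(scope="session")
def small_trained_stack():
    """A small but fully trained stack shared by pipeline-level tests:
    150-subject cohort, 1-restart forecaster bank, 3 diagnosers."""
    cohort = generate_cohort(GeneratorConfig(n_subjects=150, seed=11))
    fc_cfg = ForecasterConfig(epochs=40, n_restarts=1)
    bank, used_fc = train_forecaster_bank(cohort, fc_cfg, seed=7)
    diagnosers, used_dx = train_diagnoser_suite(cohort, epochs=80, seed=7)
    return {
        "cohort": cohort,
        "bank": bank,
        "diagnosers": diagnosers,
        "used_ids": used_fc | used_dx,
    }
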