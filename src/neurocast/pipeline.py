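"""Combined predict-then-diagnose pipeline and contingency scoring.

For each held-out subject, every test's months-0-24 values are imputed
from the prefix's own observed entries, normalised, chained forward to
the horizon (48 or 72 months), and the five horizon predictions are fed
to the horizon's diagnoser. Predictions are then tabulated against the
reference diagnoses with the missing-reference column kept separate:
category accuracy divides agreements by the subjects in that predicted
category whose reference is present, and overall accuracy pools
agreements over all subjects with a present reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .curation import (
    GRID_PREFIXES,
    TEST_NAMES,
    RawSequence,
    extract_sequences,
    impute_sequence,
    normalize_scores,
    spec_for,
)
from .diagnoser import DiagnoserModel, diagnose
from .errors import ConfigError, DataError
from .forecaster import ForecastResult, ForecasterModel, chain_forecast


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Half-up decimal rounding for report display (84.615 -> 84.62)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def select_test_subjects(cohort: pd.DataFrame, excluded_ids: set) -> pd.DataFrame:
    """Held-out test cohort: subjects never used for training/validation
    that pass the length-8 sequence filters for every one of the five
    tests. The reference diagnosis at months 48/72 may still be missing."""
    excluded = {str(s) for s in excluded_ids}
    keep: set[str] | None = None
    for t in TEST_NAMES:
        ids = {s.subject_id for s in extract_sequences(cohort, t, 8)}
        keep = ids if keep is None else keep & ids
    assert keep is not None
    n_candidates = len(keep)
    keep -= excluded
    if not keep:
        raise DataError(
            f"no eligible test subjects (sequence-complete candidates: "
            f"{n_candidates}, all excluded as training/validation subjects)"
        )
    out = cohort[cohort["subject_id"].astype(str).isin(keep)]
    return out.copy()


@dataclass
class CombinedResult:
    """One subject's chained forecasts, diagnosis call and reference."""

    subject_id: str
    horizon_month: int
    forecasts: dict[str, ForecastResult]
    probability: float
    predicted_label: int
    reference_label: int | None  # 0=CN, 1=non-CN, None=missing reference


def _prefix_sequence(cohort: pd.DataFrame, sid: str, test: str) -> RawSequence:
    grid = GRID_PREFIXES[4]
    rows = cohort[(cohort["subject_id"].astype(str) == sid)]
    vals = np.full(4, np.nan)
    for i, m in enumerate(grid):
        cell = rows.loc[rows["month"] == m, test]
        if len(cell):
            vals[i] = cell.iloc[0]
    return RawSequence(sid, test, grid, vals)


def run_combined(
    test_cohort: pd.DataFrame,
    forecaster_bank: dict[str, dict[int, ForecasterModel]],
    diagnosers: dict[int, DiagnoserModel],
    horizon_month: int,
) -> list[CombinedResult]:
    """Run the chain for every subject in the held-out cohort.

    ``forecaster_bank`` maps test name -> target position -> model;
    ``diagnosers`` maps visit month -> model.
    """
    if horizon_month not in (48, 72):
        raise ConfigError("horizon_month must be 48 or 72")
    if horizon_month not in diagnosers:
        raise ConfigError(f"no diagnoser for month {horizon_month}")
    missing = [t for t in TEST_NAMES if t not in forecaster_bank]
    if missing:
        raise ConfigError(f"forecaster bank lacks tests {missing}")
    sids = sorted(test_cohort["subject_id"].astype(str).unique())
    dx_rows = test_cohort[test_cohort["month"] == horizon_month]
    dx_map = dict(
        zip(dx_rows["subject_id"].astype(str), dx_rows["DX"], strict=True)
    )
    results: list[CombinedResult] = []
    for sid in sids:
        forecasts: dict[str, ForecastResult] = {}
        horizon_scores = []
        for t in TEST_NAMES:
            seq = impute_sequence(_prefix_sequence(test_cohort, sid, t))
            first_four = normalize_scores(seq.values, spec_for(t))
            fr = chain_forecast(
                forecaster_bank[t], first_four, horizon_month, subject_id=sid
            )
            forecasts[t] = fr
            horizon_scores.append(fr.predicted[horizon_month])
        prob, label = diagnose(diagnosers[horizon_month], np.asarray(horizon_scores))
        dx = dx_map.get(sid)
        if dx is None or pd.isna(dx):
            ref = None
        else:
            ref = 0 if dx == "CN" else 1
        results.append(
            CombinedResult(sid, horizon_month, forecasts, prob, label, ref)
        )
    return results


@dataclass
class CategoryRow:
    """One predicted-diagnosis row of the contingency report."""

    predicted: str  # 'CN' or 'non-CN'
    n_subjects: int
    n_reference_cn: int
    n_reference_noncn: int
    n_reference_missing: int

    def __post_init__(self):
        total = self.n_reference_cn + self.n_reference_noncn + self.n_reference_missing
        if total != self.n_subjects:
            raise ValueError(
                f"row counts do not reconcile: {self.n_subjects} subjects vs "
                f"{total} reference entries"
            )

    @property
    def n_agreements(self) -> int:
        return self.n_reference_cn if self.predicted == "CN" else self.n_reference_noncn

    @property
    def n_with_reference(self) -> int:
        return self.n_subjects - self.n_reference_missing

    @property
    def accuracy_pct(self) -> float:
        if self.n_with_reference == 0:
            raise DataError("category accuracy undefined: no references present")
        return 100.0 * self.n_agreements / self.n_with_reference


@dataclass
class ContingencyReport:
    horizon_month: int
    rows: list[CategoryRow]

    @classmethod
    def from_counts(
        cls,
        horizon_month: int,
        cn_row: tuple[int, int, int, int],
        noncn_row: tuple[int, int, int, int],
    ) -> "ContingencyReport":
        """Build a report from printed-style counts: each row is
        (n_subjects, n_reference_cn, n_reference_noncn, n_missing)."""
        return cls(
            horizon_month,
            [CategoryRow("CN", *cn_row), CategoryRow("non-CN", *noncn_row)],
        )

    def to_dict(self) -> dict:
        return {
            "horizon_month": self.horizon_month,
            "rows": [
                {
                    "predicted": r.predicted,
                    "n_subjects": r.n_subjects,
                    "n_reference_cn": r.n_reference_cn,
                    "n_reference_noncn": r.n_reference_noncn,
                    "n_reference_missing": r.n_reference_missing,
                    "accuracy_pct": round_half_up(r.accuracy_pct),
                }
                for r in self.rows
            ],
            "overall_accuracy_pct": round_half_up(overall_accuracy(self)),
        }


def score_against_reference(results: list[CombinedResult]) -> ContingencyReport:
    """Tabulate predicted CN / non-CN against the reference diagnoses."""
    if not results:
        raise ValueError("no combined results to score")
    horizon = results[0].horizon_month
    rows = []
    for predicted, lab in (("CN", 0), ("non-CN", 1)):
        group = [r for r in results if r.predicted_label == lab]
        rows.append(
            CategoryRow(
                predicted,
                len(group),
                sum(1 for r in group if r.reference_label == 0),
                sum(1 for r in group if r.reference_label == 1),
                sum(1 for r in group if r.reference_label is None),
            )
        )
    if all(r.n_with_reference == 0 for r in rows):
        raise DataError("every reference diagnosis is missing")
    return ContingencyReport(horizon, rows)


def overall_accuracy(report: ContingencyReport) -> float:
    """Pooled agreements over all subjects with a present reference."""
    with_ref = sum(r.n_with_reference for r in report.rows)
    if with_ref == 0:
        raise DataError("overall accuracy undefined: no references present")
    agreements = sum(r.n_agreements for r in report.rows)
    return 100.0 * agreements / with_ref


def results_to_frame(results: list[CombinedResult]) -> pd.DataFrame:
    """Per-subject prediction table for CSV export."""
    records = []
    for r in results:
        rec = {"subject_id": r.subject_id, "horizon": r.horizon_month}
        for t in TEST_NAMES:
            for month, value in sorted(r.forecasts[t].predicted.items()):
                rec[f"{t}_x{month}"] = value
        rec["prob"] = r.probability
        rec["label"] = r.predicted_label
        rec["reference"] = "" if r.reference_label is None else r.reference_label
        records.append(rec)
    return pd.DataFrame(records)
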