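"""Cohort curation: test specifications, sequence extraction, imputation,
normalisation and train/validation dataset construction.

The five neuropsychological tests are MMSE (0-30, higher is better, normal
>= 28), ADAS Q4 (0-10, normal <= 5), ADAS Cog-11 (0-70, normal <= 10),
ADAS Cog-13 (0-85, normal <= 13) and FAQ (0-30, normal <= 2). Scores are
normalised to [0, 1] by dividing by the test maximum.

Visits lie on the fixed grid 0, 6, 12, 24, 36, 48, 60, 72 months; admissible
sequence lengths are 4 (through month 24), 6 (through month 48) and
8 (through month 72). Visits missing from a table count as missing scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DataError

VISIT_MONTHS: tuple[int, ...] = (0, 6, 12, 24, 36, 48, 60, 72)
#: admissible sequence length -> visit-month prefix
GRID_PREFIXES: dict[int, tuple[int, ...]] = {
    4: VISIT_MONTHS[:4],
    6: VISIT_MONTHS[:6],
    8: VISIT_MONTHS[:8],
}
#: diagnosis visit month -> sequence length ending at that month
LENGTH_FOR_MONTH: dict[int, int] = {24: 4, 48: 6, 72: 8}

TEST_NAMES: tuple[str, ...] = ("MMSE", "ADASQ4", "ADAS11", "ADAS13", "FAQ")

HIGHER_IS_BETTER = "higher_is_better"
LOWER_IS_BETTER = "lower_is_better"


@dataclass(frozen=True)
class TestSpec:
    """Scoring range, normal cutoff and normalisation for one test."""

    name: str
    min_score: float
    max_score: float
    normal_cutoff: float
    direction: str
    norm_divisor: float

    def is_normal(self, values) -> np.ndarray:
        """Boundary scores count as normal (cutoffs are >= / <=)."""
        v = np.asarray(values, dtype=float)
        if self.direction == HIGHER_IS_BETTER:
            return v >= self.normal_cutoff
        return v <= self.normal_cutoff

    def normalize(self, values):
        return normalize_scores(values, self)

    def denormalize(self, values):
        return denormalize_scores(values, self)


_SPEC_TABLE = (
    ("MMSE", 0, 30, 28, HIGHER_IS_BETTER),
    ("ADASQ4", 0, 10, 5, LOWER_IS_BETTER),
    ("ADAS11", 0, 70, 10, LOWER_IS_BETTER),
    ("ADAS13", 0, 85, 13, LOWER_IS_BETTER),
    ("FAQ", 0, 30, 2, LOWER_IS_BETTER),
)


def default_test_specs() -> list[TestSpec]:
    """The five test specifications, normalisation divisor = maximum score."""
    return [
        TestSpec(name, float(lo), float(hi), float(cut), direction, float(hi))
        for name, lo, hi, cut, direction in _SPEC_TABLE
    ]


def spec_for(name: str) -> TestSpec:
    for spec in default_test_specs():
        if spec.name == name:
            return spec
    raise KeyError(f"unknown test name: {name!r}")


def normalize_scores(values, spec: TestSpec):
    """Map raw scores to [0, 1] by dividing by the normalisation divisor."""
    v = np.asarray(values, dtype=float)
    observed = v[~np.isnan(v)]
    if observed.size and (
        observed.min() < spec.min_score or observed.max() > spec.max_score
    ):
        raise ValueError(
            f"{spec.name} score outside [{spec.min_score}, {spec.max_score}]"
        )
    return v / spec.norm_divisor


def denormalize_scores(values, spec: TestSpec):
    """Inverse of :func:`normalize_scores` (multiply by the divisor)."""
    return np.asarray(values, dtype=float) * spec.norm_divisor


@dataclass
class RawSequence:
    """One subject's score sequence for one test on a visit-grid prefix.

    ``values`` holds raw scores with ``nan`` marking missing entries.
    """

    subject_id: str
    test: str
    months: tuple[int, ...]
    values: np.ndarray

    @property
    def length(self) -> int:
        return len(self.months)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())


def extract_sequences(
    cohort: pd.DataFrame,
    test: str,
    length: int,
    require_final_dx: bool = False,
) -> list[RawSequence]:
    """Extract per-subject grid-prefix sequences, applying the retention
    filters: at most two missing scores and a present final score (and,
    optionally, a present final-visit diagnosis). Visits absent from the
    table count as missing. Subjects are returned in sorted-id order.
    """
    if test not in TEST_NAMES:
        raise KeyError(f"unknown test name: {test!r}")
    if length not in GRID_PREFIXES:
        raise ValueError(f"sequence length must be one of {sorted(GRID_PREFIXES)}")
    grid = GRID_PREFIXES[length]
    sub = cohort[cohort["month"].isin(grid)]
    scores = sub.pivot(index="subject_id", columns="month", values=test)
    scores = scores.reindex(columns=list(grid))
    if require_final_dx:
        dx = sub.pivot(index="subject_id", columns="month", values="DX")
        dx = dx.reindex(columns=list(grid))
    out: list[RawSequence] = []
    for sid in sorted(scores.index, key=str):
        vals = scores.loc[sid].to_numpy(dtype=float)
        if np.isnan(vals).sum() > 2 or np.isnan(vals[-1]):
            continue
        if require_final_dx:
            final_dx = dx.loc[sid].iloc[-1] if sid in dx.index else None
            if final_dx is None or (isinstance(final_dx, float) and math.isnan(final_dx)) or pd.isna(final_dx):
                continue
        out.append(RawSequence(str(sid), test, grid, vals))
    return out


def impute_sequence(seq: RawSequence) -> RawSequence:
    """Fill every missing entry with the mean of the observed entries.

    This rule preserves the sequence mean exactly (in exact arithmetic):
    the filled sequence averages to the observed-entry mean.
    """
    mask = np.isnan(seq.values)
    if mask.all():
        raise DataError("cannot impute a fully missing sequence")
    if not mask.any():
        return seq
    filled = seq.values.copy()
    filled[mask] = seq.values[~mask].mean()
    return replace(seq, values=filled)


@dataclass
class ForecastDataset:
    """Normalised (input-prefix, next-value) rows for one test and target.

    ``target_index`` is the 1-based sequence position being predicted
    (5..8); inputs have width ``target_index - 1``.
    """

    test: str
    target_index: int
    inputs: np.ndarray
    targets: np.ndarray
    split: np.ndarray  # 'train' / 'validation' per row
    subject_ids: np.ndarray
    seed: int

    def rows(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        m = self.split == which
        return self.inputs[m], self.targets[m]


def build_forecast_dataset(
    sequences: list[RawSequence],
    target_index: int,
    split_frac: float = 0.8,
    seed: int = 0,
    *,
    normalized: bool = False,
) -> ForecastDataset:
    """Assemble a forecaster training table from imputed sequences.

    Each row's inputs are the first ``target_index - 1`` normalised values
    and its target the value at ``target_index``. Rows are shuffled by
    ``seed`` and the first ``floor(split_frac * n)`` form the training split.
    """
    if target_index not in (5, 6, 7, 8):
        raise ValueError("target_index must be 5, 6, 7 or 8")
    if not sequences:
        raise DataError("no sequences supplied")
    test = sequences[0].test
    spec = spec_for(test)
    rows, targets, sids = [], [], []
    for seq in sequences:
        if seq.length < target_index:
            raise ValueError(
                f"sequence of length {seq.length} cannot supply target {target_index}"
            )
        if np.isnan(seq.values).any():
            raise DataError("sequences must be imputed before dataset assembly")
        vals = seq.values if normalized else normalize_scores(seq.values, spec)
        rows.append(vals[: target_index - 1])
        targets.append(vals[target_index - 1])
        sids.append(seq.subject_id)
    X = np.asarray(rows, dtype=float)
    y = np.asarray(targets, dtype=float)
    sids = np.asarray(sids, dtype=object)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(X))
    X, y, sids = X[order], y[order], sids[order]
    n_train = math.floor(split_frac * len(X))
    split = np.array(
        ["train"] * n_train + ["validation"] * (len(X) - n_train), dtype=object
    )
    return ForecastDataset(test, target_index, X, y, split, sids, seed)


@dataclass
class DiagnosisDataset:
    """Five normalised scores at one visit month with CN(0)/non-CN(1) labels.

    The training split is class-balanced by construction: equal counts of
    label 0 and label 1.
    """

    visit_month: int
    X: np.ndarray
    y: np.ndarray
    split: np.ndarray
    subject_ids: np.ndarray
    seed: int

    def rows(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        m = self.split == which
        return self.X[m], self.y[m]


def diagnosis_survivors(cohort: pd.DataFrame, visit_month: int) -> pd.DataFrame:
    """Subjects eligible for the diagnosis set at ``visit_month``: present
    diagnosis at that visit and, for every one of the five tests, a sequence
    passing the <=2-missing / final-present filters. Returns one row per
    surviving subject with the five final-visit scores and the label.
    """
    if visit_month not in LENGTH_FOR_MONTH:
        raise ValueError("visit_month must be 24, 48 or 72")
    length = LENGTH_FOR_MONTH[visit_month]
    survivors: dict[str, dict] = {}
    keep: set[str] | None = None
    for t in TEST_NAMES:
        seqs = extract_sequences(cohort, t, length, require_final_dx=True)
        ids = {s.subject_id for s in seqs}
        keep = ids if keep is None else keep & ids
        for s in seqs:
            survivors.setdefault(s.subject_id, {})[t] = s.values[-1]
    assert keep is not None
    sub = cohort[cohort["month"] == visit_month].copy()
    sub.index = sub["subject_id"].astype(str)
    rows = []
    for sid in sorted(keep, key=str):
        dx = sub.loc[sid, "DX"]
        label = 0 if dx == "CN" else 1
        rec = {"subject_id": sid, "label": label}
        rec.update(survivors[sid])
        rows.append(rec)
    return pd.DataFrame(rows)


def build_diagnosis_dataset(
    cohort: pd.DataFrame,
    visit_month: int,
    balance_frac: float = 0.8,
    seed: int = 0,
) -> DiagnosisDataset:
    """Build the class-balanced diagnosis set for one visit month.

    The training subset takes ``floor(balance_frac * minority)`` rows from
    the minority class and an equal-size seeded sample (without
    replacement) of the majority class; everything else is validation.
    """
    table = diagnosis_survivors(cohort, visit_month)
    if table.empty or table["label"].nunique() < 2:
        raise DataError(
            f"month {visit_month}: a diagnosis class is empty after filtering"
        )
    X = np.column_stack(
        [normalize_scores(table[t].to_numpy(), spec_for(t)) for t in TEST_NAMES]
    )
    y = table["label"].to_numpy(dtype=int)
    sids = table["subject_id"].to_numpy(dtype=object)

    rng = np.random.default_rng(seed)
    idx0 = np.flatnonzero(y == 0)
    idx1 = np.flatnonzero(y == 1)
    minority, majority = (idx0, idx1) if len(idx0) <= len(idx1) else (idx1, idx0)
    k = math.floor(balance_frac * len(minority))
    if k == 0:
        raise DataError("minority class too small to form a training set")
    train_min = rng.choice(minority, size=k, replace=False)
    train_maj = rng.choice(majority, size=k, replace=False)
    split = np.full(len(y), "validation", dtype=object)
    split[train_min] = "train"
    split[train_maj] = "train"
    return DiagnosisDataset(visit_month, X, y, split, sids, seed)
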