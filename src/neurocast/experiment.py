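"""End-to-end experiment: simulate -> curate -> train -> combine -> score.

Reproduces the full study design on a synthetic cohort: a held-out test
set of fully observed subjects is carved out first, per-test forecasters
are trained for targets 5-8 and per-horizon diagnosers for months
24/48/72 on the remaining subjects, and the combined predict-then-diagnose
chain is scored against the simulated reference diagnoses at months 48
and 72. Everything is a deterministic function of the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curation import (
    TEST_NAMES,
    build_diagnosis_dataset,
    build_forecast_dataset,
    extract_sequences,
    impute_sequence,
)
from .diagnoser import (
    DEFAULT_HIDDEN,
    DiagnoserConfig,
    DiagnoserModel,
    train_diagnoser,
)
from .forecaster import (
    ForecasterConfig,
    ForecasterModel,
    select_best_forecaster,
    train_forecaster_restarts,
)
from .pipeline import (
    overall_accuracy,
    run_combined,
    score_against_reference,
    select_test_subjects,
)
from .synthetic import GeneratorConfig, generate_cohort

#: sequence length feeding each forecast target position
LENGTH_FOR_TARGET = {5: 6, 6: 6, 7: 8, 8: 8}


@dataclass
class ExperimentConfig:
    """Study conditions for one simulated experiment.

    The shipped training schedule (120 epochs, 2 restarts) is sized for a
    ~600-subject cohort on a single CPU; both are freely configurable.
    """

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    max_test_subjects: int = 66
    forecaster_epochs: int = 120
    forecaster_restarts: int = 2
    diagnoser_epochs: int = 150
    seed: int = 0


def _fully_observed_ids(cohort: pd.DataFrame) -> list[str]:
    """Subjects with every score present at all 8 visits and a present
    diagnosis at months 48 and 72 (the held-out test candidates)."""
    ids = []
    for sid, grp in cohort.groupby(cohort["subject_id"].astype(str), sort=True):
        if len(grp) != 8:
            continue
        if grp[list(TEST_NAMES)].isna().any().any():
            continue
        dx48 = grp.loc[grp["month"] == 48, "DX"]
        dx72 = grp.loc[grp["month"] == 72, "DX"]
        if dx48.isna().any() or dx72.isna().any():
            continue
        ids.append(sid)
    return ids


def train_forecaster_bank(
    cohort: pd.DataFrame,
    config: ForecasterConfig,
    seed: int,
) -> tuple[dict[str, dict[int, ForecasterModel]], set[str]]:
    """Train the 5 tests x 4 targets forecaster bank on a cohort.

    Returns the bank and the set of subject ids consumed by any
    training/validation dataset.
    """
    rng = np.random.default_rng(seed)
    bank: dict[str, dict[int, ForecasterModel]] = {}
    used: set[str] = set()
    for t in TEST_NAMES:
        bank[t] = {}
        seqs_by_len = {
            length: [
                impute_sequence(s) for s in extract_sequences(cohort, t, length)
            ]
            for length in (6, 8)
        }
        for target in (5, 6, 7, 8):
            seqs = seqs_by_len[LENGTH_FOR_TARGET[target]]
            ds = build_forecast_dataset(
                seqs, target, seed=int(rng.integers(0, 2**31 - 1))
            )
            used.update(ds.subject_ids)
            cfg = ForecasterConfig(
                units=config.units,
                epochs=config.epochs,
                batch_size=config.batch_size,
                learning_rate=config.learning_rate,
                n_restarts=config.n_restarts,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            bank[t][target] = select_best_forecaster(
                train_forecaster_restarts(ds, cfg)
            )
    return bank, used


def train_diagnoser_suite(
    cohort: pd.DataFrame, epochs: int, seed: int
) -> tuple[dict[int, DiagnoserModel], set[str]]:
    """Train the month-24/48/72 diagnosers on a cohort."""
    rng = np.random.default_rng(seed)
    models: dict[int, DiagnoserModel] = {}
    used: set[str] = set()
    for month in (24, 48, 72):
        ds = build_diagnosis_dataset(
            cohort, month, seed=int(rng.integers(0, 2**31 - 1))
        )
        used.update(ds.subject_ids)
        cfg = DiagnoserConfig(
            hidden=DEFAULT_HIDDEN[month],
            epochs=epochs,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        models[month] = train_diagnoser(ds, cfg)
    return models, used


def run_experiment(config: ExperimentConfig | None = None) -> dict:
    """Run the whole pipeline once; returns a JSON-serialisable report."""
    config = config or ExperimentConfig()
    rng = np.random.default_rng(config.seed)
    cohort = generate_cohort(config.generator)

    candidates = _fully_observed_ids(cohort)
    if len(candidates) > config.max_test_subjects:
        pick = rng.choice(
            len(candidates), size=config.max_test_subjects, replace=False
        )
        test_ids = {candidates[i] for i in sorted(pick)}
    else:
        test_ids = set(candidates)
    train_cohort = cohort[~cohort["subject_id"].astype(str).isin(test_ids)]

    fc_cfg = ForecasterConfig(
        epochs=config.forecaster_epochs, n_restarts=config.forecaster_restarts
    )
    bank, used_fc = train_forecaster_bank(
        train_cohort, fc_cfg, seed=int(rng.integers(0, 2**31 - 1))
    )
    diagnosers, used_dx = train_diagnoser_suite(
        train_cohort, config.diagnoser_epochs, seed=int(rng.integers(0, 2**31 - 1))
    )

    test_cohort = select_test_subjects(cohort, excluded_ids=used_fc | used_dx)
    report: dict = {
        "n_subjects": config.generator.n_subjects,
        "n_test_subjects": int(test_cohort["subject_id"].nunique()),
        "forecasters": {
            t: {k: {"validation_mse": bank[t][k].validation_mse} for k in bank[t]}
            for t in TEST_NAMES
        },
        "diagnosers": {
            m: {"validation_accuracy_pct": diagnosers[m].validation_accuracy}
            for m in (24, 48, 72)
        },
        "combined": {},
    }
    for horizon in (48, 72):
        results = run_combined(test_cohort, bank, diagnosers, horizon)
        contingency = score_against_reference(results)
        d = contingency.to_dict()
        d["overall_accuracy_exact"] = overall_accuracy(contingency)
        report["combined"][horizon] = d
    return report
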