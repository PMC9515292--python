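"""Synthetic longitudinal cohort generator with known ground truth.

Emulates the statistical structure a predict-then-diagnose pipeline needs
from an observational ageing cohort: five bounded integer test scores per
visit on the 0-72-month grid, slow monotone decline for progressing
subjects versus near-stationary scores for stable ones, cross-test
correlation through a shared latent severity, diagnosis labels coupled to
that severity, and sporadic missing scores and diagnoses.

Model
-----
Each subject carries one of three latent classes fixed for the whole
trajectory:

* ``stable_cn`` — low baseline severity, no drift;
* ``converter`` — slightly elevated baseline (a prodromal deficit, as seen
  in subjects who later convert), drift switching on at
  ``conversion_month``;
* ``decliner`` — impaired baseline, drift from the start.

A scalar severity ``s(t) = s0 + drift_rate * active_years(t)`` drives both
the scores and the diagnosis. Each test score is an affine map of severity
into its raw range (MMSE decreases with severity; ADAS/FAQ increase), plus
a class-specific raw-unit linear trend and correlated Gaussian noise,
rounded to the nearest integer and clipped to the test range. The
diagnosis at a visit is CN below ``cn_threshold``, AD above
``ad_threshold`` and MCI between; missingness is injected completely at
random.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curation import TEST_NAMES, VISIT_MONTHS, HIGHER_IS_BETTER, default_test_specs
from .errors import ConfigError

LATENT_CLASSES: tuple[str, ...] = ("stable_cn", "converter", "decliner")

_PROGRESSOR_DRIFT = {
    # raw score units per year; signs follow each test's abnormal direction
    "MMSE": -1.2,
    "ADASQ4": 0.6,
    "ADAS11": 2.5,
    "ADAS13": 3.0,
    "FAQ": 2.0,
}

DEFAULT_DRIFT_PER_YEAR: dict[str, dict[str, float]] = {
    "stable_cn": {t: 0.0 for t in TEST_NAMES},
    "converter": dict(_PROGRESSOR_DRIFT),
    "decliner": dict(_PROGRESSOR_DRIFT),
}

DEFAULT_NOISE_SD: dict[str, float] = {
    "MMSE": 0.8,
    "ADASQ4": 0.5,
    "ADAS11": 1.5,
    "ADAS13": 1.8,
    "FAQ": 0.8,
}

#: baseline severity ranges (uniform) per latent class
_BASELINE_SEVERITY = {
    "stable_cn": (0.02, 0.15),
    "converter": (0.12, 0.28),
    "decliner": (0.28, 0.50),
}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    ``drift_per_year`` is in raw score units per year per class and test;
    ``noise_sd`` in raw score units per test; ``cross_test_correlation`` is
    the shared loading of the per-visit noise across tests.
    """

    n_subjects: int = 600
    class_proportions: tuple[float, float, float] = (0.5, 0.25, 0.25)
    drift_per_year: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_DRIFT_PER_YEAR.items()}
    )
    noise_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    cross_test_correlation: float = 0.6
    missing_score_rate: float = 0.05
    missing_dx_rate: float = 0.05
    conversion_month: int = 24
    cn_threshold: float = 0.25
    ad_threshold: float = 0.60
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        props = np.asarray(self.class_proportions, dtype=float)
        if props.shape != (3,) or (props < 0).any():
            raise ConfigError("class_proportions must be 3 nonnegative fractions")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ConfigError("class_proportions must sum to 1 within 1e-9")
        for name, rate in (
            ("missing_score_rate", self.missing_score_rate),
            ("missing_dx_rate", self.missing_dx_rate),
        ):
            if not 0.0 <= rate < 1.0:
                raise ConfigError(f"{name} must lie in [0, 1)")
        if not 0.0 <= self.cross_test_correlation < 1.0:
            raise ConfigError("cross_test_correlation must lie in [0, 1)")
        if not self.cn_threshold < self.ad_threshold:
            raise ConfigError("cn_threshold must be below ad_threshold")


def _dx_from_severity(severity: np.ndarray, config: GeneratorConfig) -> np.ndarray:
    dx = np.full(severity.shape, "MCI", dtype=object)
    dx[severity < config.cn_threshold] = "CN"
    dx[severity > config.ad_threshold] = "AD"
    return dx


def generate_cohort(config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Generate a cohort table with one row per subject-visit.

    Columns: ``subject_id, month, MMSE, ADASQ4, ADAS11, ADAS13, FAQ, DX,
    latent_class``; missing cells are NaN. Identical configs (including the
    seed) produce bit-identical tables.
    """
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    months = np.asarray(VISIT_MONTHS, dtype=float)
    n_visits = len(months)
    specs = {s.name: s for s in default_test_specs()}

    classes = rng.choice(len(LATENT_CLASSES), size=n, p=config.class_proportions)
    lo = np.array([_BASELINE_SEVERITY[LATENT_CLASSES[c]][0] for c in classes])
    hi = np.array([_BASELINE_SEVERITY[LATENT_CLASSES[c]][1] for c in classes])
    s0 = rng.uniform(lo, hi)

    # active drift years at each visit: decliners from baseline, converters
    # only past conversion_month, stable subjects never
    years = months / 12.0
    active = np.zeros((n, n_visits))
    for i, c in enumerate(classes):
        label = LATENT_CLASSES[c]
        if label == "decliner":
            active[i] = years
        elif label == "converter":
            active[i] = np.maximum(months - config.conversion_month, 0.0) / 12.0

    # severity drift = mean normalised abnormality drift across the tests
    sev_rate = np.zeros(n)
    for i, c in enumerate(classes):
        drifts = config.drift_per_year[LATENT_CLASSES[c]]
        rates = []
        for t in TEST_NAMES:
            spec = specs[t]
            signed = drifts[t] / (spec.max_score - spec.min_score)
            if spec.direction == HIGHER_IS_BETTER:
                signed = -signed
            rates.append(signed)
        sev_rate[i] = float(np.mean(rates))
    severity = s0[:, None] + sev_rate[:, None] * active

    rho = config.cross_test_correlation
    z_shared = rng.standard_normal((n, n_visits))
    scores: dict[str, np.ndarray] = {}
    for t in TEST_NAMES:
        spec = specs[t]
        span = spec.max_score - spec.min_score
        if spec.direction == HIGHER_IS_BETTER:
            base = spec.max_score - s0 * span
        else:
            base = spec.min_score + s0 * span
        drift = np.array(
            [config.drift_per_year[LATENT_CLASSES[c]][t] for c in classes]
        )
        z_own = rng.standard_normal((n, n_visits))
        noise = config.noise_sd[t] * (
            np.sqrt(rho) * z_shared + np.sqrt(1.0 - rho) * z_own
        )
        raw = base[:, None] + drift[:, None] * active + noise
        scores[t] = np.clip(np.rint(raw), spec.min_score, spec.max_score)

    width = len(str(n))
    sids = np.array([f"S{i:0{width}d}" for i in range(1, n + 1)], dtype=object)
    table = pd.DataFrame(
        {
            "subject_id": np.repeat(sids, n_visits),
            "month": np.tile(VISIT_MONTHS, n),
            **{t: scores[t].ravel() for t in TEST_NAMES},
            "DX": _dx_from_severity(severity, config).ravel(),
            "latent_class": np.repeat(
                np.array([LATENT_CLASSES[c] for c in classes], dtype=object), n_visits
            ),
        }
    )
    if config.missing_score_rate > 0 or config.missing_dx_rate > 0:
        mask_seed = int(rng.integers(0, 2**31 - 1))
        table = inject_missingness(
            table, config.missing_score_rate, config.missing_dx_rate, mask_seed
        )
    return table


def inject_missingness(
    cohort: pd.DataFrame, score_rate: float, dx_rate: float, seed: int
) -> pd.DataFrame:
    """Blank score/diagnosis cells independently at the given rates (MCAR)."""
    for name, rate in (("score_rate", score_rate), ("dx_rate", dx_rate)):
        if not 0.0 <= rate < 1.0:
            raise ConfigError(f"{name} must lie in [0, 1)")
    out = cohort.copy()
    rng = np.random.default_rng(seed)
    n = len(out)
    for t in TEST_NAMES:
        mask = rng.random(n) < score_rate
        out.loc[mask, t] = np.nan
    dx_mask = rng.random(n) < dx_rate
    out.loc[dx_mask, "DX"] = np.nan
    return out


_DX_CODES = {"1": "CN", "2": "MCI", "3": "AD", "CN": "CN", "MCI": "MCI", "AD": "AD"}


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    """Write the wide cohort CSV; missing cells become empty fields."""
    cohort.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a wide cohort CSV. Diagnoses may be the strings CN/MCI/AD or the
    integer codes 1/2/3 (mapped to CN/MCI/AD); empty fields are missing."""
    table = pd.read_csv(path, dtype={"subject_id": str})
    def _map_dx(v):
        if pd.isna(v):
            return np.nan
        key = str(v).strip()
        if key.endswith(".0"):
            key = key[:-2]
        if key not in _DX_CODES:
            raise ValueError(f"unrecognised diagnosis code: {v!r}")
        return _DX_CODES[key]
    table["DX"] = table["DX"].map(_map_dx)
    return table
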