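"""Per-horizon perceptron diagnosers: five normalised test scores in,
probability of a non-CN (MCI or AD) state out.

The classifier is a four-hidden-layer perceptron with relu hidden
activations, a scalar sigmoid output, MSE loss and the Adam optimizer,
trained on a class-balanced subset and thresholded at 0.5 (ties go to
non-CN). Accuracy is the percent of validation rows whose thresholded
output matches the reference label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .curation import DiagnosisDataset
from .errors import DataError

#: default hidden widths per diagnosis month (the two horizons differ)
DEFAULT_HIDDEN = {24: (32, 16, 8, 4), 48: (32, 16, 8, 4), 72: (24, 12, 8, 4)}


@dataclass
class DiagnoserConfig:
    hidden: tuple[int, int, int, int] = (32, 16, 8, 4)
    epochs: int = 200
    batch_size: int = 16
    learning_rate: float = 2e-3
    threshold: float = 0.5
    seed: int = 0


@dataclass
class DiagnoserModel:
    visit_month: int
    config: DiagnoserConfig
    net: nn.MLP
    history: dict[str, list[float]]
    validation_accuracy: float  # percent


def train_diagnoser(
    dataset: DiagnosisDataset, config: DiagnoserConfig | None = None
) -> DiagnoserModel:
    """Train on the balanced training subset; score on the validation rows."""
    config = config or DiagnoserConfig()
    X_tr, y_tr = dataset.rows("train")
    X_va, y_va = dataset.rows("validation")
    if len(X_tr) == 0:
        raise DataError("empty training split")
    if (y_tr == 0).sum() != (y_tr == 1).sum():
        raise DataError("training subset is not class-balanced")
    net = nn.MLP(in_dim=5, hidden=config.hidden, seed=config.seed)
    history = nn.fit(
        net,
        X_tr,
        y_tr.astype(float),
        X_val=X_va,
        y_val=y_va.astype(float),
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        seed=config.seed,
    )
    model = DiagnoserModel(dataset.visit_month, config, net, history, float("nan"))
    model.validation_accuracy = (
        validate_diagnoser(model, X_va, y_va) if len(X_va) else float("nan")
    )
    return model


def diagnose(model: DiagnoserModel, scores) -> tuple[float, int]:
    """Probability of non-CN and the thresholded label for one subject."""
    x = np.asarray(scores, dtype=float)
    if x.shape != (5,):
        raise ValueError("exactly five normalised scores are required")
    if not np.all(np.isfinite(x)) or x.min() < 0.0 or x.max() > 1.0:
        raise ValueError("scores must be finite normalised values in [0, 1]")
    prob = float(model.net.forward(x[None, :])[0])
    label = int(prob >= model.config.threshold)
    return prob, label


def predict_labels(model: DiagnoserModel, X: np.ndarray) -> np.ndarray:
    probs = model.net.forward(np.asarray(X, dtype=float))
    return (probs >= model.config.threshold).astype(int)


def validate_diagnoser(model: DiagnoserModel, X, y) -> float:
    """Percent of rows whose thresholded output matches the label."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(X) == 0:
        raise ValueError("no rows to validate on")
    pred = predict_labels(model, X)
    return 100.0 * float((pred == y).sum()) / len(y)


# --- persistence -----------------------------------------------------------

def save_diagnoser(model: DiagnoserModel, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    (d / "weights.json").write_text(json.dumps(nn.weights_to_lists(model.net)))
    meta = {
        "visit_month": model.visit_month,
        "config": asdict(model.config),
        "validation_accuracy": model.validation_accuracy,
    }
    (d / "metadata.json").write_text(json.dumps(meta, indent=2))


def load_diagnoser(directory) -> DiagnoserModel:
    d = Path(directory)
    meta = json.loads((d / "metadata.json").read_text())
    cfg = DiagnoserConfig(
        **{**meta["config"], "hidden": tuple(meta["config"]["hidden"])}
    )
    net = nn.MLP(in_dim=5, hidden=cfg.hidden, seed=cfg.seed)
    nn.weights_from_lists(net, json.loads((d / "weights.json").read_text()))
    return DiagnoserModel(
        meta["visit_month"], cfg, net, {"train_loss": [], "val_loss": []},
        meta["validation_accuracy"],
    )
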