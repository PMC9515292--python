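"""Per-test recurrent score forecasters and the recursive chained forecast.

One univariate sequence-to-one model is trained per (test, target
position): the target-5 model maps the four observed values (months 0-24)
to the month-36 value, the target-6 model maps five values to month 48,
and so on. At application time the chain feeds each prediction back as
input, so months 36-72 are forecast from observed data through month 24
only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .curation import ForecastDataset
from .errors import ConfigError, DataError

#: target sequence position -> forecast month
TARGET_MONTHS = {5: 36, 6: 48, 7: 60, 8: 72}
HORIZON_TARGETS = {48: (5, 6), 72: (5, 6, 7, 8)}


@dataclass
class ForecasterConfig:
    """Two recurrent layers plus a dense scalar head, relu activations,
    MSE loss, Adam optimizer. ``n_restarts`` independent initialisations
    are trained and the lowest-validation-MSE one kept."""

    units: tuple[int, int] = (32, 16)
    epochs: int = 200
    batch_size: int = 16
    learning_rate: float = 2e-3
    n_restarts: int = 5
    seed: int = 0


@dataclass
class ForecasterModel:
    test: str
    target_index: int
    config: ForecasterConfig
    net: nn.SequenceRegressor
    history: dict[str, list[float]]
    validation_mse: float
    restart_index: int = 0

    @property
    def input_width(self) -> int:
        return self.target_index - 1


def train_forecaster(
    dataset: ForecastDataset, config: ForecasterConfig | None = None
) -> ForecasterModel:
    """Train one forecaster on the dataset's training split (single restart)."""
    config = config or ForecasterConfig()
    X_tr, y_tr = dataset.rows("train")
    X_va, y_va = dataset.rows("validation")
    if len(X_tr) == 0:
        raise DataError("empty training split")
    if X_tr.shape[1] != dataset.target_index - 1:
        raise ValueError("dataset input width inconsistent with target_index")
    net = nn.SequenceRegressor(units=config.units, seed=config.seed)
    history = nn.fit(
        net,
        X_tr,
        y_tr,
        X_val=X_va,
        y_val=y_va,
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        seed=config.seed,
    )
    val_mse = (
        nn.mse(np.clip(net.forward(X_va), 0.0, 1.0), y_va)
        if len(X_va)
        else history["train_loss"][-1]
    )
    return ForecasterModel(
        dataset.test, dataset.target_index, config, net, history, val_mse
    )


def train_forecaster_restarts(
    dataset: ForecastDataset, config: ForecasterConfig | None = None
) -> list[ForecasterModel]:
    """Train ``n_restarts`` candidates differing only in initialisation seed."""
    config = config or ForecasterConfig()
    candidates = []
    for r in range(config.n_restarts):
        cfg = ForecasterConfig(
            units=config.units,
            epochs=config.epochs,
            batch_size=config.batch_size,
            learning_rate=config.learning_rate,
            n_restarts=config.n_restarts,
            seed=config.seed + r,
        )
        model = train_forecaster(dataset, cfg)
        model.restart_index = r
        candidates.append(model)
    return candidates


def select_best_forecaster(candidates: list[ForecasterModel]) -> ForecasterModel:
    """Lowest validation MSE wins; ties go to the earliest restart."""
    if not candidates:
        raise ValueError("no candidate models supplied")
    first = candidates[0]
    for m in candidates[1:]:
        if m.test != first.test or m.target_index != first.target_index:
            raise ValueError("candidates must share test and target_index")
    return min(candidates, key=lambda m: (m.validation_mse, m.restart_index))


def predict_next(model: ForecasterModel, prefix) -> float:
    """One forward pass on a normalised prefix; output clipped to [0, 1]."""
    x = np.asarray(prefix, dtype=float)
    if x.ndim != 1 or len(x) != model.input_width:
        raise ValueError(
            f"prefix must have width {model.input_width}, got shape {x.shape}"
        )
    if np.isnan(x).any() or x.min() < 0.0 or x.max() > 1.0:
        raise ValueError("prefix entries must be normalised values in [0, 1]")
    y = model.net.forward(x[None, :])[0]
    return float(np.clip(y, 0.0, 1.0))


@dataclass
class ForecastResult:
    """Chained forecast for one subject and test: observed months 0-24
    plus predicted months 36/48 (horizon 48) or 36/48/60/72 (horizon 72)."""

    subject_id: str
    test: str
    observed: np.ndarray
    predicted: dict[int, float]  # month -> normalised prediction

    @property
    def horizon_value(self) -> float:
        return self.predicted[max(self.predicted)]


def chain_forecast(
    bank: dict[int, ForecasterModel],
    first_four,
    horizon_month: int,
    subject_id: str = "",
) -> ForecastResult:
    """Recursive multi-step forecast from the four observed values.

    The target-5 model predicts month 36 from the four actual values; each
    later model appends the previous predictions to its input. Only actual
    values through month 24 plus previously predicted values are ever fed
    forward.
    """
    if horizon_month not in HORIZON_TARGETS:
        raise ConfigError("horizon_month must be 48 or 72")
    targets = HORIZON_TARGETS[horizon_month]
    missing = [k for k in targets if k not in bank]
    if missing:
        raise ConfigError(f"forecaster bank lacks targets {missing}")
    x = np.asarray(first_four, dtype=float)
    if x.shape != (4,):
        raise ValueError("first_four must hold exactly the months 0-24 values")
    test = bank[targets[0]].test
    window = list(x)
    predicted: dict[int, float] = {}
    for k in targets:
        y = predict_next(bank[k], np.asarray(window))
        predicted[TARGET_MONTHS[k]] = y
        window.append(y)
    return ForecastResult(subject_id, test, x, predicted)


# --- persistence -----------------------------------------------------------

def save_forecaster(model: ForecasterModel, directory) -> None:
    """Persist a model bundle: weights.json, metadata.json, history.csv."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    (d / "weights.json").write_text(json.dumps(nn.weights_to_lists(model.net)))
    meta = {
        "test": model.test,
        "target_index": model.target_index,
        "config": asdict(model.config),
        "validation_mse": model.validation_mse,
        "restart_index": model.restart_index,
    }
    (d / "metadata.json").write_text(json.dumps(meta, indent=2))
    hist = model.history
    lines = ["epoch,train_loss,val_loss"]
    for i, tr in enumerate(hist["train_loss"]):
        va = hist["val_loss"][i] if i < len(hist["val_loss"]) else ""
        lines.append(f"{i + 1},{tr},{va}")
    (d / "history.csv").write_text("\n".join(lines) + "\n")


def load_forecaster(directory) -> ForecasterModel:
    d = Path(directory)
    meta = json.loads((d / "metadata.json").read_text())
    cfg = ForecasterConfig(**{**meta["config"], "units": tuple(meta["config"]["units"])})
    net = nn.SequenceRegressor(units=cfg.units, seed=cfg.seed)
    nn.weights_from_lists(net, json.loads((d / "weights.json").read_text()))
    return ForecasterModel(
        meta["test"],
        meta["target_index"],
        cfg,
        net,
        {"train_loss": [], "val_loss": []},
        meta["validation_mse"],
        meta["restart_index"],
    )
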