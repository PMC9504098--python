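"""Training loop, evaluation protocol and model-comparison statistics.

Defaults follow the published training recipe: SGD with momentum 0.9,
batch size 8, weight decay 1e-4, initial learning rate 0.001, at most
200 epochs, no learning-rate schedule.  The loss is mean per-pixel
squared error summed over the three organelle channels (L1 available);
an adaptive optimiser (Adam) is available by configuration.  Everything
is driven by one seed: two runs with the same seed, data and config
produce identical loss curves and weights.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import metrics
from .metrics import METRIC_DIRECTIONS
from .nn import optim
from .nn.autograd import Tensor

__all__ = ["TrainConfig", "train", "predict", "evaluate", "compare",
           "mean_pixel_accuracy"]


@dataclass
class TrainConfig:
    """Optimisation hyperparameters (defaults = the published recipe)."""

    optimizer: str = "sgd"          # "sgd" (momentum) or "adam"
    learning_rate: float = 0.001
    momentum: float = 0.9
    weight_decay: float = 1e-4
    batch_size: int = 8
    max_epochs: int = 200
    loss: str = "mse"               # "mse" or "l1"
    seed: int = 0
    patience: int | None = None     # early stop on val loss; None = off
    stop_at_train_pcc: float | None = None  # optional overfit stop rule
    pcc_every: int = 0              # evaluate train PCC every k epochs (0 = never)

    def __post_init__(self):
        for name in ("learning_rate", "batch_size", "max_epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def _loss_fn(pred: Tensor, target: np.ndarray, kind: str) -> Tensor:
    diff = pred - Tensor(target)
    if kind == "mse":
        return (diff ** 2).mean()
    if kind == "l1":
        return ((diff ** 2 + 1e-12) ** 0.5).mean()
    raise ValueError(f"unknown loss {kind!r}")


def _build_optimizer(model, cfg: TrainConfig):
    if cfg.optimizer == "sgd":
        return optim.SGD(model.parameters(), lr=cfg.learning_rate,
                         momentum=cfg.momentum, weight_decay=cfg.weight_decay)
    if cfg.optimizer == "adam":
        return optim.Adam(model.parameters(), lr=cfg.learning_rate,
                          weight_decay=cfg.weight_decay)
    raise ValueError(f"unknown optimizer {cfg.optimizer!r}")


def pixel_class_map(stack: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Per-pixel class map over [background + K organelle channels].

    The background channel is 1 − max over organelle channels; channels
    below the threshold cannot win, so dim pixels fall to background.
    """
    stack = np.asarray(stack, dtype=np.float64)
    gated = np.where(stack >= threshold, stack, 0.0)
    bg = 1.0 - stack.max(axis=0, keepdims=True)
    return np.argmax(np.concatenate([bg, gated], axis=0), axis=0)


def mean_pixel_accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    """Mean of per-class pixel accuracies of the argmax class maps."""
    pm = pixel_class_map(pred)
    tm = pixel_class_map(truth)
    ay, _ = metrics.class_accuracy(pm, tm, num_classes=pred.shape[0] + 1)
    return float(np.nanmean(ay))


def predict(model, X: np.ndarray, batch_size: int = 8) -> np.ndarray:
    """Deterministic (eval-mode) predictions for a stack of inputs."""
    was_training = model.training
    model.eval()
    outs = []
    for i in range(0, len(X), batch_size):
        outs.append(model(X[i:i + batch_size]).data)
    model.train(was_training)
    return np.concatenate(outs, axis=0)


def _dataset_pcc(model, X, Y, batch_size) -> float:
    preds = predict(model, X, batch_size)
    return metrics.pearson_cc(preds, Y)


def train(model, X: np.ndarray, Y: np.ndarray, cfg: TrainConfig,
          X_val: np.ndarray | None = None, Y_val: np.ndarray | None = None,
          verbose: bool = False):
    """Train in place; returns (history DataFrame, best state dict).

    Per epoch the train loss and mean pixel accuracy are logged; when a
    validation set is given its loss is logged too and the best weights
    (lowest validation loss, else lowest train loss) are kept and
    restored into the model at the end.
    """
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if len(X) == 0:
        raise ValueError("empty training set")
    if len(X) != len(Y):
        raise ValueError("input/target counts differ")
    batch = min(cfg.batch_size, len(X))
    rng = np.random.default_rng(cfg.seed)
    opt = _build_optimizer(model, cfg)
    history: list[dict] = []
    best_loss, best_state, since_best = np.inf, None, 0

    model.train()
    for epoch in range(cfg.max_epochs):
        t0 = time.time()
        order = rng.permutation(len(X))
        losses, mpas = [], []
        for i in range(0, len(X), batch):
            idx = order[i:i + batch]
            opt.zero_grad()
            pred = model(X[idx])
            loss = _loss_fn(pred, Y[idx], cfg.loss)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {float(loss.data)!r}; "
                    "lower the learning rate or check the inputs")
            loss.backward()
            opt.step()
            losses.append(loss.item())
            for j in range(len(idx)):
                mpas.append(mean_pixel_accuracy(pred.data[j], Y[idx[j]]))
        record = {"epoch": epoch, "train_loss": float(np.mean(losses)),
                  "mean_pixel_accuracy": float(np.mean(mpas)),
                  "seconds": time.time() - t0}

        monitor = record["train_loss"]
        if X_val is not None:
            vp = predict(model, X_val, batch)
            vl = float(np.mean((vp - Y_val) ** 2)) if cfg.loss == "mse" \
                else float(np.mean(np.abs(vp - Y_val)))
            record["val_loss"] = vl
            monitor = vl
        if cfg.pcc_every and (epoch + 1) % cfg.pcc_every == 0:
            record["train_pcc"] = _dataset_pcc(model, X, Y, batch)
        history.append(record)
        if verbose:
            print("  ".join(f"{k}={v:.4g}" if isinstance(v, float) else f"{k}={v}"
                            for k, v in record.items()))

        if monitor < best_loss:
            best_loss, best_state, since_best = monitor, model.state_dict(), 0
        else:
            since_best += 1
            if cfg.patience is not None and since_best > cfg.patience:
                break
        if (cfg.stop_at_train_pcc is not None
                and record.get("train_pcc", -np.inf) >= cfg.stop_at_train_pcc):
            break

    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return pd.DataFrame(history), best_state


def evaluate(model, X: np.ndarray, Y: np.ndarray, model_name: str = "model",
             batch_size: int = 8, **report_kwargs) -> pd.DataFrame:
    """Per-organelle metric report (means ± std) on a test set."""
    if len(X) == 0:
        raise ValueError("empty test set")
    preds = predict(model, np.asarray(X, dtype=np.float64), batch_size)
    return metrics.build_report(preds, np.asarray(Y, dtype=np.float64),
                                model=model_name, **report_kwargs)


def compare(reports) -> pd.DataFrame:
    """Pairwise relative-change table across model reports.

    ``reports`` is a list of report DataFrames (or one concatenated
    frame).  For every metric, organelle and ordered model pair (a, b)
    the percent change of a over b is computed with the metric's
    direction (NRMSE lower-is-better, the rest higher-is-better).
    """
    if isinstance(reports, pd.DataFrame):
        table = reports
    else:
        table = pd.concat(reports, ignore_index=True)
    models = list(dict.fromkeys(table["model"]))
    rows = []
    for organelle in dict.fromkeys(table["organelle"]):
        sub = table[table["organelle"] == organelle].set_index("model")
        for metric, direction in METRIC_DIRECTIONS.items():
            if metric not in sub.columns:
                continue
            for a in models:
                for b in models:
                    if a == b or a not in sub.index or b not in sub.index:
                        continue
                    rows.append({
                        "organelle": organelle, "metric": metric,
                        "model": a, "reference": b,
                        "pct_change": metrics.relative_change(
                            float(sub.loc[a, metric]), float(sub.loc[b, metric]),
                            direction),
                    })
    return pd.DataFrame(rows)
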