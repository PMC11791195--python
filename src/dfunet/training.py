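"""Training loop, hyper-parameter grid search, and evaluation metrics.

Training follows the published recipe: cross-entropy loss, SGD with
momentum 0.9 (Adam available), learning rate 1e-4, weight decay 1e-3, and a
step scheduler multiplying the rate by gamma = 0.99 every epoch.  Metrics
are confusion-matrix-derived per-class and macro precision/recall/F1 plus
one-vs-rest ROC and PR curves with a macro-averaged AUC.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import (accuracy_score, auc, confusion_matrix,
                             precision_recall_curve, precision_recall_fscore_support,
                             roc_curve)

from . import autodiff as ad
from .autodiff import Tensor, cross_entropy
from .nn import Module
from .assembly import CLASS_NAMES


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    weight_decay: float = 1e-3
    optimizer: str = "sgd"          # "sgd" (momentum) or "adam"
    momentum: float = 0.9
    step_size: int = 1
    gamma: float = 0.99
    epochs: int = 250
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate < 0 or self.weight_decay < 0:
            raise ValueError("learning rate and weight decay must be >= 0")
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must be in (0, 1]")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError("optimizer must be 'sgd' or 'adam'")


class _SGD:
    def __init__(self, params, lr, momentum, weight_decay):
        self.params = list(params)
        self.lr, self.momentum, self.wd = lr, momentum, weight_decay
        self.buf = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self.buf):
            if p.grad is None:
                continue
            g = p.grad + self.wd * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v


class _Adam:
    def __init__(self, params, lr, weight_decay, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr, self.wd, self.betas, self.eps = lr, weight_decay, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad + self.wd * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def scheduled_lr(cfg: TrainConfig, epoch: int) -> float:
    """Learning rate entering ``epoch`` (0-based): lr0 * gamma^(e // step)."""
    return cfg.learning_rate * cfg.gamma ** (epoch // cfg.step_size)


def train_model(model: Module, X: np.ndarray, y: np.ndarray,
                cfg: TrainConfig, X_val: np.ndarray | None = None,
                y_val: np.ndarray | None = None,
                verbose: bool = False) -> dict:
    """Train ``model`` on (X, y); returns a history dict with per-epoch
    loss/accuracy, the best-validation and final state dicts."""
    if len(X) == 0:
        raise ValueError("empty training data")
    rng = np.random.default_rng(cfg.seed)
    make_opt = {
        "sgd": lambda lr: _SGD(model.parameters(), lr, cfg.momentum,
                               cfg.weight_decay),
        "adam": lambda lr: _Adam(model.parameters(), lr, cfg.weight_decay),
    }[cfg.optimizer]
    opt = make_opt(cfg.learning_rate)
    history = {"epoch": [], "lr": [], "train_loss": [], "train_acc": [],
               "val_loss": [], "val_acc": []}
    best = {"val_acc": -1.0, "state": None, "epoch": -1}
    n = len(X)
    for epoch in range(cfg.epochs):
        opt.lr = scheduled_lr(cfg, epoch)
        model.train()
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, cfg.batch_size):
            bidx = order[start:start + cfg.batch_size]
            logits = model(Tensor(X[bidx]))
            loss = cross_entropy(logits, y[bidx])
            if not np.isfinite(loss.item()):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: the learning rate "
                    f"may be too high or the input data corrupted")
            model.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item() * len(bidx))
            correct += int((logits.data.argmax(1) == y[bidx]).sum())
        history["epoch"].append(epoch)
        history["lr"].append(opt.lr)
        history["train_loss"].append(float(np.sum(losses) / n))
        history["train_acc"].append(correct / n)
        if X_val is not None and len(X_val):
            vl, va = _eval_loss_acc(model, X_val, y_val, cfg.batch_size)
            history["val_loss"].append(vl)
            history["val_acc"].append(va)
            if va > best["val_acc"]:
                best.update(val_acc=va, state=model.state_dict(), epoch=epoch)
        else:
            history["val_loss"].append(float("nan"))
            history["val_acc"].append(float("nan"))
        if verbose:
            print(f"epoch {epoch:3d} lr {opt.lr:.2e} "
                  f"loss {history['train_loss'][-1]:.4f} "
                  f"acc {history['train_acc'][-1]:.3f}")
    return {"history": history, "best": best, "final_state": model.state_dict()}


def _eval_loss_acc(model, X, y, batch_size):
    model.eval()
    losses, correct = [], 0
    for start in range(0, len(X), batch_size):
        sl = slice(start, start + batch_size)
        logits = model(Tensor(X[sl]))
        losses.append(cross_entropy(logits, y[sl]).item() * len(X[sl]))
        correct += int((logits.data.argmax(1) == y[sl]).sum())
    return float(np.sum(losses) / len(X)), correct / len(X)


def predict_proba(model: Module, X: np.ndarray, batch_size: int = 32
                  ) -> np.ndarray:
    model.eval()
    out = []
    for start in range(0, len(X), batch_size):
        logits = model(Tensor(X[start:start + batch_size]))
        out.append(ad.softmax(Tensor(logits.data), axis=-1).data)
    return np.concatenate(out)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class ClassMetrics:
    accuracy: float
    per_class: dict[str, dict[str, float]]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    macro_auc: float
    roc_curves: dict[str, tuple[np.ndarray, np.ndarray]]
    pr_curves: dict[str, tuple[np.ndarray, np.ndarray]]
    confusion: np.ndarray

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class": self.per_class,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "macro_auc": self.macro_auc,
            "confusion": self.confusion.tolist(),
        }


def compute_metrics(y_true: np.ndarray, proba: np.ndarray,
                    class_order: tuple[str, ...] = CLASS_NAMES) -> ClassMetrics:
    """Confusion-matrix metrics plus one-vs-rest ROC/PR from scores.

    A class absent from the ground truth has undefined recall/AUC; recall is
    reported as 0 (with a warning) and the class is excluded from macro AUC.
    """
    n_classes = len(class_order)
    y_pred = proba.argmax(axis=1)
    labels = np.arange(n_classes)
    present = np.isin(labels, y_true)
    if not present.all():
        missing = [class_order[i] for i in labels[~present]]
        warnings.warn(f"classes absent from ground truth: {missing}; their "
                      f"recall is reported as 0 and they are excluded from "
                      f"macro AUC")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prec, rec, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=labels, zero_division=0)
    per_class, rocs, prs, aucs = {}, {}, {}, []
    for i, name in enumerate(class_order):
        entry = {"precision": float(prec[i]), "recall": float(rec[i]),
                 "f1": float(f1[i])}
        if present[i]:
            fpr, tpr, _ = roc_curve(y_true == i, proba[:, i])
            p_curve, r_curve, _ = precision_recall_curve(y_true == i,
                                                         proba[:, i])
            entry["auc"] = float(auc(fpr, tpr))
            aucs.append(entry["auc"])
            rocs[name] = (fpr, tpr)
            prs[name] = (r_curve, p_curve)
        per_class[name] = entry
    return ClassMetrics(
        accuracy=float(accuracy_score(y_true, y_pred)),
        per_class=per_class,
        macro_precision=float(prec.mean()),
        macro_recall=float(rec.mean()),
        macro_f1=float(f1.mean()),
        macro_auc=float(np.mean(aucs)) if aucs else float("nan"),
        roc_curves=rocs, pr_curves=prs,
        confusion=confusion_matrix(y_true, y_pred, labels=labels))


def evaluate(model: Module, X: np.ndarray, y: np.ndarray,
             class_order: tuple[str, ...] = CLASS_NAMES,
             batch_size: int = 32) -> ClassMetrics:
    if len(X) == 0:
        raise ValueError("empty evaluation split")
    return compute_metrics(y, predict_proba(model, X, batch_size), class_order)


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------

def grid_search(space: dict[str, list], model_builder, X, y, X_val, y_val,
                base: TrainConfig | None = None) -> tuple[TrainConfig, list[dict]]:
    """Exhaustive search over the cartesian product of ``space`` values in
    lexicographic grid order; selects by validation macro F1 with a
    first-in-order tie break.  ``model_builder`` must return a fresh model
    for each configuration."""
    if not space or any(len(v) == 0 for v in space.values()):
        raise ValueError("grid is empty")
    base = base or TrainConfig()
    keys = sorted(space)
    rows: list[dict] = []
    best_cfg, best_f1 = None, -np.inf
    for values in itertools.product(*(space[k] for k in keys)):
        cfg = TrainConfig(**{**asdict(base), **dict(zip(keys, values))})
        model = model_builder(cfg)
        train_model(model, X, y, cfg)
        metrics = evaluate(model, X_val, y_val)
        row = dict(zip(keys, values))
        row.update(val_macro_f1=metrics.macro_f1, val_accuracy=metrics.accuracy)
        rows.append(row)
        if metrics.macro_f1 > best_f1:   # strict: ties keep the earlier config
            best_f1, best_cfg = metrics.macro_f1, cfg
    return best_cfg, rows
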