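"""Training protocol and hyperparameter sweep harness.

The protocol: Adadelta with cross-entropy loss and a two-phase learning
rate — ``lr_a`` for the first ``epochs_a`` epochs, ``lr_b`` for the
remaining ``epochs_b``. Batches are reshuffled each epoch from the run
seed and the last incomplete batch is kept. No early stopping, weight
decay or augmentation. On a single thread the whole run is a
deterministic function of the seed.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import MJHResNet, ModelConfig
from .nn import softmax_cross_entropy
from .patches import PatchDataset

__all__ = ["TrainConfig", "TrainHistory", "Adadelta", "train_model", "run_sweep"]


@dataclass
class TrainConfig:
    """Optimization settings; defaults follow the two-phase 70/30 protocol."""

    epochs_a: int = 70
    epochs_b: int = 30
    lr_a: float = 1.0
    lr_b: float = 0.1
    batch_size: int = 1024
    rho: float = 0.9  # Adadelta decay
    eps: float = 1e-6  # Adadelta stabilizer
    seed: int = 0
    eval_max: int = 2048  # per-epoch held-out accuracy is measured on at most this many patches

    def __post_init__(self) -> None:
        if self.epochs_a < 1 or self.epochs_b < 0:
            raise ValueError("epoch counts must be positive")
        if self.lr_a <= 0 or self.lr_b <= 0:
            raise ValueError("learning rates must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")

    @property
    def epochs(self) -> int:
        return self.epochs_a + self.epochs_b

    def lr_at(self, epoch: int) -> float:
        """Learning rate for a 0-based epoch index."""
        return self.lr_a if epoch < self.epochs_a else self.lr_b


@dataclass
class TrainHistory:
    """Per-epoch records; all lists share the total epoch count as length."""

    loss: list = field(default_factory=list)
    train_accuracy: list = field(default_factory=list)
    eval_accuracy: list = field(default_factory=list)
    learning_rate: list = field(default_factory=list)
    wall_time: list = field(default_factory=list)


class Adadelta:
    """Adadelta with decaying accumulators of squared gradients and updates.

    The update is ``dx = -lr * sqrt(E[dx^2] + eps) / sqrt(E[g^2] + eps) * g``;
    ``lr`` acts as a plain multiplier on the adaptive step.
    """

    def __init__(self, params: list, rho: float = 0.9, eps: float = 1e-6):
        self.params = params
        self.rho = rho
        self.eps = eps
        self.acc_g = [np.zeros_like(p.value) for p in params]
        self.acc_dx = [np.zeros_like(p.value) for p in params]

    def step(self, lr: float) -> None:
        rho, eps = self.rho, self.eps
        for p, eg, edx in zip(self.params, self.acc_g, self.acc_dx):
            g = p.grad
            eg *= rho
            eg += (1 - rho) * g * g
            delta = np.sqrt(edx + eps) / np.sqrt(eg + eps) * g
            edx *= rho
            edx += (1 - rho) * delta * delta
            p.value -= lr * delta


class DivergenceError(RuntimeError):
    pass


def train_model(
    model: MJHResNet,
    dataset: PatchDataset,
    cfg: TrainConfig,
) -> tuple:
    """Train in place; returns ``(model, TrainHistory)``.

    Requires a dataset with a train split. Held-out accuracy is measured
    each epoch on a fixed seeded subsample of the test split (at most
    ``cfg.eval_max`` patches) with batch-norm in inference mode.
    """
    Xtr, ytr = dataset.train
    if Xtr.shape[0] == 0:
        raise ValueError("dataset has no train split; call split_dataset first")
    Xte, yte = dataset.test
    rng = np.random.default_rng(cfg.seed)
    classes = np.unique(dataset.labels)
    class_to_idx = {c: i for i, c in enumerate(classes)}
    ytr_idx = np.array([class_to_idx[c] for c in ytr])
    yte_idx = np.array([class_to_idx[c] for c in yte])

    if Xte.shape[0] > cfg.eval_max:
        pick = rng.permutation(Xte.shape[0])[: cfg.eval_max]
        Xev, yev = Xte[pick], yte_idx[pick]
    else:
        Xev, yev = Xte, yte_idx

    Xtr_nchw = np.ascontiguousarray(Xtr.transpose(0, 3, 1, 2), dtype=np.float32)
    opt = Adadelta(model.params(), rho=cfg.rho, eps=cfg.eps)
    history = TrainHistory()
    n = Xtr_nchw.shape[0]
    for epoch in range(cfg.epochs):
        t0 = time.time()
        lr = cfg.lr_at(epoch)
        order = rng.permutation(n)
        losses = []
        correct = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = Xtr_nchw[idx], ytr_idx[idx]
            logits = model.forward(xb, train=True)
            loss, dlogits, probs = softmax_cross_entropy(logits, yb)
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite loss at epoch {epoch + 1}")
            model.zero_grad()
            model.backward(dlogits)
            opt.step(lr)
            losses.append(loss * idx.size)
            correct += int((probs.argmax(axis=1) == yb).sum())
        history.loss.append(float(np.sum(losses) / n))
        history.train_accuracy.append(correct / n)
        if Xev.shape[0]:
            pred = model.predict_logits(Xev).argmax(axis=1)
            history.eval_accuracy.append(float((pred == yev).mean()))
        else:
            history.eval_accuracy.append(float("nan"))
        history.learning_rate.append(lr)
        history.wall_time.append(time.time() - t0)
    return model, history


def run_sweep(
    grid: list,
    dataset_for_patch_size,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
) -> pd.DataFrame:
    """Train and evaluate once per grid cell; returns a results table.

    ``grid`` is a list of setting dicts, each overriding ``ModelConfig``
    fields (``kernel``, ``patch_size``) and/or ``TrainConfig`` fields
    (``lr_a``, ``lr_b``, ...). ``dataset_for_patch_size`` maps a patch size
    to a split :class:`PatchDataset` (called once per distinct size). Each
    cell trains from a seed derived reproducibly from the base seed and
    the cell index. The table is sorted by AA (descending) with the best
    cell flagged; per-cell failures are recorded, not fatal.
    """
    from .evaluate import aggregate, confusion_matrix

    if not grid:
        raise ValueError("sweep grid is empty")
    datasets: dict = {}
    records = []
    model_fields = set(ModelConfig.__dataclass_fields__)
    train_fields = set(TrainConfig.__dataclass_fields__)
    for i, setting in enumerate(grid):
        m_over = {k: v for k, v in setting.items() if k in model_fields}
        t_over = {k: v for k, v in setting.items() if k in train_fields}
        unknown = set(setting) - model_fields - train_fields
        if unknown:
            raise ValueError(f"unknown sweep keys {sorted(unknown)}")
        cell_seed = train_cfg.seed + i
        mc = replace(model_cfg, **m_over, seed=cell_seed)
        tc = replace(train_cfg, **t_over, seed=cell_seed)
        row = {**setting, "seed": cell_seed}
        try:
            s = mc.patch_size
            if s not in datasets:
                datasets[s] = dataset_for_patch_size(s)
            ds = datasets[s]
            mc = replace(mc, in_bands=ds.patches.shape[3], n_classes=int(np.unique(ds.labels).size))
            model = MJHResNet(mc)
            model, _ = train_model(model, ds, tc)
            Xte, yte = ds.test
            t0 = time.time()
            classes = np.unique(ds.labels)
            pred = classes[model.predict_logits(Xte).argmax(axis=1)]
            predict_time = time.time() - t0
            cm = confusion_matrix(yte, pred, n_classes=classes.size)
            aa, oa = aggregate(cm)
            row.update({"AA": aa, "OA": oa, "predict_time": predict_time, "error": ""})
        except Exception as exc:  # per-cell failures are recorded
            row.update({"AA": float("nan"), "OA": float("nan"), "predict_time": float("nan"), "error": str(exc)})
        records.append(row)
    table = pd.DataFrame.from_records(records)
    table = table.sort_values("AA", ascending=False, kind="stable").reset_index(drop=True)
    table["best"] = False
    if table["AA"].notna().any():
        table.loc[table["AA"].idxmax(), "best"] = True
    return table
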