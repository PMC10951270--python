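"""Multi-task training: splits, schedules, the training loop, finetuning.

The objective is a weighted sum of spectral-angle losses (whole spectrum,
peptide part, glycan Y part, optionally B part) plus the squared error of
the peptide-fraction ratio; weights are balanced across epochs by dynamic
weight average (DWA).  The learning rate follows linear warmup then cosine
annealing with warm restarts; finetuning instead decays on validation
plateaus.  Frozen parameter groups are excluded from the optimizer and
asserted unchanged bit-wise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .metrics import dp_from_sa, dwa_update
from .nn.autograd import Tape, Tensor
from .nn import autograd as ag
from .nn.layers import Adam
from .network import GlycoSpectrumNetwork
from .spectra import AnnotatedSpectrum

__all__ = [
    "TrainConfig",
    "split_dataset",
    "lr_at",
    "train",
    "finetune",
    "train_b_model",
    "evaluate_spectra",
]


@dataclass
class TrainConfig:
    batch_size: int = 16
    base_lr: float = 0.001
    warmup_epochs: int = 5
    cosine_restart_interval: int = 15
    restart_multiplier: int = 2
    finetune_lr: float = 0.001
    finetune_patience: int = 5
    finetune_factor: float = 0.1
    b_model_lr: float = 0.0001
    seed: int = 0
    max_epochs: int = 60
    dwa_temperature: float = 2.0
    grad_clip: float = 5.0
    plateau_threshold: float = 1e-4

    def __post_init__(self) -> None:
        if min(self.batch_size, self.warmup_epochs, self.max_epochs) <= 0:
            raise ValueError("TrainConfig values must be positive")


def split_dataset(
    records: Sequence, seed: int
) -> tuple[list, list, list]:
    """Random 3/5 train, 1/5 validation, 1/5 holdout split at precursor level."""
    n = len(records)
    if n < 5:
        raise ValueError("need at least 5 records to split 3/5-1/5-1/5")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(n * 3 / 5))
    n_val = int(round(n / 5))
    idx_train = order[:n_train]
    idx_val = order[n_train : n_train + n_val]
    idx_hold = order[n_train + n_val :]
    return (
        [records[i] for i in idx_train],
        [records[i] for i in idx_val],
        [records[i] for i in idx_hold],
    )


def lr_at(epoch: float, config: TrainConfig) -> float:
    """Warmup 0 -> base_lr, then cosine annealing with warm restarts."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    if epoch < config.warmup_epochs:
        return config.base_lr * epoch / config.warmup_epochs
    t = epoch - config.warmup_epochs
    interval = float(config.cosine_restart_interval)
    while t >= interval:
        t -= interval
        interval *= config.restart_multiplier
    return 0.5 * config.base_lr * (1.0 + math.cos(math.pi * t / interval))


_TASKS = ("total", "pep", "gly", "ratio")


def _sample_losses(
    net: GlycoSpectrumNetwork,
    rec: AnnotatedSpectrum,
    training: bool,
    rng: np.random.Generator | None,
) -> dict[str, Tensor]:
    """Per-spectrum loss terms; a part with no matched target ions is skipped."""
    out = net.forward_tensors(rec.index, training=training, rng=rng)
    losses: dict[str, Tensor] = {}
    t_full = rec.full_vector()
    if t_full.sum() > 0:
        losses["total"] = ag.spectral_angle_loss(out["full"], t_full)
    if rec.s_pep.sum() > 0:
        losses["pep"] = ag.spectral_angle_loss(out["pep"], rec.s_pep)
    if rec.s_y.sum() > 0:
        losses["gly"] = ag.spectral_angle_loss(out["y"], rec.s_y)
    t_ratio = rec.ratio if rec.ratio is not None else rec.observed_ratio()
    losses["ratio"] = ag.squared_error(out["ratio"], t_ratio)
    if out["b"] is not None and rec.s_b.sum() > 0:
        losses["B"] = ag.spectral_angle_loss(out["b"], rec.s_b)
    return losses


def _clip_grads(params: dict[str, Tensor], max_norm: float) -> None:
    sq = 0.0
    for p in params.values():
        if p.grad is not None:
            sq += float(np.sum(p.grad * p.grad))
    norm = math.sqrt(sq)
    if norm > max_norm > 0:
        s = max_norm / norm
        for p in params.values():
            if p.grad is not None:
                p.grad *= s


def _validation_loss(
    net: GlycoSpectrumNetwork, records: Sequence[AnnotatedSpectrum]
) -> float:
    """Uniform-weight total objective on a validation set (eval mode)."""
    if not records:
        return math.nan
    total = 0.0
    for rec in records:
        losses = _sample_losses(net, rec, training=False, rng=None)
        total += sum(float(t.data) for t in losses.values())
    return total / len(records)


def _run_training(
    net: GlycoSpectrumNetwork,
    train_set: Sequence[AnnotatedSpectrum],
    val_set: Sequence[AnnotatedSpectrum],
    config: TrainConfig,
    frozen: set[str],
    lr_schedule,
    with_B: bool,
) -> pd.DataFrame:
    params = net.params()
    frozen_snapshot = {k: params[k].data.copy() for k in frozen}
    opt = Adam(params, lr=config.base_lr, frozen=frozen)
    rng = np.random.default_rng(config.seed)
    tasks = _TASKS + ("B",) if with_B else _TASKS
    weights = {k: 1.0 for k in tasks}
    task_history: list[dict[str, float]] = []
    rows = []
    best_val = math.inf
    best_state = net.state_dict()
    n = len(train_set)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        task_sums = {k: 0.0 for k in tasks}
        task_counts = {k: 0 for k in tasks}
        lr_epoch = None
        for start in range(0, n, config.batch_size):
            batch = [train_set[i] for i in order[start : start + config.batch_size]]
            lr = lr_schedule(epoch + start / n)
            lr_epoch = lr if lr_epoch is None else lr_epoch
            opt.zero_grad()
            with Tape() as tape:
                batch_loss = None
                for rec in batch:
                    losses = _sample_losses(net, rec, training=True, rng=rng)
                    for k, t in losses.items():
                        val = float(t.data)
                        if not math.isfinite(val):
                            raise RuntimeError(
                                f"non-finite {k} loss at epoch {epoch}"
                            )
                        task_sums[k] += val
                        task_counts[k] += 1
                        term = ag.scale(t, weights[k] / len(batch))
                        batch_loss = (
                            term
                            if batch_loss is None
                            else ag.add(batch_loss, term)
                        )
                tape.backward(batch_loss)
            _clip_grads(params, config.grad_clip)
            if lr > 0:
                opt.step(lr)
        task_means = {
            k: (task_sums[k] / task_counts[k]) if task_counts[k] else math.nan
            for k in tasks
        }
        task_history.append(task_means)
        val_loss = _validation_loss(net, val_set)
        rows.append(
            {
                "epoch": epoch,
                "lr": lr_epoch,
                "val_loss": val_loss,
                **{f"loss_{k}": task_means[k] for k in tasks},
                **{f"w_{k}": weights[k] for k in tasks},
            }
        )
        if math.isnan(val_loss) or val_loss < best_val:
            if not math.isnan(val_loss):
                best_val = val_loss
            best_state = net.state_dict()
        # DWA weights for the next epoch (first two epochs: uniform)
        if len(task_history) >= 2:
            l1 = [task_history[-1][k] for k in tasks]
            l2 = [task_history[-2][k] for k in tasks]
            if all(math.isfinite(x) and x > 0 for x in l1 + l2):
                w = dwa_update(l1, l2, temperature=config.dwa_temperature)
                weights = dict(zip(tasks, w))
    for k in frozen:
        if not np.array_equal(params[k].data, frozen_snapshot[k]):
            raise AssertionError(f"frozen parameter {k} changed during training")
    net.load_state_dict(best_state)
    return pd.DataFrame(rows)


def train(
    net: GlycoSpectrumNetwork,
    train_set: Sequence[AnnotatedSpectrum],
    val_set: Sequence[AnnotatedSpectrum],
    config: TrainConfig = TrainConfig(),
    frozen: set[str] | None = None,
) -> pd.DataFrame:
    """Multi-task training with warmup + cosine warm restarts.

    Returns the per-epoch history (losses, DWA weights, learning rate,
    validation loss); the network is left at the best-validation checkpoint.
    """
    return _run_training(
        net,
        train_set,
        val_set,
        config,
        frozen or set(),
        lambda e: lr_at(e, config),
        with_B=net.config.with_B,
    )


def finetune(
    net: GlycoSpectrumNetwork,
    train_set: Sequence[AnnotatedSpectrum],
    val_set: Sequence[AnnotatedSpectrum],
    config: TrainConfig = TrainConfig(),
    frozen: set[str] | None = None,
) -> pd.DataFrame:
    """Plateau-decay finetuning: no warmup; lr x0.1 after 5 stale epochs."""
    state = {"lr": config.finetune_lr, "best": math.inf, "stale": 0}

    params = net.params()
    frozen = frozen or set()
    frozen_snapshot = {k: params[k].data.copy() for k in frozen}
    opt = Adam(params, lr=config.finetune_lr, frozen=frozen)
    rng = np.random.default_rng(config.seed)
    tasks = _TASKS + ("B",) if net.config.with_B else _TASKS
    weights = {k: 1.0 for k in tasks}
    task_history: list[dict[str, float]] = []
    rows = []
    best_state = net.state_dict()
    n = len(train_set)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        task_sums = {k: 0.0 for k in tasks}
        task_counts = {k: 0 for k in tasks}
        for start in range(0, n, config.batch_size):
            batch = [train_set[i] for i in order[start : start + config.batch_size]]
            opt.zero_grad()
            with Tape() as tape:
                batch_loss = None
                for rec in batch:
                    losses = _sample_losses(net, rec, training=True, rng=rng)
                    for k, t in losses.items():
                        val = float(t.data)
                        if not math.isfinite(val):
                            raise RuntimeError(
                                f"non-finite {k} loss at epoch {epoch}"
                            )
                        task_sums[k] += val
                        task_counts[k] += 1
                        term = ag.scale(t, weights[k] / len(batch))
                        batch_loss = (
                            term
                            if batch_loss is None
                            else ag.add(batch_loss, term)
                        )
                tape.backward(batch_loss)
            _clip_grads(params, config.grad_clip)
            opt.step(state["lr"])
        task_means = {
            k: (task_sums[k] / task_counts[k]) if task_counts[k] else math.nan
            for k in tasks
        }
        task_history.append(task_means)
        val_loss = _validation_loss(net, val_set)
        improved = val_loss < state["best"] - config.plateau_threshold
        if improved:
            state["best"] = val_loss
            state["stale"] = 0
            best_state = net.state_dict()
        else:
            state["stale"] += 1
            if state["stale"] > config.finetune_patience:
                state["lr"] *= config.finetune_factor
                state["stale"] = 0
        rows.append(
            {
                "epoch": epoch,
                "lr": state["lr"],
                "val_loss": val_loss,
                **{f"loss_{k}": task_means[k] for k in tasks},
                **{f"w_{k}": weights[k] for k in tasks},
            }
        )
        if len(task_history) >= 2:
            l1 = [task_history[-1][k] for k in tasks]
            l2 = [task_history[-2][k] for k in tasks]
            if all(math.isfinite(x) and x > 0 for x in l1 + l2):
                w = dwa_update(l1, l2, temperature=config.dwa_temperature)
                weights = dict(zip(tasks, w))
    for k in frozen:
        if not np.array_equal(params[k].data, frozen_snapshot[k]):
            raise AssertionError(f"frozen parameter {k} changed during finetuning")
    net.load_state_dict(best_state)
    return pd.DataFrame(rows)


def train_b_model(
    net: GlycoSpectrumNetwork,
    train_set: Sequence[AnnotatedSpectrum],
    val_set: Sequence[AnnotatedSpectrum],
    config: TrainConfig = TrainConfig(),
) -> pd.DataFrame:
    """Train the B-ion head on top of a trained base model.

    Everything except the B head is frozen; the learning rate is the lower
    B-model rate scheduled with the same warmup + cosine restarts.  Records
    should already exclude high-mannose glycans and spectra failing the B-ion
    filter.
    """
    if not net.config.with_B:
        raise ValueError("network was built without a B head")
    b_config = TrainConfig(**{**config.__dict__, "base_lr": config.b_model_lr})
    return _run_training(
        net,
        train_set,
        val_set,
        b_config,
        net.non_b_param_names(),
        lambda e: lr_at(e, b_config),
        with_B=True,
    )


def evaluate_spectra(
    net: GlycoSpectrumNetwork, records: Sequence[AnnotatedSpectrum]
) -> pd.DataFrame:
    """Per-spectrum similarity metrics of predictions against annotations."""
    from .metrics import spectral_angle

    rows = []
    for rec in records:
        pred = net.predict(rec.index)
        row: dict = {}
        t_full = rec.full_vector()
        if t_full.sum() > 0 and pred.full.sum() > 0:
            row["sa_total"] = spectral_angle(pred.full, t_full)
            row["dp_total"] = dp_from_sa(row["sa_total"])
        if rec.s_pep.sum() > 0 and pred.pep.sum() > 0:
            row["sa_pep"] = spectral_angle(pred.pep, rec.s_pep)
        if rec.s_y.sum() > 0 and pred.y.sum() > 0:
            row["sa_gly"] = spectral_angle(pred.y, rec.s_y)
        if rec.s_b.sum() > 0 and pred.b.sum() > 0:
            row["sa_B"] = spectral_angle(pred.b, rec.s_b)
        t_ratio = rec.ratio if rec.ratio is not None else rec.observed_ratio()
        row["ratio_error"] = pred.ratio - t_ratio
        rows.append(row)
    return pd.DataFrame(rows)
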