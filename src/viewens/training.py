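"""The two training procedures and the momentum / variable-step optimizer.

Explicit training (held-out validation): every training presentation is a
randomly cropped, stochastically distorted view; gradients accumulate
over ``p_max`` presentations, one momentum update is applied, and the
model is then scored on fixed-offset undistorted views of an independent
validation set.  The checkpoint is refreshed whenever that score sets a
new strict maximum, and the *best* checkpoint (not the final model) is
returned.

Implicit training (no held-out set): the same presentation/update loop,
but after each update the model is scored on the fixed-offset
undistorted views of exactly the ``p_max`` training samples presented in
the just-finished cycle; cycle scores pool into a per-epoch total
accuracy and checkpointing happens only at epoch boundaries.

Optimizer: classical momentum ("inertia") with a multiplicative per-epoch
step decay — step(1) = initial_step, step(e) = step(e-1) * (1 - d(e))
where d(e) is `decay_epochs_2_3` for epochs 2 and 3 and `decay_default`
otherwise.  The schedule is multiplicative because a subtractive reading
of the same constants would drive the step to zero within three epochs,
which is inconsistent with training budgets of hundreds of epochs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .mcnn import MCNNModel, forward_batch, loss_and_grads
from .records import Dataset
from .views import DistortionSpec

__all__ = [
    "TrainingConfig",
    "TrainingError",
    "TrainingHistory",
    "HistoryEntry",
    "step_schedule",
    "bp_update",
    "train_explicit",
    "train_implicit",
]


class TrainingError(RuntimeError):
    """Raised when optimization breaks down (e.g. non-finite gradients)."""


@dataclass(frozen=True)
class TrainingConfig:
    """Optimizer schedule, cycle size and augmentation settings.

    Defaults follow the reference large-scale configuration: initial step
    0.02, per-epoch decay 0.01 except 0.0505 in epochs 2 and 3, p_max =
    560 presentations per update/validation cycle, at most 500 epochs.
    The momentum coefficient is not pinned down by that configuration;
    0.9 is the customary default.
    """

    f2: int
    initial_step: float = 0.02
    decay_default: float = 0.01
    decay_epochs_2_3: float = 0.0505
    momentum: float = 0.9
    p_max: int = 560
    max_epochs: int = 500
    distortion: DistortionSpec = field(default_factory=DistortionSpec)
    val_offset: int = 1
    update_granularity: str = "per_cycle"  # or "per_sample"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_step <= 0:
            raise ValueError("initial_step must be positive")
        for d in (self.decay_default, self.decay_epochs_2_3):
            if not (0 <= d < 1):
                raise ValueError("decay fractions must lie in [0, 1)")
        if self.p_max < 1 or self.max_epochs < 1 or self.f2 < 1:
            raise ValueError("p_max, max_epochs and f2 must be >= 1")
        if self.update_granularity not in ("per_cycle", "per_sample"):
            raise ValueError("update_granularity must be 'per_cycle' or 'per_sample'")


@dataclass
class HistoryEntry:
    scope: str  # "cycle" or "epoch"
    epoch: int
    cycle: int
    step_size: float
    train_loss: float
    val_accuracy: float
    checkpoint_saved: bool
    val_offset: int
    val_distorted: bool = False


@dataclass
class TrainingHistory:
    entries: list[HistoryEntry] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([e.__dict__ for e in self.entries])

    def saved_scores(self) -> list[float]:
        """Validation scores at the checkpoints, in save order."""
        return [e.val_accuracy for e in self.entries if e.checkpoint_saved]

    @property
    def best_val_accuracy(self) -> float:
        scores = self.saved_scores()
        return scores[-1] if scores else float("nan")


def step_schedule(epoch: int, cfg: TrainingConfig) -> float:
    """Learning rate for a 1-based epoch under the multiplicative decay."""
    if epoch < 1:
        raise ValueError("epoch is 1-based")
    step = cfg.initial_step
    for e in range(2, epoch + 1):
        d = cfg.decay_epochs_2_3 if e in (2, 3) else cfg.decay_default
        step *= 1.0 - d
    return step


def bp_update(
    model: MCNNModel,
    grads: dict[str, np.ndarray],
    opt_state: dict[str, np.ndarray] | None,
    step: float,
    momentum: float,
) -> tuple[MCNNModel, dict[str, np.ndarray]]:
    """One momentum step: v <- mu*v - step*g;  w <- w + v.  In-place on model."""
    if opt_state is None:
        opt_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    for name, g in grads.items():
        if not np.all(np.isfinite(g)):
            raise TrainingError(f"non-finite gradient for parameter {name!r}")
        v = opt_state[name]
        v *= momentum
        v -= step * g
        model.params[name] += v
    return model, opt_state


def _stack_views(records, offset: int, f2: int, dtype) -> np.ndarray:
    start = offset - 1
    return np.stack([r.data[:, start : start + f2] for r in records]).astype(dtype)


def _check_train_inputs(train: Dataset, cfg: TrainingConfig, model: MCNNModel) -> int:
    if len(train) == 0:
        raise ValueError("training dataset is empty")
    train.labels()  # rejects unlabeled records
    f1 = train.records[0].n_samples
    if cfg.f2 > f1:
        raise ValueError(f"f2={cfg.f2} exceeds record length F1={f1}")
    if model.config.input_len != cfg.f2:
        raise ValueError(
            f"model input length {model.config.input_len} != configured view length {cfg.f2}"
        )
    p_max = cfg.p_max
    if p_max > len(train):
        warnings.warn(
            f"p_max={p_max} exceeds the {len(train)} training samples; "
            "one cycle per epoch will be used",
            stacklevel=3,
        )
        p_max = len(train)
    return p_max


def _present_batch(data_full, labels, idx_chunk, cfg: TrainingConfig, rng, n_offsets, dtype):
    """Draw a fresh random crop (and stochastic distortion) per presented sample."""
    f2 = cfg.f2
    views = []
    for i in idx_chunk:
        off = int(rng.integers(0, n_offsets))  # 0-based internally
        v = data_full[i][:, off : off + f2]
        if rng.random() < cfg.distortion.probability:
            if cfg.distortion.kind == "uniform":
                noise = rng.uniform(-cfg.distortion.max_amplitude, cfg.distortion.max_amplitude, v.shape)
            else:
                noise = np.zeros(v.shape)
                w = max(1, f2 // 10)
                start = int(rng.integers(0, f2 - w + 1))
                noise[:, start : start + w] = rng.uniform(
                    -cfg.distortion.max_amplitude, cfg.distortion.max_amplitude, (v.shape[0], w)
                )
            v = v + noise
        views.append(v)
    return np.stack(views).astype(dtype), labels[idx_chunk].astype(dtype)


def _train_loop(model, train: Dataset, cfg: TrainingConfig, score_cycle, end_epoch):
    """Shared presentation/update loop; scoring hooks differ per algorithm.

    ``score_cycle(model, idx_chunk, epoch, cycle, step, loss)`` is called
    after each weight update; ``end_epoch(model, epoch)`` after each epoch.
    """
    p_max = _check_train_inputs(train, cfg, model)
    rng = np.random.default_rng(cfg.seed)
    model = model.copy()
    dtype = model.dtype
    data_full = [r.data for r in train.records]
    labels = train.labels()
    n_offsets = train.records[0].n_samples - cfg.f2 + 1
    opt_state = None
    cycle = 0
    for epoch in range(1, cfg.max_epochs + 1):
        step = step_schedule(epoch, cfg)
        order = rng.permutation(len(train))
        for lo in range(0, len(order), p_max):
            idx_chunk = order[lo : lo + p_max]
            xs, ys = _present_batch(data_full, labels, idx_chunk, cfg, rng, n_offsets, dtype)
            if cfg.update_granularity == "per_cycle":
                loss, grads, _ = loss_and_grads(model, xs, ys)
                model, opt_state = bp_update(model, grads, opt_state, step, cfg.momentum)
            else:  # per_sample: one update per presentation, score at cycle end
                losses = []
                for j in range(xs.shape[0]):
                    loss_j, grads, _ = loss_and_grads(model, xs[j : j + 1], ys[j : j + 1])
                    model, opt_state = bp_update(model, grads, opt_state, step, cfg.momentum)
                    losses.append(loss_j)
                loss = float(np.mean(losses))
            cycle += 1
            score_cycle(model, idx_chunk, epoch, cycle, step, loss)
        end_epoch(model, epoch)
    return model


def train_explicit(
    model: MCNNModel, train: Dataset, val: Dataset, cfg: TrainingConfig
) -> tuple[MCNNModel, TrainingHistory]:
    """Crop-and-distort training with held-out validation every cycle."""
    if len(val) == 0:
        raise ValueError("explicit training requires a non-empty validation set")
    val.labels()
    history = TrainingHistory()
    val_x = _stack_views(val.records, cfg.val_offset, cfg.f2, model.dtype)
    val_y = val.labels()
    state = {"best": -np.inf, "best_model": None}

    def score_cycle(m, idx_chunk, epoch, cycle, step, loss):
        probs = forward_batch(m, val_x)
        acc = float(np.mean((probs >= 0.5).astype(int) == val_y))
        saved = acc > state["best"]
        if saved:
            state["best"] = acc
            state["best_model"] = m.copy()
        history.entries.append(
            HistoryEntry("cycle", epoch, cycle, step, loss, acc, saved, cfg.val_offset)
        )

    _train_loop(model, train, cfg, score_cycle, lambda m, e: None)
    return state["best_model"], history


def train_implicit(
    model: MCNNModel, train: Dataset, cfg: TrainingConfig
) -> tuple[MCNNModel, TrainingHistory]:
    """Self-validated training: each cycle is scored on its own samples'
    fixed-offset undistorted views; checkpoints only at epoch ends on the
    pooled (total) accuracy."""
    history = TrainingHistory()
    labels = train.labels()
    state = {"best": -np.inf, "best_model": None, "correct": 0, "total": 0}

    def score_cycle(m, idx_chunk, epoch, cycle, step, loss):
        recs = [train.records[i] for i in idx_chunk]
        vx = _stack_views(recs, cfg.val_offset, cfg.f2, m.dtype)
        probs = forward_batch(m, vx)
        correct = int(np.sum((probs >= 0.5).astype(int) == labels[idx_chunk]))
        state["correct"] += correct
        state["total"] += len(idx_chunk)
        history.entries.append(
            HistoryEntry(
                "cycle", epoch, cycle, step, loss, correct / len(idx_chunk), False, cfg.val_offset
            )
        )

    def end_epoch(m, epoch):
        total_acc = state["correct"] / state["total"]
        state["correct"] = 0
        state["total"] = 0
        saved = total_acc > state["best"]
        if saved:
            state["best"] = total_acc
            state["best_model"] = m.copy()
        history.entries.append(
            HistoryEntry("epoch", epoch, 0, step_schedule(epoch, cfg), np.nan, total_acc, saved, cfg.val_offset)
        )

    _train_loop(model, train, cfg, score_cycle, end_epoch)
    return state["best_model"], history


def pooled_accuracy(correct_counts: list[int], totals: list[int]) -> float:
    """Total accuracy over cycles: sum(correct) / sum(presented)."""
    tot = sum(totals)
    if tot == 0:
        raise ValueError("no samples pooled")
    return sum(correct_counts) / tot
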