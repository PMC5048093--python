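"""Model/Results facade over the training and ensemble machinery.

``MCNNClassifier`` is constructed from datasets plus an architecture and
a training configuration; ``fit()`` runs explicit or implicit training
and returns an ``MCNNResults`` carrying the best checkpoint, the full
training history and evaluation helpers.  ``ViewEnsemble`` fuses several
results by Simple Average.  This mirrors the fit/results idiom of
statistical modelling packages so that the pipeline reads as

    res_a = MCNNClassifier(train_a, val_a, config=cfg, training=tc).fit()
    res_b = MCNNClassifier(train_b, config=cfg_b, training=tc,
                           method="implicit").fit()
    report = ViewEnsemble([res_a, res_b]).evaluate(test, subview_spec)
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .ensemble import PredictionResult, SubviewSpec, ensemble_predict, subview_predict
from .mcnn import ConvUnitSpec, MCNNConfig, MCNNModel, init_model
from .records import Dataset
from .training import TrainingConfig, TrainingHistory, train_explicit, train_implicit

__all__ = ["MCNNClassifier", "MCNNResults", "ViewEnsemble", "tiny_config", "tiny_training_config"]


def tiny_config(n_channels: int = 2, input_len: int = 160) -> MCNNConfig:
    """Small single-stage network paired with the easy synthetic benchmark:
    (160 - 11 + 1) / 10 = 15 samples per map, 4 maps, FC 16."""
    return MCNNConfig(n_channels, input_len, (ConvUnitSpec(11, 10, 4),), fc_width=16)


def tiny_training_config(seed: int = 0, max_epochs: int = 30) -> TrainingConfig:
    """Training settings for the easy benchmark: the reference step schedule
    (0.02 start, 0.01 decay, 0.0505 in epochs 2-3) with the cycle size
    scaled to the 200-record training set (p_max = 10 keeps the
    updates-per-epoch count comparable to the reference 560-of-12320
    configuration); crop length 160 of 200."""
    return TrainingConfig(f2=160, p_max=10, max_epochs=max_epochs, seed=seed)


class MCNNClassifier:
    """A multichannel CNN screening classifier bound to its training data.

    Parameters
    ----------
    train, val : Dataset
        Labeled datasets; ``val`` is required for ``method="explicit"``
        and ignored (may be None) for ``method="implicit"``.
    config : MCNNConfig
        Network architecture.
    training : TrainingConfig
        Optimizer schedule and augmentation settings.
    method : {"explicit", "implicit"}
    init_seed : int
        Seed for the weight initialization (independent of the
        presentation-order seed in ``training.seed``).
    """

    def __init__(
        self,
        train: Dataset,
        val: Dataset | None = None,
        *,
        config: MCNNConfig,
        training: TrainingConfig,
        method: str = "explicit",
        init_seed: int = 0,
    ) -> None:
        if method not in ("explicit", "implicit"):
            raise ValueError("method must be 'explicit' or 'implicit'")
        if method == "explicit" and (val is None or len(val) == 0):
            raise ValueError("explicit training requires a validation dataset")
        self.train_data = train
        self.val_data = val
        self.config = config
        self.training = training
        self.method = method
        self.init_seed = init_seed

    def fit(self) -> "MCNNResults":
        model = init_model(self.config, self.init_seed)
        if self.method == "explicit":
            best, history = train_explicit(model, self.train_data, self.val_data, self.training)
        else:
            best, history = train_implicit(model, self.train_data, self.training)
        return MCNNResults(self, best, history)


class MCNNResults:
    """Best checkpoint of a fitted classifier plus its training history."""

    def __init__(self, spec: MCNNClassifier, model: MCNNModel, history: TrainingHistory):
        self.model_spec = spec
        self.model = model
        self.history = history

    @property
    def best_val_accuracy(self) -> float:
        return self.history.best_val_accuracy

    def predict(
        self, data: Dataset, spec: SubviewSpec | None = None, subview: bool = True
    ) -> pd.DataFrame:
        """Per-record probabilities; columns record_id, prob_abnormal,
        predicted_class.  ``subview=False`` scores only the first offset."""
        spec = spec or SubviewSpec(length=self.model.config.input_len)
        if not subview:
            spec = replace(spec, offsets=(spec.offsets[0],))
        rows = []
        for rec in data:
            r = subview_predict(self.model, rec, spec)
            rows.append((r.record_id, r.prob_abnormal, r.predicted_class))
        return pd.DataFrame(rows, columns=["record_id", "prob_abnormal", "predicted_class"])

    def predict_proba(self, data: Dataset, spec: SubviewSpec | None = None,
                      subview: bool = True) -> np.ndarray:
        return self.predict(data, spec, subview)["prob_abnormal"].to_numpy()

    def evaluate(
        self,
        data: Dataset,
        spec: SubviewSpec | None = None,
        subview: bool = True,
        threshold: float = 0.5,
        npv_target: float = 0.95,
    ) -> _metrics.MetricsReport:
        probs = self.predict_proba(data, spec, subview)
        return _metrics.evaluate(data.labels(), probs, threshold, npv_target)

    def summary(self) -> str:
        spec = self.model_spec
        cfg = self.model.config
        lengths = cfg.stage_lengths()
        lines = [
            "Multichannel CNN screening classifier",
            "=" * 46,
            f"method:            {spec.method} training",
            f"channels:          {cfg.n_channels}",
            f"input length:      {cfg.input_len}",
            f"stage lengths:     {' -> '.join(str(v) for v in lengths)}",
            f"FC fan-in / width: {cfg.fc_input_size} / {cfg.fc_width}",
            f"parameters:        {sum(p.size for p in self.model.params.values())}",
            f"epochs run:        {max((e.epoch for e in self.history.entries), default=0)}",
            f"checkpoints saved: {len(self.history.saved_scores())}",
            f"best val accuracy: {self.best_val_accuracy:.4f}",
        ]
        return "\n".join(lines)


class ViewEnsemble:
    """Simple-Average fusion of fitted members (equal weights)."""

    def __init__(self, members: list[MCNNResults]):
        if not members:
            raise ValueError("at least one member is required")
        self.members = members

    def predict(self, data: Dataset, spec: SubviewSpec | None = None) -> pd.DataFrame:
        spec = spec or SubviewSpec(length=self.members[0].model.config.input_len)
        rows = []
        models = [m.model for m in self.members]
        for rec in data:
            r = ensemble_predict(models, rec, spec)
            rows.append((r.record_id, r.prob_abnormal, r.predicted_class))
        return pd.DataFrame(rows, columns=["record_id", "prob_abnormal", "predicted_class"])

    def evaluate(
        self,
        data: Dataset,
        spec: SubviewSpec | None = None,
        threshold: float = 0.5,
        npv_target: float = 0.95,
    ) -> _metrics.MetricsReport:
        probs = self.predict(data, spec)["prob_abnormal"].to_numpy()
        return _metrics.evaluate(data.labels(), probs, threshold, npv_target)
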