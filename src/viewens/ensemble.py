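"""Subview prediction (test-time crop averaging) and Simple-Average fusion.

Subview prediction extracts n fixed-offset C x F2 crops of a test record,
scores each with the network, and averages the n probabilities.  Simple
Average fuses member classifiers by the per-class arithmetic mean of
their probability vectors, predicting the argmax class.  For a binary
fused probability the decision rule is p >= 0.5 -> abnormal; exact ties
classify abnormal, which is the conservative choice for screening.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mcnn import MCNNModel, forward
from .records import TimeSeriesRecord
from .views import DistortionSpec, LocalViewSpec, add_distortion, extract_local_view

__all__ = [
    "DEFAULT_SUBVIEW_OFFSETS",
    "SubviewSpec",
    "PredictionResult",
    "simple_predict",
    "subview_predict",
    "fuse_simple_average",
    "ensemble_predict",
]

#: The nine reference crop offsets (1-based) for 1700-sample views of
#: 1900-sample records: 1, 26, 51, ..., 201.
DEFAULT_SUBVIEW_OFFSETS: tuple[int, ...] = tuple(range(1, 202, 25))


@dataclass(frozen=True)
class SubviewSpec:
    """Ordered crop offsets plus the view length; distortion defaults off
    at test time."""

    offsets: tuple[int, ...] = DEFAULT_SUBVIEW_OFFSETS
    length: int = 1700
    distort: bool = False
    distortion: DistortionSpec = field(default_factory=DistortionSpec)

    def __post_init__(self) -> None:
        object.__setattr__(self, "offsets", tuple(int(o) for o in self.offsets))
        if len(self.offsets) < 1:
            raise ValueError("at least one offset is required")
        if any(o < 1 for o in self.offsets):
            raise ValueError("offsets are 1-based and must be >= 1")

    def validate_for(self, f1: int) -> None:
        bad = [o for o in self.offsets if o > f1 - self.length + 1]
        if self.length > f1 or bad:
            raise ValueError(
                f"offsets {bad} invalid for F1={f1}, F2={self.length} "
                f"(valid range 1..{f1 - self.length + 1})"
            )


@dataclass
class PredictionResult:
    record_id: str
    prob_abnormal: float
    model_id: str = ""
    per_offset_probs: list[float] | None = None
    offsets: tuple[int, ...] | None = None

    @property
    def predicted_class(self) -> int:
        return int(self.prob_abnormal >= 0.5)


def simple_predict(
    model: MCNNModel, rec: TimeSeriesRecord, offset: int = 1, length: int | None = None,
    model_id: str = "",
) -> PredictionResult:
    """Score a single fixed-offset view (the n=1 case of subview prediction)."""
    length = model.config.input_len if length is None else length
    spec = SubviewSpec(offsets=(offset,), length=length)
    return subview_predict(model, rec, spec, model_id=model_id)


def subview_predict(
    model: MCNNModel,
    rec: TimeSeriesRecord,
    spec: SubviewSpec,
    rng: np.random.Generator | None = None,
    model_id: str = "",
) -> PredictionResult:
    """Average P(abnormal) over the fixed-offset crops of ``spec``."""
    spec.validate_for(rec.n_samples)
    if spec.distort and rng is None:
        rng = np.random.default_rng(0)
    probs = []
    for off in spec.offsets:
        view = extract_local_view(rec, LocalViewSpec(spec.length, off))
        if spec.distort:
            view, _ = add_distortion(view, spec.distortion, rng)
        probs.append(forward(model, view))
    return PredictionResult(
        rec.id, float(np.mean(probs)), model_id, [float(p) for p in probs], spec.offsets
    )


def fuse_simple_average(member_probs) -> tuple[np.ndarray, int]:
    """Equal-weight mean of member per-class probability vectors.

    Members may be scalars p (expanded to (1-p, p)) or length-M vectors
    summing to 1.  Returns (fused vector, argmax class index); for binary
    input class 1 = abnormal, with the tie at 0.5 resolved abnormal.
    """
    vectors = []
    for p in member_probs:
        v = np.atleast_1d(np.asarray(p, dtype=float))
        if v.size == 1:
            v = np.array([1.0 - v[0], v[0]])
        vectors.append(v)
    if not vectors:
        raise ValueError("at least one member is required")
    m = vectors[0].size
    if any(v.size != m for v in vectors):
        raise ValueError("members disagree on the number of classes")
    for v in vectors:
        if abs(v.sum() - 1.0) > 1e-6:
            raise ValueError(f"probability vector {v} does not sum to 1")
    fused = np.mean(vectors, axis=0)
    if m == 2:
        cls = int(fused[1] >= fused[0])  # tie -> abnormal
    else:
        cls = int(np.argmax(fused))
    return fused, cls


def ensemble_predict(
    models: list[MCNNModel],
    rec: TimeSeriesRecord,
    spec: SubviewSpec,
    rng: np.random.Generator | None = None,
    model_ids: list[str] | None = None,
) -> PredictionResult:
    """Subview prediction per member, then Simple-Average fusion."""
    if not models:
        raise ValueError("at least one model is required")
    ids = model_ids or [f"m{i}" for i in range(len(models))]
    member = [subview_predict(m, rec, spec, rng, mid) for m, mid in zip(models, ids)]
    fused, _ = fuse_simple_average([r.prob_abnormal for r in member])
    return PredictionResult(rec.id, float(fused[1]), "+".join(ids), [r.prob_abnormal for r in member])
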