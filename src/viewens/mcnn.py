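"""Multichannel 1D convolutional network (MCNN) with analytic backprop.

Architecture: each channel owns its private stack of convolution units
(CU = valid 1D convolution + non-overlapping max-pooling; no weight
sharing across channels), the per-channel features are concatenated into
one fully connected hidden layer, and a single logistic output unit
yields P(abnormal).  Map connectivity between consecutive stages is full
within a channel.

The shape algebra is exact and enforced at construction: after each
stage the per-map length is (L - kernel_len + 1) / pool_len, which must
be a positive integer.

Gradients are computed analytically in numpy (binary cross-entropy loss)
and are validated against central finite differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .records import TimeSeriesRecord

__all__ = [
    "ConvUnitSpec",
    "MCNNConfig",
    "MCNNModel",
    "preset_config",
    "init_model",
    "forward",
    "forward_batch",
    "loss_and_grads",
    "save_model",
    "load_model",
]

_ACTIVATIONS = ("tanh", "relu", "sigmoid")


@dataclass(frozen=True)
class ConvUnitSpec:
    """One convolution unit: kernel length, pooling length, map count."""

    kernel_len: int
    pool_len: int
    n_maps: int

    def __post_init__(self) -> None:
        if min(self.kernel_len, self.pool_len, self.n_maps) < 1:
            raise ValueError("kernel_len, pool_len and n_maps must all be >= 1")


@dataclass(frozen=True)
class MCNNConfig:
    n_channels: int
    input_len: int
    stages: tuple[ConvUnitSpec, ...]
    fc_width: int = 50
    out_width: int = 1
    activation: str = "tanh"
    share_channels: bool = False  # ablation hook: share CU weights across channels

    def __post_init__(self) -> None:
        if self.n_channels < 1 or self.input_len < 1:
            raise ValueError("n_channels and input_len must be >= 1")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"activation must be one of {_ACTIVATIONS}")
        if self.out_width != 1:
            raise ValueError("only a single logistic output unit is supported")
        object.__setattr__(self, "stages", tuple(self.stages))
        self.stage_lengths()  # raises on broken shape algebra

    def stage_lengths(self) -> list[int]:
        """Per-channel map length after each stage, starting at input_len."""
        lengths = [self.input_len]
        for i, st in enumerate(self.stages):
            conv_len = lengths[-1] - st.kernel_len + 1
            if conv_len < 1:
                raise ValueError(f"stage {i}: kernel {st.kernel_len} longer than input {lengths[-1]}")
            if conv_len % st.pool_len != 0:
                raise ValueError(
                    f"stage {i}: conv output length {conv_len} not divisible by "
                    f"pool length {st.pool_len} (non-overlapping pooling, valid convolution)"
                )
            lengths.append(conv_len // st.pool_len)
        return lengths

    @property
    def fc_input_size(self) -> int:
        """Fan-in of the fully connected layer: C x last-stage maps x last length."""
        last_maps = self.stages[-1].n_maps if self.stages else 1
        return self.n_channels * last_maps * self.stage_lengths()[-1]


def preset_config(name: str) -> MCNNConfig:
    """The two reference architectures.

    MCNN_A: 8 channels x 1700 inputs, kernels (21, 13, 9), pools (7, 6, 6),
    maps (6, 7, 5), FC 50, one logistic output — per-channel lengths
    1700 -> 240 -> 38 -> 5, FC fan-in 200.  MCNN_B: 8 x 1900 with kernels
    (18, 12, 8) — lengths 1900 -> 269 -> 43 -> 6, FC fan-in 240.  MCNN_A is
    used with crop augmentation (1700 < 1900); MCNN_B consumes the whole
    record.
    """
    if name == "MCNN_A":
        stages = (ConvUnitSpec(21, 7, 6), ConvUnitSpec(13, 6, 7), ConvUnitSpec(9, 6, 5))
        return MCNNConfig(8, 1700, stages)
    if name == "MCNN_B":
        stages = (ConvUnitSpec(18, 7, 6), ConvUnitSpec(12, 6, 7), ConvUnitSpec(8, 6, 5))
        return MCNNConfig(8, 1900, stages)
    raise ValueError(f"unknown preset {name!r}; expected 'MCNN_A' or 'MCNN_B'")


@dataclass
class MCNNModel:
    """Configuration plus a flat name -> array parameter dictionary.

    Parameter names: ``conv_w_c{c}_s{s}`` of shape (maps_s, maps_prev,
    kernel_len), ``conv_b_c{c}_s{s}`` of shape (maps_s,), plus ``fc_w``,
    ``fc_b``, ``out_w``, ``out_b``.  With ``share_channels`` the c index
    is fixed at 0.
    """

    config: MCNNConfig
    params: dict[str, np.ndarray]

    def validate(self) -> None:
        for name, arr in self.params.items():
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"parameter {name!r} contains non-finite values")

    def copy(self) -> "MCNNModel":
        return MCNNModel(self.config, {k: v.copy() for k, v in self.params.items()})

    @property
    def dtype(self):
        return self.params["fc_w"].dtype


def _channel_indices(cfg: MCNNConfig) -> list[int]:
    return [0] * cfg.n_channels if cfg.share_channels else list(range(cfg.n_channels))


def init_model(
    cfg: MCNNConfig, seed: int, zero: bool = False, dtype=np.float32
) -> MCNNModel:
    """Glorot-uniform initialization, deterministic given the seed.

    ``zero=True`` is a debug mode: every parameter is 0, so the forward
    output is exactly sigmoid(0) = 0.5 for any input.
    """
    rng = np.random.default_rng(seed)

    def draw(shape, fan_in, fan_out):
        if zero:
            return np.zeros(shape, dtype=dtype)
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=shape).astype(dtype)

    params: dict[str, np.ndarray] = {}
    n_stacks = 1 if cfg.share_channels else cfg.n_channels
    for c in range(n_stacks):
        prev_maps = 1
        for s, st in enumerate(cfg.stages):
            fan_in = prev_maps * st.kernel_len
            fan_out = st.n_maps * st.kernel_len
            params[f"conv_w_c{c}_s{s}"] = draw((st.n_maps, prev_maps, st.kernel_len), fan_in, fan_out)
            params[f"conv_b_c{c}_s{s}"] = np.zeros(st.n_maps, dtype=dtype)
            prev_maps = st.n_maps
    fc_in = cfg.fc_input_size
    params["fc_w"] = draw((cfg.fc_width, fc_in), fc_in, cfg.fc_width)
    params["fc_b"] = np.zeros(cfg.fc_width, dtype=dtype)
    params["out_w"] = draw((cfg.out_width, cfg.fc_width), cfg.fc_width, cfg.out_width)
    params["out_b"] = np.zeros(cfg.out_width, dtype=dtype)
    return MCNNModel(cfg, params)


def _act(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "tanh":
        return np.tanh(z)
    if kind == "relu":
        return np.maximum(z, 0.0)
    return 1.0 / (1.0 + np.exp(-z))


def _act_grad_from_output(h: np.ndarray, kind: str) -> np.ndarray:
    if kind == "tanh":
        return 1.0 - h * h
    if kind == "relu":
        return (h > 0).astype(h.dtype)
    return h * (1.0 - h)


def _conv_valid(a: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Valid cross-correlation: (B, P, L) x (M, P, K) -> (B, M, L-K+1)."""
    k = w.shape[2]
    windows = np.lib.stride_tricks.sliding_window_view(a, k, axis=2)  # (B, P, L-K+1, K)
    return np.einsum("bplk,mpk->bml", windows, w, optimize=True)


def _forward_cache(model: MCNNModel, x: np.ndarray) -> tuple[np.ndarray, dict]:
    """Batched forward pass; returns probabilities (B,) and the backprop cache."""
    cfg = model.config
    act = cfg.activation
    cache: dict = {"channel": []}
    feats = []
    for c, cw in enumerate(_channel_indices(cfg)):
        a = x[:, c : c + 1, :]  # (B, 1, L0)
        stage_cache = []
        for s, st in enumerate(cfg.stages):
            w = model.params[f"conv_w_c{cw}_s{s}"]
            b = model.params[f"conv_b_c{cw}_s{s}"]
            z = _conv_valid(a, w) + b[None, :, None]  # (B, M, Lc)
            bsz, m, lc = z.shape
            zp = z.reshape(bsz, m, lc // st.pool_len, st.pool_len)
            arg = zp.argmax(axis=3)
            zmax = np.take_along_axis(zp, arg[..., None], axis=3)[..., 0]
            h = _act(zmax, act)
            stage_cache.append({"a_in": a, "arg": arg, "h": h, "lc": lc})
            a = h
        cache["channel"].append(stage_cache)
        feats.append(a.reshape(a.shape[0], -1))
    feat = np.concatenate(feats, axis=1)  # (B, fc_in)
    u = feat @ model.params["fc_w"].T + model.params["fc_b"]
    g = _act(u, act)
    v = g @ model.params["out_w"].T + model.params["out_b"]  # (B, 1)
    p = 1.0 / (1.0 + np.exp(-v[:, 0]))
    cache.update({"feat": feat, "g": g, "x": x})
    return p, cache


def _check_input(cfg: MCNNConfig, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x)
    if x.shape != (cfg.n_channels, cfg.input_len):
        raise ValueError(
            f"input shape {x.shape} does not match config "
            f"({cfg.n_channels}, {cfg.input_len})"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    return x


def forward(model: MCNNModel, x: np.ndarray | TimeSeriesRecord) -> float:
    """P(abnormal) for one C x F2 input, strictly in (0, 1)."""
    if isinstance(x, TimeSeriesRecord):
        x = x.data
    x = _check_input(model.config, x)
    p, _ = _forward_cache(model, x[None].astype(model.dtype))
    return float(p[0])


def forward_batch(model: MCNNModel, xs) -> np.ndarray:
    """Vectorized forward over a list/array of C x F2 inputs (order preserved)."""
    arr = np.stack([_check_input(model.config, x.data if isinstance(x, TimeSeriesRecord) else x) for x in xs])
    p, _ = _forward_cache(model, arr.astype(model.dtype))
    return p


def channel_features(model: MCNNModel, x: np.ndarray) -> list[np.ndarray]:
    """Flattened last-stage feature vector per channel (diagnostic helper)."""
    x = _check_input(model.config, x)
    _, cache = _forward_cache(model, x[None].astype(model.dtype))
    cfg = model.config
    feat = cache["feat"][0]
    per = cfg.fc_input_size // cfg.n_channels
    return [feat[c * per : (c + 1) * per].copy() for c in range(cfg.n_channels)]


def loss_and_grads(
    model: MCNNModel, xs: np.ndarray, ys: np.ndarray
) -> tuple[float, dict[str, np.ndarray], np.ndarray]:
    """Mean binary cross-entropy over a batch plus gradients for every parameter.

    ``xs``: (B, C, F2) array; ``ys``: (B,) 0/1 labels.  Returns
    ``(loss, grads, probs)``; gradient arrays mirror ``model.params``.
    """
    cfg = model.config
    act = cfg.activation
    xs = np.asarray(xs, dtype=model.dtype)
    ys = np.asarray(ys, dtype=model.dtype)
    bsz = xs.shape[0]
    p, cache = _forward_cache(model, xs)
    eps = np.finfo(model.dtype).tiny
    loss = float(-np.mean(ys * np.log(p + eps) + (1 - ys) * np.log(1 - p + eps)))

    grads = {k: np.zeros_like(v) for k, v in model.params.items()}
    dv = ((p - ys) / bsz)[:, None]  # (B, 1): d loss / d output pre-activation
    g = cache["g"]
    grads["out_w"] += dv.T @ g
    grads["out_b"] += dv.sum(axis=0)
    dg = dv @ model.params["out_w"]
    du = dg * _act_grad_from_output(g, act)
    grads["fc_w"] += du.T @ cache["feat"]
    grads["fc_b"] += du.sum(axis=0)
    dfeat = du @ model.params["fc_w"]  # (B, fc_in)

    per = cfg.fc_input_size // cfg.n_channels
    for c, cw in enumerate(_channel_indices(cfg)):
        stage_cache = cache["channel"][c]
        last = stage_cache[-1]["h"]
        dh = dfeat[:, c * per : (c + 1) * per].reshape(last.shape)
        for s in range(len(cfg.stages) - 1, -1, -1):
            st = cfg.stages[s]
            sc = stage_cache[s]
            w = model.params[f"conv_w_c{cw}_s{s}"]
            # through activation (applied post-pooling)
            dzmax = dh * _act_grad_from_output(sc["h"], act)  # (B, M, Lp)
            # un-pool: scatter to the argmax position of each window
            b_, m, lp = dzmax.shape
            dz = np.zeros((b_, m, lp, st.pool_len), dtype=model.dtype)
            np.put_along_axis(dz, sc["arg"][..., None], dzmax[..., None], axis=3)
            dz = dz.reshape(b_, m, sc["lc"])  # (B, M, Lc)
            a_in = sc["a_in"]
            k = st.kernel_len
            windows = np.lib.stride_tricks.sliding_window_view(a_in, k, axis=2)
            grads[f"conv_w_c{cw}_s{s}"] += np.einsum("bml,bplk->mpk", dz, windows, optimize=True)
            grads[f"conv_b_c{cw}_s{s}"] += dz.sum(axis=(0, 2))
            if s > 0:
                da = np.zeros_like(a_in)
                for kk in range(k):
                    da[:, :, kk : kk + sc["lc"]] += np.einsum("bml,mp->bpl", dz, w[:, :, kk], optimize=True)
                dh = da
    return loss, grads, p


def save_model(model: MCNNModel, path: str | Path) -> None:
    """Self-describing checkpoint: config JSON + named parameter arrays (.npz)."""
    cfg = model.config
    meta = asdict(cfg)
    meta["stages"] = [asdict(s) for s in cfg.stages]
    meta["format_version"] = 1
    with open(Path(path), "wb") as fh:
        np.savez(
            fh,
            __config__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            **model.params,
        )


def load_model(path: str | Path) -> MCNNModel:
    with np.load(Path(path)) as z:
        meta = json.loads(bytes(z["__config__"]).decode())
        meta.pop("format_version", None)
        stages = tuple(ConvUnitSpec(**s) for s in meta.pop("stages"))
        cfg = MCNNConfig(stages=stages, **meta)
        params = {k: z[k] for k in z.files if k != "__config__"}
    model = MCNNModel(cfg, params)
    model.validate()
    return model
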