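"""The five-class quality classifier: CNN feature extractor, GRU, attention.

The full model (``CNN_GRU_ATT``) consumes a 250 x 40 scalogram as an image:
three convolutional blocks (3x3 conv -> ReLU -> batch norm -> max pool ->
25% dropout) with filter counts doubling 32 -> 64 -> 128; the first block
pools 2x2 and the later blocks pool 1x2 so only the frequency axis keeps
shrinking, preserving temporal structure.  The per-timestep feature maps
are flattened (125 steps x 640 features under the default config), run
through a 50-unit GRU returning the full sequence, a time-distributed
50-unit ReLU dense layer, a context-vector attention pool, and a 5-way
softmax head.  Two ablations drop the GRU (``CNN_ATT``) or the whole
convolutional front end (``GRU_ATT``, which feeds the 40-bin scalogram rows
directly to the GRU).

``gru_step`` and ``attention_pool`` expose the two recurrences as
standalone, single-sample functions so they can be checked against scalar
arithmetic independently of the batched layers.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

from . import layers as L
from .scalogram import Scalogram


@dataclass
class GRUParams:
    """Weights of a single GRU cell (input W, recurrent U, bias b per gate)."""

    W_z: np.ndarray
    W_r: np.ndarray
    W_h: np.ndarray
    U_z: np.ndarray
    U_r: np.ndarray
    U_h: np.ndarray
    b_z: np.ndarray
    b_r: np.ndarray
    b_h: np.ndarray

    @property
    def hidden_size(self) -> int:
        return self.b_z.shape[0]


@dataclass
class AttentionParams:
    """Projection (W, b) and trainable context vector u of the attention pool."""

    W: np.ndarray
    b: np.ndarray
    u: np.ndarray


class NetworkVariant(str, Enum):
    CNN_ATT = "cnn_att"
    GRU_ATT = "gru_att"
    CNN_GRU_ATT = "cnn_gru_att"


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``pool_schedule`` entries are (time, frequency) pool factors per conv
    block; the default halves time once and frequency three times, so a
    (250, 40) input becomes a 125-step sequence of 5*conv_filters[-1]
    features.
    """

    conv_filters: tuple[int, int, int] = (32, 64, 128)
    kernel: tuple[int, int] = (3, 3)
    dropout: float = 0.25
    pool_schedule: tuple[tuple[int, int], ...] = ((2, 2), (1, 2), (1, 2))
    gru_units: int = 50
    dense_units: int = 50
    n_classes: int = 5
    input_shape: tuple[int, int] = (250, 40)
    variant: NetworkVariant = NetworkVariant.CNN_GRU_ATT
    seed: int = 0
    dtype: str = "float64"

    def __post_init__(self) -> None:
        if self.n_classes != 5:
            raise ValueError("the quality classifier is a five-class model")
        f = self.conv_filters
        if not (len(f) == 3 and f[1] == 2 * f[0] and f[2] == 2 * f[1]):
            raise ValueError("conv filter counts must double across the three blocks")
        if self.dtype not in ("float32", "float64"):
            raise ValueError("dtype must be 'float32' or 'float64'")


def desk_scale_config(seed: int = 0, variant=NetworkVariant.CNN_GRU_ATT) -> ModelConfig:
    """A narrow configuration (4/8/16 filters) for CPU-budget experiments.

    Same topology and depth as the default model, reduced channel widths and
    float32 arithmetic so a full cross-validation fits in minutes on one
    core.
    """
    return ModelConfig(conv_filters=(4, 8, 16), variant=variant, seed=seed, dtype="float32")


def gru_step(x_t: np.ndarray, h_prev: np.ndarray, params: GRUParams) -> np.ndarray:
    """One GRU update for a single sample.

    z_t = sigmoid(W_z x_t + U_z h_prev + b_z); r_t likewise;
    h~_t = tanh(W_h x_t + U_h (r_t * h_prev) + b_h);
    h_t = (1 - z_t) * h_prev + z_t * h~_t.
    """
    x_t = np.asarray(x_t, dtype=np.float64)
    h_prev = np.asarray(h_prev, dtype=np.float64)
    p = params
    if x_t.shape[0] != p.W_z.shape[0] or h_prev.shape[0] != p.hidden_size:
        raise ValueError("gru_step: shape mismatch between inputs and parameters")
    z = L.sigmoid(x_t @ p.W_z + h_prev @ p.U_z + p.b_z)
    r = L.sigmoid(x_t @ p.W_r + h_prev @ p.U_r + p.b_r)
    hh = np.tanh(x_t @ p.W_h + (r * h_prev) @ p.U_h + p.b_h)
    return (1 - z) * h_prev + z * hh


def attention_pool(
    h_seq: np.ndarray, params: AttentionParams
) -> tuple[np.ndarray, np.ndarray]:
    """Attention-weighted summary of a (T, D) hidden sequence.

    Returns (v, alpha): the context representation v = sum_t alpha_t h_t and
    the softmax attention weights alpha (sum to 1).
    """
    h_seq = np.asarray(h_seq, dtype=np.float64)
    if h_seq.ndim != 2 or h_seq.shape[0] < 1:
        raise ValueError("attention_pool expects a non-empty (T, D) sequence")
    ut = np.tanh(h_seq @ params.W + params.b)
    alpha = L.softmax(ut @ params.u, axis=0)
    v = alpha @ h_seq
    return v, alpha


class QualityModel:
    """A layer stack with softmax head over the five quality classes."""

    def __init__(self, cfg: ModelConfig, layer_list: list[L.Layer]):
        self.cfg = cfg
        self.layers = layer_list

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a batch of scalograms (B, 250, 40) or (B, 250, 40, 1)."""
        x = np.asarray(x, dtype=np.dtype(self.cfg.dtype))
        if x.ndim == 3:
            x = x[..., None]
        out = x
        for layer in self.layers:
            out = layer.forward(out, train)
        return out

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities (rows sum to 1) in inference mode."""
        return L.softmax(self.forward(np.asarray(x)), axis=-1)

    def get_weights(self):
        state = [copy.deepcopy(layer.params) for layer in self.layers]
        bn = [
            (layer._mean_acc.copy(), layer._var_acc.copy(), layer._updates)
            if isinstance(layer, L.BatchNorm)
            else None
            for layer in self.layers
        ]
        return state, bn

    def set_weights(self, weights) -> None:
        state, bn = weights
        for layer, params, stats in zip(self.layers, state, bn):
            for k in layer.params:
                layer.params[k] = params[k].copy()
            if stats is not None:
                layer._mean_acc = stats[0].copy()
                layer._var_acc = stats[1].copy()
                layer._updates = stats[2]

    def n_parameters(self) -> int:
        return sum(p.size for layer in self.layers for p in layer.params.values())

    def gru_params(self) -> GRUParams:
        for layer in self.layers:
            if isinstance(layer, L.GRULayer):
                return GRUParams(**{k: v.copy() for k, v in layer.params.items()})
        raise ValueError(f"variant {self.cfg.variant} has no GRU layer")

    def attention_params(self) -> AttentionParams:
        for layer in self.layers:
            if isinstance(layer, L.AttentionPool):
                return AttentionParams(**{k: v.copy() for k, v in layer.params.items()})
        raise AssertionError("model has no attention layer")


def _conv_blocks(cfg: ModelConfig, rng, init_rng) -> tuple[list[L.Layer], int, int]:
    stack: list[L.Layer] = []
    t, f = cfg.input_shape
    in_ch = 1
    for filters, pool in zip(cfg.conv_filters, cfg.pool_schedule):
        stack += [
            L.Conv3x3(in_ch, filters, init_rng),
            L.ReLU(),
            L.BatchNorm(filters),
            L.MaxPool(pool),
            L.Dropout(cfg.dropout, rng),
        ]
        t //= pool[0]
        f //= pool[1]
        in_ch = filters
    return stack, t, f * in_ch


def build_model(cfg: ModelConfig) -> QualityModel:
    """Assemble the requested variant with seeded weight initialisation."""
    init_rng = np.random.default_rng(cfg.seed)
    drop_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    stack: list[L.Layer] = []
    if cfg.variant in (NetworkVariant.CNN_GRU_ATT, NetworkVariant.CNN_ATT):
        conv, _, feat = _conv_blocks(cfg, drop_rng, init_rng)
        stack += conv
        stack.append(L.FlattenTime())
    elif cfg.variant == NetworkVariant.GRU_ATT:
        stack.append(L.SqueezeChannel())
        feat = cfg.input_shape[1]
    else:
        raise ValueError(f"unknown variant {cfg.variant!r}")

    if cfg.variant in (NetworkVariant.CNN_GRU_ATT, NetworkVariant.GRU_ATT):
        stack.append(L.GRULayer(feat, cfg.gru_units, init_rng))
        feat = cfg.gru_units
    stack += [
        L.Dense(feat, cfg.dense_units, init_rng),
        L.ReLU(),
        L.AttentionPool(cfg.dense_units, init_rng),
        L.Dense(cfg.dense_units, cfg.n_classes, init_rng),
    ]
    if cfg.dtype != "float64":
        dt = np.dtype(cfg.dtype)
        for layer in stack:
            for k in layer.params:
                layer.params[k] = layer.params[k].astype(dt)
            layer.zero_grads()
            if isinstance(layer, L.BatchNorm):
                layer._mean_acc = layer._mean_acc.astype(dt)
                layer._var_acc = layer._var_acc.astype(dt)
    return QualityModel(cfg, stack)


def predict_window(scalogram: Scalogram | np.ndarray, model: QualityModel) -> np.ndarray:
    """Five-class probability vector for one scalogram (deterministic)."""
    values = scalogram.values if isinstance(scalogram, Scalogram) else scalogram
    values = np.asarray(values, dtype=np.float64)
    if values.shape != model.cfg.input_shape:
        raise ValueError(
            f"scalogram shape {values.shape}, expected {model.cfg.input_shape}"
        )
    return model.predict_proba(values[None])[0]


def save_checkpoint(path, model: QualityModel) -> None:
    """Write weights (.npz) and the architecture config (JSON) side by side."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for i, layer in enumerate(model.layers):
        for k, v in layer.params.items():
            arrays[f"{i}/{k}"] = v
        if isinstance(layer, L.BatchNorm):
            arrays[f"{i}/running_mean"] = layer.running_mean
            arrays[f"{i}/running_var"] = layer.running_var
    np.savez(path / "weights.npz", **arrays)
    cfg = model.cfg
    (path / "config.json").write_text(
        json.dumps(
            {
                "conv_filters": list(cfg.conv_filters),
                "kernel": list(cfg.kernel),
                "dropout": cfg.dropout,
                "pool_schedule": [list(p) for p in cfg.pool_schedule],
                "gru_units": cfg.gru_units,
                "dense_units": cfg.dense_units,
                "n_classes": cfg.n_classes,
                "input_shape": list(cfg.input_shape),
                "variant": cfg.variant.value,
                "seed": cfg.seed,
                "dtype": cfg.dtype,
            },
            indent=1,
        )
    )


def load_checkpoint(path) -> QualityModel:
    path = Path(path)
    raw = json.loads((path / "config.json").read_text())
    cfg = ModelConfig(
        conv_filters=tuple(raw["conv_filters"]),
        kernel=tuple(raw["kernel"]),
        dropout=raw["dropout"],
        pool_schedule=tuple(tuple(p) for p in raw["pool_schedule"]),
        gru_units=raw["gru_units"],
        dense_units=raw["dense_units"],
        n_classes=raw["n_classes"],
        input_shape=tuple(raw["input_shape"]),
        variant=NetworkVariant(raw["variant"]),
        seed=raw["seed"],
        dtype=raw.get("dtype", "float64"),
    )
    model = build_model(cfg)
    with np.load(path / "weights.npz") as data:
        for i, layer in enumerate(model.layers):
            for k in layer.params:
                layer.params[k] = data[f"{i}/{k}"]
            if isinstance(layer, L.BatchNorm):
                layer.set_running_stats(
                    data[f"{i}/running_mean"], data[f"{i}/running_var"]
                )
    return model
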