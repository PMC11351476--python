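"""Depthwise-separable spatiotemporal CNN for single-trial classification.

The backbone learns F1 temporal band-pass-like filters of length 20 (~half a
second at 39 Hz), then D spatial filters spanning all C voxels per temporal
filter (a depthwise convolution, max-norm 1), then a separable convolution
(depthwise length-20 temporal summary + F2 pointwise mixers), average pooling
over 8 samples, and a single sigmoid output unit (max-norm 0.25).  Output
probability > threshold (default 0.5) is read as a right-hand response,
otherwise left.

Weight-norm constraints are enforced by projection after every optimizer
step.  A dual-input variant runs one backbone per co-recorded modality
(phase / intensity) and concatenates the flattened features before the head.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn


@dataclass
class ModelConfig:
    C: int = 42                 # flattened input voxels
    T: int = 56                 # time samples per trial
    F1: int = 8                 # temporal filters
    D: int = 2                  # spatial filters per temporal filter
    F2: int = 16                # pointwise filters
    temporal_kernel: int = 20
    separable_kernel: int = 20
    pool: int = 8
    dropout_p: float = 0.5
    depthwise_max_norm: float = 1.0
    dense_max_norm: float = 0.25
    decision_threshold: float = 0.5
    bn_momentum: float = 0.1
    bn_eps: float = 1e-5

    def __post_init__(self) -> None:
        if min(self.C, self.T, self.F1, self.D, self.F2,
               self.temporal_kernel, self.separable_kernel, self.pool) < 1:
            raise ValueError("all architecture counts must be positive")
        if not (0.0 <= self.dropout_p < 1.0):
            raise ValueError("dropout_p must lie in [0, 1)")
        if self.T < self.pool:
            raise ValueError("T must be at least the pooling kernel")

    @property
    def n_features(self) -> int:
        """Flattened feature length entering the dense head: F2 * (T // pool)."""
        return self.F2 * (self.T // self.pool)


@dataclass
class LayerSpec:
    name: str
    n_filters: int | None
    size: tuple | None
    n_params: int
    output_shape: tuple
    activation: str | None
    options: str = ""


@dataclass
class NetworkSpec:
    layers: list[LayerSpec]

    @property
    def total_params(self) -> int:
        return sum(l.n_params for l in self.layers)

    def to_table(self):
        import pandas as pd
        return pd.DataFrame([asdict(l) for l in self.layers])


def count_parameters(cfg: ModelConfig) -> dict[str, int]:
    """Per-layer trainable-parameter counts (convolutions are bias-free;
    batch-norm contributes its scale and shift; the dense head has a bias)."""
    counts = {
        "temporal_conv": cfg.temporal_kernel * cfg.F1,
        "batchnorm_1": 2 * cfg.F1,
        "depthwise_conv": cfg.C * cfg.D * cfg.F1,
        "batchnorm_2": 2 * cfg.D * cfg.F1,
        "separable_conv": cfg.separable_kernel * cfg.D * cfg.F1 + cfg.F2 * (cfg.D * cfg.F1),
        "batchnorm_3": 2 * cfg.F2,
        "dense": cfg.n_features + 1,
    }
    counts["total"] = sum(counts.values())
    return counts


def network_spec(cfg: ModelConfig) -> NetworkSpec:
    counts = count_parameters(cfg)
    c, t, f1, d, f2 = cfg.C, cfg.T, cfg.F1, cfg.D, cfg.F2
    tp = t // cfg.pool
    return NetworkSpec([
        LayerSpec("input", None, None, 0, (c, t), None),
        LayerSpec("reshape", None, None, 0, (1, c, t), None),
        LayerSpec("conv2d_temporal", f1, (1, cfg.temporal_kernel),
                  counts["temporal_conv"], (f1, c, t), "linear", "mode=same, no bias"),
        LayerSpec("batchnorm", None, None, counts["batchnorm_1"], (f1, c, t), None),
        LayerSpec("depthwise_conv2d", d * f1, (c, 1), counts["depthwise_conv"],
                  (d * f1, 1, t), "linear", f"mode=valid, depth={d}, max_norm={cfg.depthwise_max_norm}"),
        LayerSpec("batchnorm", None, None, counts["batchnorm_2"], (d * f1, 1, t), None),
        LayerSpec("activation", None, None, 0, (d * f1, 1, t), "elu"),
        LayerSpec("dropout", None, None, 0, (d * f1, 1, t), None, f"p={cfg.dropout_p}"),
        LayerSpec("separable_conv2d", f2, (1, cfg.separable_kernel),
                  counts["separable_conv"], (f2, 1, t), "linear", "mode=same, no bias"),
        LayerSpec("batchnorm", None, None, counts["batchnorm_3"], (f2, 1, t), None),
        LayerSpec("activation", None, None, 0, (f2, 1, t), "elu"),
        LayerSpec("avgpool2d", None, (1, cfg.pool), 0, (f2, 1, tp), None),
        LayerSpec("dropout", None, None, 0, (f2, 1, tp), None, f"p={cfg.dropout_p}"),
        LayerSpec("flatten", None, None, 0, (f2 * tp,), None),
        LayerSpec("dense", 1, None, counts["dense"], (1,), "sigmoid",
                  f"max_norm={cfg.dense_max_norm}"),
    ])


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def _backbone_layers(cfg: ModelConfig, rng: np.random.Generator) -> list[nn.Layer]:
    """Everything from the (N,1,C,T) input through the flattened features."""
    if cfg.T < cfg.temporal_kernel // 2 or cfg.C < 1:
        raise ValueError("input smaller than kernel requirements")
    return [
        nn.TemporalConv(cfg.F1, cfg.temporal_kernel, rng),
        nn.BatchNorm(cfg.F1, cfg.bn_momentum, cfg.bn_eps),
        nn.DepthwiseSpatialConv(cfg.F1, cfg.D, cfg.C, rng),
        nn.BatchNorm(cfg.D * cfg.F1, cfg.bn_momentum, cfg.bn_eps),
        nn.ELU(),
        nn.Dropout(cfg.dropout_p, rng),
        nn.SeparableConv(cfg.D * cfg.F1, cfg.separable_kernel, cfg.F2, rng),
        nn.BatchNorm(cfg.F2, cfg.bn_momentum, cfg.bn_eps),
        nn.ELU(),
        nn.AvgPool(cfg.pool),
        nn.Dropout(cfg.dropout_p, rng),
        nn.Flatten(),
    ]


class Network:
    """Single-input classifier: backbone + dense + sigmoid."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0xC0]))
        layers = _backbone_layers(cfg, rng)
        self.dense = nn.Dense(cfg.n_features, 1, rng)
        layers += [self.dense, nn.Sigmoid()]
        self.seq = nn.Sequential(layers)
        self.depthwise = next(l for l in layers if isinstance(l, nn.DepthwiseSpatialConv))

    # -- inference ----------------------------------------------------------
    def _as_batch(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        if x.ndim != 3 or x.shape[1] != self.cfg.C or x.shape[2] != self.cfg.T:
            raise ValueError(f"expected trials of shape ({self.cfg.C}, {self.cfg.T}), "
                             f"got {x.shape}")
        return x[:, None, :, :]

    def forward_logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        h = self._as_batch(x)
        for layer in self.seq.layers[:-1]:
            h = layer.forward(h, training)
        return h

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Deterministic evaluation-mode forward pass: probabilities in [0,1]."""
        h = self._as_batch(x)
        return self.seq.forward(h, training=False).ravel()

    def backward(self, g: np.ndarray, *, from_logits: bool = True) -> None:
        layers = self.seq.layers[:-1] if from_logits else self.seq.layers
        for layer in reversed(layers):
            g = layer.backward(g)

    # -- parameters ---------------------------------------------------------
    def params(self) -> list[nn.Param]:
        return self.seq.params()

    def n_trainable(self) -> int:
        return sum(p.value.size for p in self.params())

    def get_weights(self) -> list[np.ndarray]:
        state = [p.value.copy() for p in self.params()]
        state += [l.running_mean.copy() for l in self.seq.layers if isinstance(l, nn.BatchNorm)]
        state += [l.running_var.copy() for l in self.seq.layers if isinstance(l, nn.BatchNorm)]
        return state

    def set_weights(self, state: list[np.ndarray]) -> None:
        ps = self.params()
        bns = [l for l in self.seq.layers if isinstance(l, nn.BatchNorm)]
        if len(state) != len(ps) + 2 * len(bns):
            raise ValueError("weight list does not match the network")
        for p, v in zip(ps, state[:len(ps)]):
            p.value[...] = v
        for l, v in zip(bns, state[len(ps):len(ps) + len(bns)]):
            l.running_mean[...] = v
        for l, v in zip(bns, state[len(ps) + len(bns):]):
            l.running_var[...] = v


class DualNetwork:
    """Two parallel backbones (one per modality) feeding a shared dense head."""

    def __init__(self, cfg_a: ModelConfig, cfg_b: ModelConfig, seed: int = 0):
        if cfg_a.T != cfg_b.T:
            raise ValueError("both modalities must share the epoch length T")
        self.cfg_a, self.cfg_b = cfg_a, cfg_b
        rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0xD0]))
        self.branch_a = nn.Sequential(_backbone_layers(cfg_a, rng))
        self.branch_b = nn.Sequential(_backbone_layers(cfg_b, rng))
        self.n_features = cfg_a.n_features + cfg_b.n_features
        self.dense = nn.Dense(self.n_features, 1, rng)
        self.sigmoid = nn.Sigmoid()
        self.cfg = cfg_a  # threshold and norms are read from the first config

    def _as_batches(self, x) -> tuple[np.ndarray, np.ndarray]:
        xa, xb = x
        xa = np.asarray(xa, dtype=np.float64)
        xb = np.asarray(xb, dtype=np.float64)
        if xa.ndim == 2:
            xa, xb = xa[None], xb[None]
        return xa[:, None, :, :], xb[:, None, :, :]

    def forward_logits(self, x, training: bool = False) -> np.ndarray:
        xa, xb = self._as_batches(x)
        fa = self.branch_a.forward(xa, training)
        fb = self.branch_b.forward(xb, training)
        self._split = fa.shape[1]
        return self.dense.forward(np.concatenate([fa, fb], axis=1), training)

    def predict_proba(self, x) -> np.ndarray:
        return self.sigmoid.forward(self.forward_logits(x, False), False).ravel()

    def backward(self, g: np.ndarray, *, from_logits: bool = True) -> None:
        if not from_logits:
            g = self.sigmoid.backward(g)
        g = self.dense.backward(g)
        self.branch_a.backward(g[:, :self._split])
        self.branch_b.backward(g[:, self._split:])

    def params(self) -> list[nn.Param]:
        return self.branch_a.params() + self.branch_b.params() + self.dense.params()

    def n_trainable(self) -> int:
        return sum(p.value.size for p in self.params())

    def get_weights(self) -> list[np.ndarray]:
        out = [p.value.copy() for p in self.params()]
        for seq in (self.branch_a, self.branch_b):
            for l in seq.layers:
                if isinstance(l, nn.BatchNorm):
                    out.append(l.running_mean.copy())
                    out.append(l.running_var.copy())
        return out

    def set_weights(self, state: list[np.ndarray]) -> None:
        ps = self.params()
        for p, v in zip(ps, state[:len(ps)]):
            p.value[...] = v
        i = len(ps)
        for seq in (self.branch_a, self.branch_b):
            for l in seq.layers:
                if isinstance(l, nn.BatchNorm):
                    l.running_mean[...] = state[i]
                    l.running_var[...] = state[i + 1]
                    i += 2


def build_network(cfg: ModelConfig, seed: int = 0) -> tuple[Network, NetworkSpec]:
    """Construct the trainable network and its layer-by-layer description."""
    return Network(cfg, seed=seed), network_spec(cfg)


def build_dual(cfg_phase: ModelConfig, cfg_intensity: ModelConfig,
               seed: int = 0) -> DualNetwork:
    return DualNetwork(cfg_phase, cfg_intensity, seed=seed)


# ---------------------------------------------------------------------------
# constraints and decisions
# ---------------------------------------------------------------------------

def _project_rows(w: np.ndarray, axis: int, max_norm: float) -> None:
    norms = np.linalg.norm(w, axis=axis, keepdims=True)
    scale = np.minimum(1.0, max_norm / np.maximum(norms, 1e-12))
    w *= scale


def constrain_weights(net: Network | DualNetwork, cfg: ModelConfig | None = None
                      ) -> Network | DualNetwork:
    """Project weights onto their norm balls: each depthwise spatial filter to
    L2 norm <= depthwise max-norm, each dense row to <= dense max-norm.
    Idempotent; weights already within bounds are untouched."""
    cfg = cfg or net.cfg
    if isinstance(net, DualNetwork):
        for seq in (net.branch_a, net.branch_b):
            for l in seq.layers:
                if isinstance(l, nn.DepthwiseSpatialConv):
                    _project_rows(l.w.value, 2, cfg.depthwise_max_norm)
        _project_rows(net.dense.w.value, 1, cfg.dense_max_norm)
        return net
    _project_rows(net.depthwise.w.value, 2, cfg.depthwise_max_norm)
    _project_rows(net.dense.w.value, 1, cfg.dense_max_norm)
    return net


def forward(net: Network | DualNetwork, trial) -> float | np.ndarray:
    """Evaluation-mode probability for one trial (scalar) or a batch."""
    p = net.predict_proba(trial)
    return float(p[0]) if p.size == 1 else p


def predict_label(probability, threshold: float = 0.5):
    """'right' iff the probability strictly exceeds the threshold, else 'left'
    (a probability exactly at threshold is read as a left response)."""
    p = np.asarray(probability, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    labels = np.where(p > threshold, "right", "left")
    return str(labels[()]) if labels.ndim == 0 else labels


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, net: Network, cfg: ModelConfig) -> None:
    weights = net.get_weights()
    np.savez(path, n_arrays=len(weights),
             config=json.dumps(asdict(cfg)),
             **{f"w{i}": w for i, w in enumerate(weights)})


def load_checkpoint(path) -> tuple[Network, ModelConfig]:
    with np.load(path, allow_pickle=False) as f:
        cfg = ModelConfig(**json.loads(str(f["config"])))
        net = Network(cfg)
        net.set_weights([f[f"w{i}"] for i in range(int(f["n_arrays"]))])
    return net, cfg
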