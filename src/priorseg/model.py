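"""Network specification, shape arithmetic, forward pass and training loss.

The architecture is a 3D fully convolutional network: ``depth`` unpadded
3x3x3 convolutional layers (ELU) whose outputs are centrally cropped and
concatenated by a dense connection, batch-normalized, then processed by two
1x1x1 convolutional layers (128 and 64 filters, ELU, dropout p = 0.1) and a
1x1x1 classifier producing a per-voxel softmax over C classes.  Each valid
3x3x3 convolution shrinks the spatial side by two voxels, so a depth-8
network maps a 25^3 input onto a 9^3 output; deeper variants add two voxels
of input side per extra layer.

The training loss is categorical cross-entropy averaged over batch and
voxels plus an l2 penalty on the convolution filters (weight decay alpha,
default 1e-4); biases and batch-norm parameters are not penalized.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn

__all__ = [
    "LayerSpec",
    "NetworkSpec",
    "LossConfig",
    "output_side",
    "required_input_side",
    "build_network",
    "count_parameters",
    "Network",
    "loss",
    "softmax",
]

HEAD_WIDTHS = (128, 64)
DROPOUT_P = 0.1


@dataclass(frozen=True)
class LayerSpec:
    """One layer of the declarative network description."""

    kind: str  # conv3 | dense_connection | batch_norm | conv1 | classifier
    filters: int = 0
    kernel: int = 0
    nonlinearity: str = "none"  # ELU | spatial_softmax | none
    dropout_p: float = 0.0


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyperparameters plus the ordered layer list."""

    depth: int
    width: int
    in_channels: int
    n_classes: int
    layers: tuple[LayerSpec, ...] = field(default=())

    @property
    def dense_channels(self) -> int:
        return self.depth * self.width

    def output_side(self, input_side: int) -> int:
        return output_side(input_side, self.depth)

    def required_input_side(self, out_side: int) -> int:
        return required_input_side(out_side, self.depth)


def output_side(input_side: int, depth: int) -> int:
    """Spatial side after ``depth`` valid 3x3x3 convolutions: in - 2*depth."""
    if input_side <= 0:
        raise ValueError("input side must be positive")
    out = input_side - 2 * depth
    if out <= 0:
        raise ValueError(f"input side {input_side} too small for depth {depth}")
    return out


def required_input_side(out_side: int, depth: int) -> int:
    """Inverse of :func:`output_side`: the input side producing ``out_side``."""
    if out_side <= 0:
        raise ValueError("output side must be positive")
    return out_side + 2 * depth


def build_network(depth: int, width: int, in_channels: int, n_classes: int) -> NetworkSpec:
    """Declarative spec: depth x conv3(width) -> dense connection ->
    batch norm -> conv1(128)+dropout -> conv1(64)+dropout -> classifier(C)."""
    if depth < 1 or width < 1 or in_channels < 1:
        raise ValueError("depth, width and in_channels must be >= 1")
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    layers = [LayerSpec("conv3", filters=width, kernel=3, nonlinearity="ELU") for _ in range(depth)]
    layers.append(LayerSpec("dense_connection", filters=depth * width))
    layers.append(LayerSpec("batch_norm", filters=depth * width))
    layers.append(LayerSpec("conv1", filters=HEAD_WIDTHS[0], kernel=1, nonlinearity="ELU", dropout_p=DROPOUT_P))
    layers.append(LayerSpec("conv1", filters=HEAD_WIDTHS[1], kernel=1, nonlinearity="ELU", dropout_p=DROPOUT_P))
    layers.append(LayerSpec("classifier", filters=n_classes, kernel=1, nonlinearity="spatial_softmax"))
    return NetworkSpec(depth=depth, width=width, in_channels=in_channels, n_classes=n_classes, layers=tuple(layers))


def count_parameters(spec: NetworkSpec) -> int:
    """Exact learnable-parameter count: filters + biases per convolution plus
    one scale/shift pair per dense-connection channel."""
    total = 0
    cin = spec.in_channels
    for layer in spec.layers:
        if layer.kind == "conv3":
            total += 27 * cin * layer.filters + layer.filters
            cin = layer.filters
        elif layer.kind == "dense_connection":
            cin = layer.filters
        elif layer.kind == "batch_norm":
            total += 2 * layer.filters
        elif layer.kind in ("conv1", "classifier"):
            total += cin * layer.filters + layer.filters
            cin = layer.filters
    return total


@dataclass
class LossConfig:
    """weight_decay: l2 penalty on convolution filters; prob_clip: floor
    applied to probabilities before the log."""

    weight_decay: float = 1e-4
    prob_clip: float = 1e-7

    def __post_init__(self) -> None:
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")
        if not 0 < self.prob_clip < 0.5:
            raise ValueError("prob_clip must be in (0, 0.5)")


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(probabilities: np.ndarray, targets: np.ndarray, prob_clip: float = 1e-7) -> float:
    """J = -(1/(B*V)) sum_{c,b,v} t log p, with p clipped to [eps, 1-eps].

    ``probabilities`` and ``targets`` are (B, ..., C); targets must lie on the
    probability simplex per voxel.
    """
    p = np.asarray(probabilities, dtype=np.float64)
    t = np.asarray(targets, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: probabilities {p.shape} vs targets {t.shape}")
    sums = t.sum(axis=-1)
    if not np.allclose(sums, 1.0, atol=1e-5):
        raise ValueError("targets must sum to 1 over classes at every voxel")
    n = p.size // p.shape[-1]  # B * V
    p = np.clip(p, prob_clip, 1.0 - prob_clip)
    return float(-(t * np.log(p)).sum() / n)


def loss(
    probabilities: np.ndarray,
    targets: np.ndarray,
    filter_weights: list[np.ndarray] | None = None,
    config: LossConfig | None = None,
) -> float:
    """Full training loss L = J + alpha * ||W||^2 (filters only)."""
    config = config or LossConfig()
    j = cross_entropy(probabilities, targets, config.prob_clip)
    reg = 0.0
    if filter_weights and config.weight_decay > 0:
        reg = config.weight_decay * float(sum((np.asarray(w, dtype=np.float64) ** 2).sum() for w in filter_weights))
    return j + reg


class Network:
    """Instantiated network: parameters plus forward/backward machinery.

    Parameters are created with seeded Glorot-uniform filters and zero
    biases.  ``forward`` in inference mode is deterministic (dropout off,
    batch norm uses running statistics).
    """

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator, dtype=np.float32):
        self.spec = spec
        self.dtype = dtype
        self.trunk: list[nn.Conv3D] = []
        self.trunk_act: list[nn.ELU] = []
        cin = spec.in_channels
        for _ in range(spec.depth):
            self.trunk.append(nn.Conv3D(cin, spec.width, 3, rng, dtype))
            self.trunk_act.append(nn.ELU())
            cin = spec.width
        self.bn = nn.BatchNorm(spec.dense_channels, dtype=dtype)
        self.head = [
            nn.Conv3D(spec.dense_channels, HEAD_WIDTHS[0], 1, rng, dtype),
            nn.Conv3D(HEAD_WIDTHS[0], HEAD_WIDTHS[1], 1, rng, dtype),
            nn.Conv3D(HEAD_WIDTHS[1], spec.n_classes, 1, rng, dtype),
        ]
        self.head_act = [nn.ELU(), nn.ELU()]
        self.head_drop = [nn.Dropout(DROPOUT_P), nn.Dropout(DROPOUT_P)]
        self._dense: nn.DenseConnection | None = None
        self._probs: np.ndarray | None = None

    # -- parameter access -------------------------------------------------
    def parameters(self) -> dict[str, np.ndarray]:
        params: dict[str, np.ndarray] = {}
        for i, conv in enumerate(self.trunk):
            params[f"trunk{i}.W"], params[f"trunk{i}.b"] = conv.W, conv.b
        params["bn.gamma"], params["bn.beta"] = self.bn.gamma, self.bn.beta
        for i, conv in enumerate(self.head):
            params[f"head{i}.W"], params[f"head{i}.b"] = conv.W, conv.b
        return params

    def gradients(self) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        for i, conv in enumerate(self.trunk):
            grads[f"trunk{i}.W"], grads[f"trunk{i}.b"] = conv.dW, conv.db
        grads["bn.gamma"], grads["bn.beta"] = self.bn.dgamma, self.bn.dbeta
        for i, conv in enumerate(self.head):
            grads[f"head{i}.W"], grads[f"head{i}.b"] = conv.dW, conv.db
        return grads

    def filter_weights(self) -> list[np.ndarray]:
        """Convolution filters subject to weight decay (no biases, no BN)."""
        return [c.W for c in self.trunk] + [c.W for c in self.head]

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: v.copy() for k, v in self.parameters().items()}
        state["bn.running_mean"] = self.bn.running_mean.copy()
        state["bn.running_var"] = self.bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        for k, v in params.items():
            v[...] = state[k]
        self.bn.running_mean[...] = state["bn.running_mean"]
        self.bn.running_var[...] = state["bn.running_var"]

    def n_parameters(self) -> int:
        return sum(v.size for v in self.parameters().values())

    # -- forward / backward ----------------------------------------------
    def forward(
        self,
        x: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Input (B, side, side, side, N) -> per-voxel class probabilities
        (B, out, out, out, C)."""
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim != 5 or x.shape[-1] != self.spec.in_channels:
            raise ValueError(
                f"expected input (B, s, s, s, {self.spec.in_channels} channels), got {x.shape}"
            )
        side = x.shape[1]
        out_side = self.spec.output_side(side)  # raises if too small

        feature_maps = []
        h = x
        for conv, act in zip(self.trunk, self.trunk_act):
            h = act.forward(conv.forward(h, training), training)
            feature_maps.append(h)

        dense = nn.DenseConnection(out_side)
        d = dense.forward(feature_maps, training)
        d = self.bn.forward(d, training)
        h = self.head_act[0].forward(self.head[0].forward(d, training), training)
        h = self.head_drop[0].forward(h, training, rng)
        h = self.head_act[1].forward(self.head[1].forward(h, training), training)
        h = self.head_drop[1].forward(h, training, rng)
        logits = self.head[2].forward(h, training)
        probs = softmax(logits, axis=-1)
        if training:
            self._dense = dense
            self._probs = probs
        return probs

    def backward(self, targets: np.ndarray) -> None:
        """Accumulate gradients of L = J + alpha*||W||^2 w.r.t. parameters.

        Must follow a training-mode forward on the same batch; the softmax
        and cross-entropy gradients are fused: dJ/dlogits = (p - t)/(B*V).
        """
        probs = self._probs
        if probs is None:
            raise RuntimeError("backward called before a training-mode forward")
        t = np.asarray(targets, dtype=probs.dtype)
        if t.shape != probs.shape:
            raise ValueError(f"target shape {t.shape} != output shape {probs.shape}")
        n = probs.size // probs.shape[-1]
        dlogits = (probs - t) / n

        g = self.head[2].backward(dlogits)
        g = self.head_drop[1].backward(g)
        g = self.head[1].backward(self.head_act[1].backward(g))
        g = self.head_drop[0].backward(g)
        g = self.head[0].backward(self.head_act[0].backward(g))
        g = self.bn.backward(g)
        crop_grads = self._dense.backward(g)

        upstream = None
        for conv, act, gcrop in zip(reversed(self.trunk), reversed(self.trunk_act), reversed(crop_grads)):
            total = gcrop if upstream is None else gcrop + upstream
            upstream = conv.backward(act.backward(total))
        self._dense = None
        self._probs = None

    def add_weight_decay_gradients(self, weight_decay: float) -> None:
        if weight_decay == 0:
            return
        for conv in self.trunk + self.head:
            conv.dW += 2.0 * weight_decay * conv.W

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Checkpoint weights (npz) with a JSON sidecar describing the spec."""
        path = Path(path)
        np.savez(path, **self.state_dict())
        sidecar = {
            "depth": self.spec.depth,
            "width": self.spec.width,
            "in_channels": self.spec.in_channels,
            "n_classes": self.spec.n_classes,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "Network":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        spec = build_network(
            sidecar["depth"], sidecar["width"], sidecar["in_channels"], sidecar["n_classes"]
        )
        net = cls(spec, np.random.default_rng(0))
        with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
            net.load_state_dict({k: data[k] for k in data.files})
        return net
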