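"""The small sequential CNN: declarative spec, parameter accounting, and a
NumPy compute backend (forward, backward, input gradients).

The architecture is fixed up to input size and output width: pairs of 3x3
valid-padding convolutions and 2x2 stride-2 max-pooling layers with filter
counts 4, 8, 8, 8, 16, 16, followed by flatten, a 32-unit rectified dense
layer and a softmax output.  For a 257x257 RGB input and two classes this
network has exactly 7210 trainable parameters (7342 with six classes): the
valid/floor shape recurrence 257 -> 255 -> 127 -> 125 -> 62 -> 60 -> 30 ->
28 -> 14 -> 12 -> 6 -> 4 -> 2 leaves a 2x2x16 map, i.e. a 64-wide flatten.
This padding/pooling/width combination is the unique standard choice that
reproduces both printed totals; 'same' padding would give 13354.

The backend is deliberately plain NumPy: at ~7k parameters a GPU framework
buys nothing, and an explicit backward pass is what the relevance-propagation
module needs anyway.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "LayerSpec",
    "NetworkSpec",
    "TrainedModel",
    "ShapeError",
    "FILTER_SCHEDULE",
    "HIDDEN_WIDTH",
    "build_network",
    "count_parameters",
    "spatial_trace",
    "flatten_width",
    "min_input_size",
    "SequentialCNN",
    "init_model",
    "penultimate_activations",
    "save_model",
    "load_model",
    "describe",
]

#: Convolution filter counts of the six conv/pool stages.
FILTER_SCHEDULE = (4, 8, 8, 8, 16, 16)
#: Width of the penultimate dense layer (the embedded feature space).
HIDDEN_WIDTH = 32
KERNEL = 3


class ShapeError(ValueError):
    """A layer's spatial output would underflow (or shapes mismatch)."""


@dataclass(frozen=True)
class LayerSpec:
    """One layer of the sequential network.

    kind is one of ``conv`` (3x3, valid padding), ``pool`` (2x2, stride 2,
    floor), ``flatten``, ``dense``.  ``units`` is the filter count for conv
    and the output width for dense; activation is ``relu``, ``softmax`` or
    ``none``.
    """

    kind: str
    units: int = 0
    activation: str = "none"
    kernel_size: int = KERNEL
    padding: str = "valid"

    def __post_init__(self) -> None:
        if self.kind not in ("conv", "pool", "flatten", "dense"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind == "conv" and self.kernel_size != KERNEL:
            raise ValueError("all convolutions use a 3x3 kernel")
        if self.kind == "conv" and self.padding != "valid":
            raise ValueError("convolutions are valid-padding")


@dataclass(frozen=True)
class NetworkSpec:
    """Declarative description of the full network for one input shape."""

    input_height: int
    input_width: int
    input_channels: int
    n_classes: int
    layers: tuple[LayerSpec, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "input_height": self.input_height,
            "input_width": self.input_width,
            "input_channels": self.input_channels,
            "n_classes": self.n_classes,
            "layers": [vars(l) | {} for l in self.layers],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        layers = tuple(LayerSpec(**l) for l in d["layers"])
        return cls(
            input_height=d["input_height"],
            input_width=d["input_width"],
            input_channels=d["input_channels"],
            n_classes=d["n_classes"],
            layers=layers,
        )


def build_network(
    height: int,
    width: int,
    channels: int = 3,
    n_classes: int = 2,
    *,
    n_stages: int = 6,
) -> NetworkSpec:
    """Build the fixed architecture for a given input shape and class count.

    ``n_stages`` (default 6, the reference architecture) selects how many
    conv/pool pairs to use; fewer stages (with the same filter-count prefix)
    accommodate small test images that the full stack would shrink below one
    pixel.  Raises :class:`ShapeError` naming the first underflowing layer if
    the input is too small for the requested depth.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if not (1 <= n_stages <= len(FILTER_SCHEDULE)):
        raise ValueError(f"n_stages must be in [1, {len(FILTER_SCHEDULE)}]")
    layers: list[LayerSpec] = []
    for f in FILTER_SCHEDULE[:n_stages]:
        layers.append(LayerSpec(kind="conv", units=f, activation="relu"))
        layers.append(LayerSpec(kind="pool"))
    layers.append(LayerSpec(kind="flatten"))
    layers.append(LayerSpec(kind="dense", units=HIDDEN_WIDTH, activation="relu"))
    layers.append(LayerSpec(kind="dense", units=n_classes, activation="softmax"))
    spec = NetworkSpec(
        input_height=height,
        input_width=width,
        input_channels=channels,
        n_classes=n_classes,
        layers=tuple(layers),
    )
    spatial_trace(spec)  # validates: raises ShapeError on underflow
    return spec


def spatial_trace(spec: NetworkSpec) -> list[tuple[int, int]]:
    """(height, width) after every conv/pool layer, in layer order.

    Valid 3x3 convolution subtracts 2 from each spatial dimension; 2x2
    stride-2 pooling halves with floor.  Raises :class:`ShapeError` naming
    the first layer whose output would drop below 1 pixel.
    """
    h, w = spec.input_height, spec.input_width
    trace: list[tuple[int, int]] = []
    for i, layer in enumerate(spec.layers):
        if layer.kind == "conv":
            h2, w2 = h - 2, w - 2
        elif layer.kind == "pool":
            h2, w2 = h // 2, w // 2
        else:
            break
        if h2 < 1 or w2 < 1:
            raise ShapeError(
                f"layer {i} ({layer.kind}) underflows: spatial size "
                f"{h}x{w} -> {h2}x{w2}; input too small for this depth"
            )
        h, w = h2, w2
        trace.append((h, w))
    return trace


def flatten_width(spec: NetworkSpec) -> int:
    """Length of the flattened feature vector entering the dense layers."""
    trace = spatial_trace(spec)
    h, w = trace[-1] if trace else (spec.input_height, spec.input_width)
    channels = spec.input_channels
    for layer in spec.layers:
        if layer.kind == "conv":
            channels = layer.units
    return h * w * channels


def min_input_size(n_stages: int = 6) -> int:
    """Smallest square input the given depth supports (190 for six stages)."""
    s = 1
    for _ in range(n_stages):
        s = 2 * s + 2  # invert pool (ceil) then conv
    return s


def count_parameters(spec: NetworkSpec) -> int:
    """Total trainable parameters.

    Convolutions contribute k*k*c_in*c_out + c_out, dense layers
    n_in*n_out + n_out; pooling and flatten are parameter-free.
    """
    total = 0
    channels = spec.input_channels
    n_in = None  # set at flatten
    for layer in spec.layers:
        if layer.kind == "conv":
            total += layer.kernel_size**2 * channels * layer.units + layer.units
            channels = layer.units
        elif layer.kind == "flatten":
            n_in = flatten_width(spec)
        elif layer.kind == "dense":
            if n_in is None:
                raise ValueError("dense layer before flatten")
            total += n_in * layer.units + layer.units
            n_in = layer.units
    return total


def describe(spec: NetworkSpec) -> str:
    """Human-readable layer table (shape trace and per-layer parameters)."""
    lines = [
        f"Input: {spec.input_height}x{spec.input_width}x{spec.input_channels}",
        f"{'layer':<12}{'output':<16}{'params':>8}",
    ]
    h, w = spec.input_height, spec.input_width
    channels = spec.input_channels
    n_in = None
    total = 0
    for layer in spec.layers:
        if layer.kind == "conv":
            h, w = h - 2, w - 2
            p = 9 * channels * layer.units + layer.units
            channels = layer.units
            out = f"{h}x{w}x{channels}"
        elif layer.kind == "pool":
            h, w = h // 2, w // 2
            p = 0
            out = f"{h}x{w}x{channels}"
        elif layer.kind == "flatten":
            n_in = h * w * channels
            p = 0
            out = f"{n_in}"
        else:
            p = n_in * layer.units + layer.units  # type: ignore[operator]
            n_in = layer.units
            out = f"{layer.units} ({layer.activation})"
        total += p
        lines.append(f"{layer.kind:<12}{out:<16}{p:>8}")
    lines.append(f"{'total':<28}{total:>8}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# NumPy compute backend
# ---------------------------------------------------------------------------


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    # x: (N, H, W, Cin); W: (3, 3, Cin, Cout)
    n, h, w, _ = x.shape
    ho, wo = h - 2, w - 2
    z = np.broadcast_to(b, (n, ho, wo, b.shape[0])).copy()
    for i in range(3):
        for j in range(3):
            z += np.tensordot(x[:, i : i + ho, j : j + wo, :], W[i, j], axes=([3], [0]))
    return z


def _conv_backward(
    x: np.ndarray, W: np.ndarray, dz: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n, h, w, _ = x.shape
    ho, wo = dz.shape[1], dz.shape[2]
    dW = np.zeros_like(W)
    dx = np.zeros_like(x)
    for i in range(3):
        for j in range(3):
            patch = x[:, i : i + ho, j : j + wo, :]
            dW[i, j] = np.tensordot(patch, dz, axes=([0, 1, 2], [0, 1, 2]))
            dx[:, i : i + ho, j : j + wo, :] += np.tensordot(dz, W[i, j], axes=([3], [1]))
    db = dz.sum(axis=(0, 1, 2))
    return dW, db, dx


def _pool_forward(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n, h, w, c = x.shape
    ho, wo = h // 2, w // 2
    windows = (
        x[:, : 2 * ho, : 2 * wo, :]
        .reshape(n, ho, 2, wo, 2, c)
        .transpose(0, 1, 3, 5, 2, 4)
        .reshape(n, ho, wo, c, 4)
    )
    idx = windows.argmax(axis=-1)
    out = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _pool_backward(dz: np.ndarray, idx: np.ndarray, in_shape: tuple) -> np.ndarray:
    n, h, w, c = in_shape
    ho, wo = dz.shape[1], dz.shape[2]
    flat = np.zeros((n, ho, wo, c, 4), dtype=dz.dtype)
    np.put_along_axis(flat, idx[..., None], dz[..., None], axis=-1)
    dx = np.zeros(in_shape, dtype=dz.dtype)
    dx[:, : 2 * ho, : 2 * wo, :] = (
        flat.reshape(n, ho, wo, c, 2, 2).transpose(0, 1, 4, 2, 5, 3).reshape(n, 2 * ho, 2 * wo, c)
    )
    return dx


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class SequentialCNN:
    """Weights plus forward/backward passes for a :class:`NetworkSpec`.

    Weights are initialized from a uniform fan-in-scaled distribution
    U(-sqrt(1/fan_in), +sqrt(1/fan_in)); biases start at zero.  All math is
    float64 for exact reproducibility and clean gradient checks.
    """

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.weights: list[dict | None] = []
        channels = spec.input_channels
        n_in = None
        for layer in spec.layers:
            if layer.kind == "conv":
                fan_in = 9 * channels
                lim = np.sqrt(1.0 / fan_in)
                self.weights.append(
                    {
                        "W": rng.uniform(-lim, lim, size=(3, 3, channels, layer.units)),
                        "b": np.zeros(layer.units),
                    }
                )
                channels = layer.units
            elif layer.kind == "dense":
                if n_in is None:
                    n_in = flatten_width(spec)
                lim = np.sqrt(1.0 / n_in)
                self.weights.append(
                    {
                        "W": rng.uniform(-lim, lim, size=(n_in, layer.units)),
                        "b": np.zeros(layer.units),
                    }
                )
                n_in = layer.units
            else:
                self.weights.append(None)

    # -- weight bookkeeping -------------------------------------------------

    def get_weights(self) -> list[dict | None]:
        return copy.deepcopy(self.weights)

    def set_weights(self, weights: list[dict | None]) -> None:
        self.weights = copy.deepcopy(weights)

    def n_parameters(self) -> int:
        return sum(
            w["W"].size + w["b"].size for w in self.weights if w is not None
        )

    # -- forward ------------------------------------------------------------

    def forward(self, x: np.ndarray, want_caches: bool = False):
        """Return pre-softmax logits (N, n_classes); optionally layer caches.

        Each cache records the layer's input ``x`` (post-activation of the
        previous layer) and, for parameterized layers, the pre-activation
        ``z`` — exactly what backprop and relevance propagation need.
        """
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 3:
            x = x[None]
        expected = (self.spec.input_height, self.spec.input_width, self.spec.input_channels)
        if x.shape[1:] != expected:
            raise ShapeError(f"input shape {x.shape[1:]} != model input {expected}")
        caches: list[dict] = []
        a = x
        for layer, w in zip(self.spec.layers, self.weights):
            if layer.kind == "conv":
                z = _conv_forward(a, w["W"], w["b"])
                out = np.maximum(z, 0.0) if layer.activation == "relu" else z
                caches.append({"kind": "conv", "x": a, "z": z, "layer": layer})
                a = out
            elif layer.kind == "pool":
                out, idx = _pool_forward(a)
                caches.append({"kind": "pool", "x_shape": a.shape, "idx": idx, "x": a, "layer": layer})
                a = out
            elif layer.kind == "flatten":
                caches.append({"kind": "flatten", "x_shape": a.shape, "layer": layer})
                a = a.reshape(a.shape[0], -1)
            else:  # dense
                z = a @ w["W"] + w["b"]
                if layer.activation == "relu":
                    out = np.maximum(z, 0.0)
                else:  # softmax output or linear: logits returned raw
                    out = z
                caches.append({"kind": "dense", "x": a, "z": z, "layer": layer})
                a = out
        return (a, caches) if want_caches else a

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x))

    def penultimate(self, x: np.ndarray) -> np.ndarray:
        """Post-activation values of the hidden dense layer, (N, 32)."""
        _, caches = self.forward(x, want_caches=True)
        cache = caches[-2]
        assert cache["layer"].kind == "dense"
        z = cache["z"]
        return np.maximum(z, 0.0) if cache["layer"].activation == "relu" else z

    # -- backward -----------------------------------------------------------

    def backward(self, caches: list[dict], dlogits: np.ndarray):
        """Backprop ``dlogits`` (gradient at the pre-softmax output) through
        the network; returns (per-layer weight gradients, input gradient)."""
        grads: list[dict | None] = [None] * len(self.weights)
        da = dlogits
        for li in range(len(self.spec.layers) - 1, -1, -1):
            cache = caches[li]
            layer: LayerSpec = cache["layer"]
            w = self.weights[li]
            if layer.kind == "dense":
                dz = da
                if layer.activation == "relu":
                    dz = da * (cache["z"] > 0)
                grads[li] = {"W": cache["x"].T @ dz, "b": dz.sum(axis=0)}
                da = dz @ w["W"].T
            elif layer.kind == "flatten":
                da = da.reshape(cache["x_shape"])
            elif layer.kind == "pool":
                da = _pool_backward(da, cache["idx"], cache["x_shape"])
            else:  # conv
                dz = da
                if layer.activation == "relu":
                    dz = da * (cache["z"] > 0)
                dW, db, da = _conv_backward(cache["x"], w["W"], dz)
                grads[li] = {"W": dW, "b": db}
        return grads, da

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        """Mean cross-entropy and its weight gradients for integer labels."""
        logits, caches = self.forward(x, want_caches=True)
        p = softmax(logits)
        n = x.shape[0]
        eps = 1e-12
        loss = -np.log(p[np.arange(n), y] + eps).mean()
        dlogits = p.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        grads, _ = self.backward(caches, dlogits)
        return loss, grads

    def loss(self, x: np.ndarray, y: np.ndarray, batch: int = 64) -> float:
        """Mean cross-entropy without gradients (evaluation)."""
        total, n = 0.0, x.shape[0]
        for s in range(0, n, batch):
            logits = self.forward(x[s : s + batch])
            p = softmax(logits)
            yy = y[s : s + batch]
            total += -np.log(p[np.arange(len(yy)), yy] + 1e-12).sum()
        return total / n

    def input_gradient(self, x: np.ndarray, target_class: int) -> np.ndarray:
        """Gradient of the target class's pre-softmax score w.r.t. the input."""
        logits, caches = self.forward(x, want_caches=True)
        if not (0 <= target_class < logits.shape[1]):
            raise ValueError(f"invalid class index {target_class}")
        dlogits = np.zeros_like(logits)
        dlogits[:, target_class] = 1.0
        _, dx = self.backward(caches, dlogits)
        return dx


@dataclass
class TrainedModel:
    """A network together with its training history.

    ``history`` maps 'train_loss'/'val_loss' to equal-length per-epoch lists;
    ``best_epoch`` indexes the epoch whose weights the network carries
    (earliest epoch wins ties on the validation loss).
    """

    spec: NetworkSpec
    network: SequentialCNN
    history: dict = field(default_factory=lambda: {"train_loss": [], "val_loss": []})
    best_epoch: int = -1

    @property
    def epochs_trained(self) -> int:
        return len(self.history["train_loss"])


def init_model(spec: NetworkSpec, seed: int) -> TrainedModel:
    """Fresh, untrained model with seeded fan-in-scaled uniform weights."""
    return TrainedModel(spec=spec, network=SequentialCNN(spec, seed=seed))


def penultimate_activations(model: TrainedModel, samples) -> np.ndarray:
    """(n, 32) matrix of hidden-layer activations for a list of samples."""
    x = np.stack([s.pixels for s in samples])
    return model.network.penultimate(x)


def save_model(model: TrainedModel, path_prefix: str | Path) -> None:
    """Write ``<prefix>.npz`` (weights) and ``<prefix>.json`` (spec+history)."""
    path_prefix = Path(path_prefix)
    arrays = {}
    for i, w in enumerate(model.network.weights):
        if w is not None:
            arrays[f"W{i}"] = w["W"]
            arrays[f"b{i}"] = w["b"]
    np.savez(path_prefix.with_suffix(".npz"), **arrays)
    meta = {
        "spec": model.spec.to_dict(),
        "history": model.history,
        "best_epoch": model.best_epoch,
    }
    path_prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_model(path_prefix: str | Path) -> TrainedModel:
    path_prefix = Path(path_prefix)
    meta = json.loads(path_prefix.with_suffix(".json").read_text())
    spec = NetworkSpec.from_dict(meta["spec"])
    net = SequentialCNN(spec, seed=0)
    with np.load(path_prefix.with_suffix(".npz")) as data:
        for i, w in enumerate(net.weights):
            if w is not None:
                w["W"] = data[f"W{i}"]
                w["b"] = data[f"b{i}"]
    return TrainedModel(
        spec=spec, network=net, history=meta["history"], best_epoch=meta["best_epoch"]
    )
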