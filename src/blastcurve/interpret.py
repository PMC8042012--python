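"""Model introspection: gradient saliency maps, layer-wise relevance
propagation (LRP), and 2-D embedding of the penultimate layer with a
cluster-separation score.

Saliency is the per-pixel magnitude of the gradient of the target class's
pre-softmax score with respect to the input (reduced over color channels by
max of absolute values).  LRP decomposes the same pre-softmax score into
signed per-pixel relevances by propagating it backward through the network
with the stabilized epsilon rule: at a linear layer with input x, weights W
and pre-activations z, relevance flows as

    R_j = x_j * sum_k  W_jk * R_k / (z_k + eps * sign(z_k)),

max-pooling routes relevance to the winning input, and channel relevances
are summed at the input.  With zero biases the total relevance is conserved
at every layer boundary up to epsilon leakage.  The penultimate 32-d
activations are embedded with t-SNE and class separation is quantified by
the mean silhouette coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

from .datasets import ImageSample
from .network import ShapeError, TrainedModel, _conv_backward, _pool_backward

__all__ = [
    "RelevanceMap",
    "Embedding2D",
    "saliency_map",
    "lrp_map",
    "embed_penultimate",
    "separation_score",
]


@dataclass
class RelevanceMap:
    """Per-pixel attribution for one sample and one output class.

    ``values`` is signed for LRP and non-negative for saliency; its shape
    equals the input's spatial shape.
    """

    values: np.ndarray
    target_class: int
    method: str
    explained_score: float = float("nan")  # the pre-softmax logit decomposed

    def __post_init__(self) -> None:
        if self.method == "saliency" and (self.values < 0).any():
            raise ValueError("saliency maps must be non-negative")


def saliency_map(
    model: TrainedModel,
    sample: ImageSample,
    target_class: int,
    *,
    channel_reduction: str = "max_abs",
) -> RelevanceMap:
    """Gradient saliency for one sample and class.

    The per-pixel value is the maximum over RGB channels of the absolute
    gradient of the target pre-softmax score (``channel_reduction='sum_abs'``
    sums instead).
    """
    net = model.network
    x = sample.pixels[None]
    grad = net.input_gradient(x, target_class)[0]  # validates target_class
    if channel_reduction == "max_abs":
        values = np.abs(grad).max(axis=-1)
    elif channel_reduction == "sum_abs":
        values = np.abs(grad).sum(axis=-1)
    else:
        raise ValueError(f"unknown channel_reduction {channel_reduction!r}")
    logit = float(net.forward(x)[0, target_class])
    return RelevanceMap(
        values=values, target_class=target_class, method="saliency", explained_score=logit
    )


def _stabilize(z: np.ndarray, eps: float) -> np.ndarray:
    sign = np.where(z >= 0, 1.0, -1.0)
    return z + eps * sign


def lrp_map(
    model: TrainedModel,
    sample: ImageSample,
    target_class: int,
    *,
    epsilon: float = 1e-6,
    rule: str = "epsilon",
) -> RelevanceMap:
    """Layer-wise relevance propagation of the target pre-softmax score.

    ``rule='epsilon'`` (default) uses the stabilized rule at every conv and
    dense layer; ``rule='alpha_beta'`` (alpha=1, beta=0) propagates through
    positive weight contributions only.  Bias neurons absorb their share of
    relevance (it is not redistributed), so exact conservation holds for
    zero-bias networks.
    """
    if rule not in ("epsilon", "alpha_beta"):
        raise ValueError(f"unknown LRP rule {rule!r}")
    net = model.network
    x = sample.pixels[None]
    logits, caches = net.forward(x, want_caches=True)
    if not (0 <= target_class < logits.shape[1]):
        raise ValueError(f"invalid class index {target_class}")

    R = np.zeros_like(logits)
    R[0, target_class] = logits[0, target_class]

    for idx in range(len(caches) - 1, -1, -1):
        cache = caches[idx]
        kind = cache["kind"]
        if kind == "dense":
            w = net.weights[idx]
            a, z = cache["x"], cache["z"]
            if rule == "epsilon":
                s = R / _stabilize(z, epsilon)
                R = a * (s @ w["W"].T)
            else:
                Wp = np.maximum(w["W"], 0.0)
                zp = a @ Wp
                s = R / _stabilize(zp, epsilon)
                R = a * (s @ Wp.T)
        elif kind == "flatten":
            R = R.reshape(cache["x_shape"])
        elif kind == "pool":
            R = _pool_backward(R, cache["idx"], cache["x_shape"])
        else:  # conv
            w = net.weights[idx]
            a, z = cache["x"], cache["z"]
            if rule == "epsilon":
                s = R / _stabilize(z, epsilon)
                _, _, c = _conv_backward(a, w["W"], s)
            else:
                Wp = np.maximum(w["W"], 0.0)
                from .network import _conv_forward

                zp = _conv_forward(a, Wp, np.zeros(Wp.shape[-1]))
                s = R / _stabilize(zp, epsilon)
                _, _, c = _conv_backward(a, Wp, s)
            R = a * c
    values = R[0].sum(axis=-1)  # sum relevance over RGB at the input
    return RelevanceMap(
        values=values,
        target_class=target_class,
        method="lrp",
        explained_score=float(logits[0, target_class]),
    )


@dataclass
class Embedding2D:
    """Seeded 2-D embedding of per-sample feature vectors."""

    coords: np.ndarray
    labels: list
    perplexity: float
    seed: int
    degenerate: bool = False

    def to_csv(self, path, sample_ids=None) -> None:
        import pandas as pd

        ids = sample_ids if sample_ids is not None else list(range(len(self.labels)))
        pd.DataFrame(
            {
                "sample_id": ids,
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "label": self.labels,
            }
        ).to_csv(path, index=False)


def embed_penultimate(
    activations: np.ndarray,
    labels,
    *,
    perplexity: float = 30.0,
    seed: int = 0,
) -> Embedding2D:
    """t-SNE of penultimate-layer activations to 2-D (deterministic per seed).

    Degenerate input (all rows identical, e.g. a dead rectifier layer) is
    flagged and embedded as zeros rather than passed to the solver.
    """
    activations = np.asarray(activations, dtype=float)
    n = activations.shape[0]
    if n < 5:
        raise ValueError(f"need at least 5 samples to embed, got {n}")
    if perplexity >= n:
        raise ValueError(f"perplexity {perplexity} must be < n = {n}")
    labels = list(labels)
    if len(labels) != n:
        raise ValueError("labels length does not match activations")
    if np.allclose(activations, activations[0]):
        return Embedding2D(
            coords=np.zeros((n, 2)), labels=labels, perplexity=perplexity, seed=seed,
            degenerate=True,
        )
    tsne = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca",
    )
    coords = tsne.fit_transform(activations)
    return Embedding2D(coords=coords, labels=labels, perplexity=perplexity, seed=seed)


def separation_score(coords_or_activations: np.ndarray, labels) -> float:
    """Mean silhouette coefficient (Euclidean) of the class labeling.

    Near 1 for well-separated compact classes, near 0 (or below) when the
    classes overlap.  Requires at least two classes with two samples each.
    """
    X = np.asarray(coords_or_activations, dtype=float)
    labels = np.asarray(list(labels))
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("separation score needs at least two classes")
    if (counts < 2).any():
        small = classes[counts < 2].tolist()
        raise ValueError(f"classes with fewer than 2 samples: {small}")
    return float(silhouette_score(X, labels, metric="euclidean"))
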