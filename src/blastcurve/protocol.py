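"""Nested incremental cross-validation protocol for learning-curve analysis.

The design: every sample sits in the test set of exactly one of ``n_folds``
folds; within a fold a fixed validation set is drawn once and the remaining
pool is permuted into strictly nested training subsets (size_start,
size_start + size_step, ..., size_max, each containing the previous).  For
every fold and subset size a fresh network is initialized and trained with
on-the-fly augmentation (random flips and a uniform 0-359 degree rotation)
and validation-loss early stopping, then scored on the fold's fixed test
set.  The result is a table of (fold, train_size, metric) records — the
learning curve.

The experiment is organised statsmodels-style: a
:class:`LearningCurveExperiment` is built from a dataset plus a
:class:`ProtocolConfig`; its :meth:`~LearningCurveExperiment.fit` returns a
:class:`LearningCurveResults` carrying the records, per-size box summaries,
a text ``summary()`` and plotting hooks.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import rotate as _sk_rotate

from .datasets import ImageSample, LabeledDataset
from .metrics import RocCurve, f1_macro, roc_auc, roc_curve, summarize_box
from .network import (
    NetworkSpec,
    SequentialCNN,
    TrainedModel,
    build_network,
    min_input_size,
)

__all__ = [
    "ProtocolConfig",
    "FoldAssignment",
    "FoldPlan",
    "plan_folds",
    "apply_augmentation",
    "augment_image",
    "balance_by_augmentation",
    "early_stop_epoch",
    "train_model",
    "LearningCurveExperiment",
    "LearningCurveResults",
    "run_learning_curve",
]


class ProtocolError(ValueError):
    """Invalid protocol configuration or insufficient data for it."""


@dataclass
class ProtocolConfig:
    """All protocol constants in one place.

    Defaults reproduce the 250-image reference design: ten folds with
    disjoint 10% test sets, 25 fixed validation images per fold, nested
    training subsets growing from 10 to 200 in steps of 10, early stopping
    with patience 50, and per-class balancing to 150 images in the
    multiclass task.  Optimizer settings (Adam, lr 1e-3, batch 16,
    max_epochs 500) are not dictated by the reference analysis and are
    exposed here.
    """

    n_folds: int = 10
    test_fraction: float = 0.10
    test_size: int | None = None  # explicit per-fold test size (e.g. 600)
    val_size: int = 25
    size_start: int = 10
    size_step: int = 10
    size_max: int = 200
    sizes: list[int] | None = None  # explicit subset sizes; overrides start/step/max
    patience: int = 50
    max_epochs: int = 500
    learning_rate: float = 1e-3
    batch_size: int = 16
    metric: str = "roc_auc"  # or "f1_macro"
    positive_class: str | None = None  # binary mode; default: first class
    target_per_class: int | None = None  # multiclass balancing (150)
    augment: bool = True
    augment_mode: str = "online"  # or "append"
    stratified_test: bool = False  # balanced test sets (large-dataset mode)
    n_stages: int | None = None  # None: deepest depth the image size allows (<= 6)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ProtocolError("patience must be >= 1")
        if self.sizes is None and self.size_start > self.size_max:
            raise ProtocolError("size_start must be <= size_max")
        if self.metric not in ("roc_auc", "f1_macro"):
            raise ProtocolError(f"unknown metric {self.metric!r}")
        if self.augment_mode not in ("online", "append"):
            raise ProtocolError(f"unknown augment_mode {self.augment_mode!r}")

    @property
    def subset_sizes(self) -> list[int]:
        if self.sizes is not None:
            return sorted(self.sizes)
        return list(range(self.size_start, self.size_max + 1, self.size_step))


@dataclass
class FoldAssignment:
    """One fold's disjoint test/val/pool split plus its nested subsets."""

    test_ids: list[str]
    val_ids: list[str]
    pool_ids: list[str]
    nested_subsets: list[list[str]]


@dataclass
class FoldPlan:
    """The full cross-validation design; validates its own invariants."""

    folds: list[FoldAssignment]
    all_ids: list[str]
    covers_all: bool = True  # False in fixed-test-size (large dataset) mode

    def validate(self) -> None:
        seen: set[str] = set()
        for k, f in enumerate(self.folds):
            test, val, pool = set(f.test_ids), set(f.val_ids), set(f.pool_ids)
            if test & val or test & pool or val & pool:
                raise ProtocolError(f"fold {k}: test/val/pool overlap")
            if test & seen:
                raise ProtocolError(f"fold {k}: test set overlaps a previous fold's")
            seen |= test
            prev: set[str] = set()
            for sub in f.nested_subsets:
                cur = set(sub)
                if not prev <= cur:
                    raise ProtocolError(f"fold {k}: subsets are not nested")
                if not cur <= pool:
                    raise ProtocolError(f"fold {k}: subset leaks outside the pool")
                prev = cur
        if self.covers_all and seen != set(self.all_ids):
            raise ProtocolError("test sets do not cover every sample exactly once")


def plan_folds(
    sample_ids: list[str],
    config: ProtocolConfig,
    rng: np.random.Generator,
    labels: dict[str, str] | None = None,
) -> FoldPlan:
    """Draw the nested cross-validation design.

    Default mode partitions all ids into ``n_folds`` disjoint test sets
    (uniform random, near-equal sizes) covering every id exactly once.  With
    ``stratified_test`` and an explicit ``test_size``, each fold's test set
    is instead class-balanced with ``test_size`` unique images, disjoint
    across folds on the test side only (the large-dataset variant).
    """
    ids = list(sample_ids)
    n = len(ids)
    if len(set(ids)) != n:
        raise ProtocolError("sample ids must be unique")
    sizes = config.subset_sizes

    if config.stratified_test:
        if config.test_size is None or labels is None:
            raise ProtocolError("stratified_test requires test_size and labels")
        classes = sorted(set(labels.values()))
        per_class = config.test_size // len(classes)
        if per_class * len(classes) != config.test_size:
            raise ProtocolError("test_size must divide evenly among classes")
        by_class = {c: [i for i in ids if labels[i] == c] for c in classes}
        for c, members in by_class.items():
            if len(members) < per_class * config.n_folds:
                raise ProtocolError(
                    f"class {c!r} has {len(members)} images; needs "
                    f"{per_class * config.n_folds} for disjoint balanced test sets"
                )
        chunks: list[list[str]] = [[] for _ in range(config.n_folds)]
        for c in classes:
            perm = list(rng.permutation(by_class[c]))
            for k in range(config.n_folds):
                chunks[k].extend(perm[k * per_class : (k + 1) * per_class])
        covers_all = False
    else:
        perm = list(rng.permutation(ids))
        if config.test_size is not None:
            # fixed test size: disjoint across folds, full coverage only if
            # the sizes happen to tile the dataset
            if config.test_size * config.n_folds > n:
                raise ProtocolError(
                    f"{n} samples cannot provide {config.n_folds} disjoint "
                    f"test sets of {config.test_size}"
                )
            chunks = [
                perm[k * config.test_size : (k + 1) * config.test_size]
                for k in range(config.n_folds)
            ]
            covers_all = config.test_size * config.n_folds == n
        else:
            # partition mode: every sample tests in exactly one fold
            if n < config.n_folds:
                raise ProtocolError(f"{n} samples cannot fill {config.n_folds} folds")
            chunks = [
                list(c)
                for c in np.array_split(np.asarray(perm, dtype=object), config.n_folds)
            ]
            covers_all = True

    folds = []
    for k in range(config.n_folds):
        test = [str(i) for i in chunks[k]]
        rest = [i for i in ids if i not in set(test)]
        if len(rest) < config.val_size + sizes[-1]:
            raise ProtocolError(
                f"fold {k}: {len(rest)} non-test samples cannot supply "
                f"{config.val_size} validation images plus a pool of {sizes[-1]}"
            )
        val = [str(i) for i in rng.choice(rest, size=config.val_size, replace=False)]
        pool = [i for i in rest if i not in set(val)]
        pool = [str(i) for i in rng.permutation(pool)]
        nested = [pool[:s] for s in sizes]
        folds.append(
            FoldAssignment(test_ids=test, val_ids=val, pool_ids=pool, nested_subsets=nested)
        )
    plan = FoldPlan(folds=folds, all_ids=ids, covers_all=covers_all)
    plan.validate()
    return plan


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------


def apply_augmentation(
    sample: ImageSample,
    *,
    flip_h: bool = False,
    flip_v: bool = False,
    angle_deg: float = 0.0,
    fill: tuple[float, float, float] | None = None,
) -> ImageSample:
    """Deterministically apply flips then a rotation (bilinear, constant fill).

    ``fill`` defaults to the mean border color of the image (a stand-in for
    the configured background).  Values are clipped to [0, 1]; the label and
    id are preserved.
    """
    img = sample.pixels
    if flip_h:
        img = img[:, ::-1, :]
    if flip_v:
        img = img[::-1, :, :]
    if angle_deg % 360.0 != 0.0:
        if fill is None:
            border = np.concatenate([img[0], img[-1], img[:, 0], img[:, -1]])
            fill = tuple(border.mean(axis=0))
        bg = np.asarray(fill)
        img = _sk_rotate(img - bg, angle_deg, order=1, mode="constant", cval=0.0) + bg
        img = np.clip(img, 0.0, 1.0)
    else:
        img = img.copy()
    return ImageSample(pixels=img, label=sample.label, sample_id=sample.sample_id)


def augment_image(
    sample: ImageSample,
    rng: np.random.Generator,
    fill: tuple[float, float, float] | None = None,
) -> ImageSample:
    """Random augmentation: independent horizontal/vertical flips (prob 0.5
    each) and a rotation angle drawn uniformly from [0, 359) degrees."""
    return apply_augmentation(
        sample,
        flip_h=bool(rng.random() < 0.5),
        flip_v=bool(rng.random() < 0.5),
        angle_deg=float(rng.uniform(0.0, 359.0)),
        fill=fill,
    )


def balance_by_augmentation(
    train_set: LabeledDataset, target: int, rng: np.random.Generator
) -> LabeledDataset:
    """Bring every class to exactly ``target`` images.

    Classes below target keep all originals and add augmented copies of
    randomly chosen originals (ids suffixed ``_augNNN`` so provenance stays
    traceable); classes above target are randomly subsampled.
    """
    out: list[ImageSample] = []
    for cls in train_set.class_order:
        members = [s for s in train_set.samples if s.label == cls]
        if not members:
            raise ProtocolError(f"class {cls!r} has no images; cannot balance")
        if len(members) >= target:
            chosen = rng.choice(len(members), size=target, replace=False)
            out.extend(members[i] for i in sorted(chosen))
        else:
            out.extend(members)
            n_extra = target - len(members)
            picks = rng.integers(0, len(members), size=n_extra)
            for j, p in enumerate(picks):
                src = members[int(p)]
                aug = augment_image(src, rng)
                aug.sample_id = f"{src.sample_id}_aug{j:03d}"
                out.append(aug)
    return LabeledDataset(out, class_order=train_set.class_order)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def early_stop_epoch(val_losses, patience: int) -> tuple[int, int]:
    """Walk the early-stopping rule over a validation-loss sequence.

    Returns ``(best_epoch, n_epochs_trained)`` (0-based best epoch).  The
    best epoch is the earliest strict minimum; training stops after the
    first epoch lying ``patience`` epochs past the best one, or at the end
    of the sequence.
    """
    best = np.inf
    best_epoch = 0
    for e, loss in enumerate(val_losses):
        if loss < best:
            best, best_epoch = loss, e
        elif e - best_epoch >= patience:
            return best_epoch, e + 1
    return best_epoch, len(list(val_losses))


class _Adam:
    """Standard Adam (beta1 0.9, beta2 0.999, eps 1e-8)."""

    def __init__(self, weights: list[dict | None], lr: float):
        self.lr = lr
        self.t = 0
        self.m = [None if w is None else {k: np.zeros_like(v) for k, v in w.items()} for w in weights]
        self.v = [None if w is None else {k: np.zeros_like(v) for k, v in w.items()} for w in weights]

    def step(self, weights: list[dict | None], grads: list[dict | None]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        corr1 = 1 - b1**self.t
        corr2 = 1 - b2**self.t
        for w, g, m, v in zip(weights, grads, self.m, self.v):
            if w is None or g is None:
                continue
            for k in w:
                m[k] = b1 * m[k] + (1 - b1) * g[k]
                v[k] = b2 * v[k] + (1 - b2) * g[k] ** 2
                w[k] -= self.lr * (m[k] / corr1) / (np.sqrt(v[k] / corr2) + eps)


def _epoch_arrays(
    train_set: LabeledDataset,
    lut: dict[str, int],
    config: ProtocolConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Materialize one epoch's training arrays, applying augmentation."""
    samples = list(train_set.samples)
    if config.augment:
        if config.augment_mode == "online":
            samples = [augment_image(s, rng) for s in samples]
        else:  # append a random number of augmented copies
            k = int(rng.integers(0, len(samples) + 1))
            picks = rng.integers(0, len(samples), size=k)
            samples = samples + [augment_image(samples[int(p)], rng) for p in picks]
    X = np.stack([s.pixels for s in samples])
    y = np.array([lut[s.label] for s in samples], dtype=np.int64)
    return X, y


def train_model(
    spec: NetworkSpec,
    train_set: LabeledDataset,
    val_set: LabeledDataset,
    config: ProtocolConfig,
    seed: int,
) -> TrainedModel:
    """Train a freshly initialized network with early stopping.

    Minimizes softmax cross-entropy with Adam on per-epoch augmented
    minibatches; after each epoch the (un-augmented) validation loss is
    computed, and training stops once it has not improved for
    ``config.patience`` epochs (or at ``config.max_epochs``).  The returned
    model carries the best-validation-epoch weights and the full loss
    history.
    """
    if len(train_set) == 0 or len(val_set) == 0:
        raise ProtocolError("train and validation sets must be non-empty")
    if set(train_set.sample_ids) & set(val_set.sample_ids):
        raise ProtocolError("train and validation sets overlap")
    lut = {c: i for i, c in enumerate(train_set.class_order)}
    Xv = np.stack([s.pixels for s in val_set.samples])
    yv = np.array([lut[s.label] for s in val_set.samples], dtype=np.int64)

    net = SequentialCNN(spec, seed=seed)
    rng = np.random.default_rng([seed, 0x5EED])
    opt = _Adam(net.weights, config.learning_rate)

    history: dict = {"train_loss": [], "val_loss": []}
    best_loss = np.inf
    best_epoch = 0
    best_weights = net.get_weights()
    for epoch in range(config.max_epochs):
        X, y = _epoch_arrays(train_set, lut, config, rng)
        order = rng.permutation(len(y))
        X, y = X[order], y[order]
        losses = []
        for s in range(0, len(y), config.batch_size):
            loss, grads = net.loss_and_grads(X[s : s + config.batch_size], y[s : s + config.batch_size])
            opt.step(net.weights, grads)
            losses.append(loss * len(y[s : s + config.batch_size]))
        history["train_loss"].append(float(np.sum(losses) / len(y)))
        val_loss = net.loss(Xv, yv)
        history["val_loss"].append(float(val_loss))
        if val_loss < best_loss:  # strict: earliest epoch wins ties
            best_loss = val_loss
            best_epoch = epoch
            best_weights = net.get_weights()
        elif epoch - best_epoch >= config.patience:
            break
    net.set_weights(best_weights)
    return TrainedModel(spec=spec, network=net, history=history, best_epoch=best_epoch)


# ---------------------------------------------------------------------------
# The learning-curve experiment (model / results objects)
# ---------------------------------------------------------------------------


def _derive_seed(master: int, *parts: int) -> int:
    """Stable per-(fold, size) seed below 2**31."""
    ss = np.random.SeedSequence([int(master)] + [int(p) for p in parts])
    return int(ss.generate_state(1)[0] % (2**31))


class LearningCurveExperiment:
    """Learning-curve analysis of the small CNN on one labeled dataset.

    Parameters
    ----------
    dataset : LabeledDataset
        The images.  Binary mode uses ``config.positive_class`` (default:
        the first class in ``class_order``) as the positive label.
    config : ProtocolConfig
        The protocol constants.
    spec : NetworkSpec, optional
        Network template; by default the fixed architecture is built for the
        dataset's image size with the deepest stage count the size allows.
    """

    def __init__(
        self,
        dataset: LabeledDataset,
        config: ProtocolConfig,
        spec: NetworkSpec | None = None,
    ):
        self.dataset = dataset
        self.config = config
        h, w, _ = dataset.samples[0].pixels.shape
        n_classes = len(dataset.class_order)
        if spec is None:
            n_stages = config.n_stages
            if n_stages is None:
                n_stages = max(s for s in range(1, 7) if min_input_size(s) <= min(h, w))
            spec = build_network(h, w, 3, n_classes, n_stages=n_stages)
        self.spec = spec

    @classmethod
    def from_directory(cls, image_dir, config: ProtocolConfig, **load_kwargs):
        from .datasets import load_dataset

        return cls(load_dataset(image_dir, **load_kwargs), config)

    def plan(self) -> FoldPlan:
        rng = np.random.default_rng([self.config.seed, 0xF01D])
        labels = dict(zip(self.dataset.sample_ids, self.dataset.labels))
        return plan_folds(self.dataset.sample_ids, self.config, rng, labels=labels)

    def fit(self, *, keep_models: bool = False, verbose: bool = False) -> "LearningCurveResults":
        """Run the full protocol: every fold x subset size, fresh model each.

        Within a fold the test set is fixed, so metric differences across
        sizes are paired; across identical master seeds the whole table is
        bit-reproducible.
        """
        cfg = self.config
        plan = self.plan()
        ds = self.dataset
        lut = {c: i for i, c in enumerate(ds.class_order)}
        pos = cfg.positive_class or ds.class_order[0]
        if cfg.metric == "roc_auc" and pos not in lut:
            raise ProtocolError(f"positive_class {pos!r} not in class order")

        records = []
        models: dict[tuple[int, int], TrainedModel] = {}
        predictions: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
        for k, fold in enumerate(plan.folds):
            test = ds.subset(fold.test_ids)
            val = ds.subset(fold.val_ids)
            Xt, yt = test.to_arrays()
            for size, subset_ids in zip(cfg.subset_sizes, fold.nested_subsets):
                t0 = time.time()
                seed = _derive_seed(cfg.seed, k, size)
                train = ds.subset(subset_ids)
                if cfg.target_per_class is not None:
                    train = balance_by_augmentation(
                        train, cfg.target_per_class, np.random.default_rng([seed, 0xBA1])
                    )
                model = train_model(self.spec, train, val, cfg, seed)
                proba = model.network.predict_proba(Xt)
                if cfg.metric == "roc_auc":
                    value = roc_auc(proba[:, lut[pos]], (yt == lut[pos]).astype(int))
                else:
                    pred = [ds.class_order[i] for i in proba.argmax(axis=1)]
                    true = [ds.class_order[i] for i in yt]
                    value = f1_macro(pred, true)
                records.append(
                    {
                        "fold": k,
                        "train_size": size,
                        "metric_name": cfg.metric,
                        "metric_value": value,
                        "epochs_trained": model.epochs_trained,
                        "seed": seed,
                    }
                )
                predictions[(k, size)] = (yt.copy(), proba)
                if keep_models:
                    models[(k, size)] = model
                if verbose:
                    print(
                        f"fold {k} size {size}: {cfg.metric}={value:.3f} "
                        f"({model.epochs_trained} epochs, {time.time() - t0:.1f}s)"
                    )
        return LearningCurveResults(
            records=pd.DataFrame.from_records(records),
            plan=plan,
            config=cfg,
            spec=self.spec,
            class_order=list(ds.class_order),
            positive_class=pos,
            predictions=predictions,
            models=models,
        )


@dataclass
class LearningCurveResults:
    """Fitted learning curve: records table, fold plan, per-fold predictions."""

    records: pd.DataFrame
    plan: FoldPlan
    config: ProtocolConfig
    spec: NetworkSpec
    class_order: list[str]
    positive_class: str
    predictions: dict = field(default_factory=dict)
    models: dict = field(default_factory=dict)

    def mean_by_size(self) -> pd.Series:
        return self.records.groupby("train_size")["metric_value"].mean()

    def sd_by_size(self) -> pd.Series:
        return self.records.groupby("train_size")["metric_value"].std(ddof=1)

    def box_by_size(self) -> dict[int, object]:
        return {
            int(size): summarize_box(grp["metric_value"].to_numpy())
            for size, grp in self.records.groupby("train_size")
        }

    def roc_curves(self, size: int) -> list[RocCurve]:
        """Per-fold ROC curves at one training-set size (binary mode only)."""
        if self.config.metric != "roc_auc":
            raise ProtocolError("ROC curves are defined for the binary metric only")
        lut = {c: i for i, c in enumerate(self.class_order)}
        pos = lut[self.positive_class]
        curves = []
        for (k, s), (yt, proba) in sorted(self.predictions.items()):
            if s == size:
                curves.append(roc_curve(proba[:, pos], (yt == pos).astype(int)))
        if not curves:
            raise ProtocolError(f"no predictions stored for size {size}")
        return curves

    def summary(self) -> str:
        name = self.records["metric_name"].iloc[0]
        lines = [
            "Learning-curve experiment",
            f"  metric: {name}   folds: {self.config.n_folds}   "
            f"network parameters: {self._n_params()}",
            f"  {'size':>6} {'n':>3} {'mean':>7} {'sd':>7} {'median':>7} {'q1':>7} {'q3':>7}",
        ]
        for size, grp in self.records.groupby("train_size"):
            v = grp["metric_value"].to_numpy()
            box = summarize_box(v)
            sd = v.std(ddof=1) if len(v) > 1 else float("nan")
            lines.append(
                f"  {int(size):>6} {len(v):>3} {v.mean():>7.3f} {sd:>7.3f} "
                f"{box.median:>7.3f} {box.q1:>7.3f} {box.q3:>7.3f}"
            )
        return "\n".join(lines)

    def _n_params(self) -> int:
        from .network import count_parameters

        return count_parameters(self.spec)

    def to_csv(self, path: str | Path) -> None:
        cols = ["fold", "train_size", "metric_name", "metric_value", "epochs_trained", "seed"]
        self.records[cols].to_csv(path, index=False)

    @staticmethod
    def records_from_csv(path: str | Path) -> pd.DataFrame:
        df = pd.read_csv(path)
        expected = {"fold", "train_size", "metric_name", "metric_value", "epochs_trained", "seed"}
        missing = expected - set(df.columns)
        if missing:
            raise ProtocolError(f"results CSV missing columns: {sorted(missing)}")
        return df

    def plot(self, ax=None):
        from .plotting import plot_learning_curve

        return plot_learning_curve(self.records, ax=ax)


def run_learning_curve(
    dataset: LabeledDataset,
    config: ProtocolConfig,
    spec: NetworkSpec | None = None,
    **fit_kwargs,
) -> LearningCurveResults:
    """Functional entry point: build the experiment and fit it."""
    return LearningCurveExperiment(dataset, config, spec=spec).fit(**fit_kwargs)
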