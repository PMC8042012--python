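"""In-memory containers and on-disk formats for labeled single-cell image sets.

A dataset is a directory of 8-bit RGB PNG files plus a ``labels.csv`` table
with header ``filename,label``, mirroring the flat re-annotation spreadsheet
that typically accompanies cytomorphology collections.  In memory every image
is a float RGB array in [0, 1].
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "ImageSample",
    "LabeledDataset",
    "LabelsTable",
    "ALL_CLASS_COUNTS",
    "filter_classes_by_count",
    "load_dataset",
    "save_dataset",
    "find_exact_duplicates",
]

#: Diagnostic class sizes of the expert re-annotation of the 250-image ALL
#: collection (ten morphological types; used for class-bookkeeping checks and
#: as the default class-frequency profile of the six-class synthetic mode).
ALL_CLASS_COUNTS: Mapping[str, int] = {
    "basophil": 1,
    "erythroblast": 1,
    "eosinophil": 2,
    "lymphoblast": 126,
    "lymphocyte_atypical": 12,
    "lymphocyte_typical": 52,
    "metamyelocyte": 1,
    "monocyte": 5,
    "neutrophil_segmented": 22,
    "thrombocyte": 28,
}


class DatasetError(ValueError):
    """Raised for malformed datasets (missing files, duplicate names, ...)."""


@dataclass
class ImageSample:
    """One RGB single-cell image with its class label.

    Attributes
    ----------
    pixels : ndarray, shape (H, W, 3)
        Float RGB values in [0, 1].
    label : str
        Class label.
    sample_id : str
        Unique identifier (doubles as the on-disk filename stem).
    """

    pixels: np.ndarray
    label: str
    sample_id: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise DatasetError(
                f"sample {self.sample_id!r}: expected (H, W, 3) RGB pixels, "
                f"got shape {self.pixels.shape}"
            )
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise DatasetError(
                f"sample {self.sample_id!r}: pixel values outside [0, 1] "
                f"(min {lo:.4g}, max {hi:.4g})"
            )


@dataclass
class LabelsTable:
    """Rows of (filename, label) with an explicit class ordering."""

    rows: list[tuple[str, str]]
    class_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [fn for fn, _ in self.rows]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise DatasetError(f"duplicate filenames in labels table: {dup}")
        if not self.class_order:
            self.class_order = sorted({lbl for _, lbl in self.rows})
        unknown = {lbl for _, lbl in self.rows} - set(self.class_order)
        if unknown:
            raise DatasetError(f"labels not in class_order: {sorted(unknown)}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "LabelsTable":
        df = pd.read_csv(path)
        if list(df.columns[:2]) != ["filename", "label"]:
            raise DatasetError(
                f"{path}: expected CSV header 'filename,label', got {list(df.columns)}"
            )
        return cls(rows=list(zip(df["filename"].astype(str), df["label"].astype(str))))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.rows, columns=["filename", "label"]).to_csv(path, index=False)

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {c: 0 for c in self.class_order}
        for _, lbl in self.rows:
            counts[lbl] += 1
        return counts


class LabeledDataset:
    """An ordered collection of :class:`ImageSample` with a fixed class order."""

    def __init__(self, samples: Sequence[ImageSample], class_order: Sequence[str] | None = None):
        self.samples: list[ImageSample] = list(samples)
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise DatasetError("duplicate sample_ids in dataset")
        if class_order is None:
            class_order = sorted({s.label for s in self.samples})
        self.class_order: list[str] = list(class_order)
        unknown = {s.label for s in self.samples} - set(self.class_order)
        if unknown:
            raise DatasetError(f"labels not in class_order: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[ImageSample]:
        return iter(self.samples)

    def __getitem__(self, i: int) -> ImageSample:
        return self.samples[i]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.samples]

    def by_id(self, sample_id: str) -> ImageSample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def subset(self, ids: Iterable[str]) -> "LabeledDataset":
        wanted = list(ids)
        index = {s.sample_id: s for s in self.samples}
        missing = [i for i in wanted if i not in index]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        return LabeledDataset([index[i] for i in wanted], class_order=self.class_order)

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in self.class_order}
        for s in self.samples:
            counts[s.label] += 1
        return counts

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Stack into (X, y) with y as integer indices into ``class_order``."""
        X = np.stack([s.pixels for s in self.samples]).astype(np.float64)
        lut = {c: i for i, c in enumerate(self.class_order)}
        y = np.array([lut[s.label] for s in self.samples], dtype=np.int64)
        return X, y


def filter_classes_by_count(
    counts: Mapping[str, int], min_count: int = 5
) -> list[str]:
    """Classes with at least ``min_count`` members, in descending frequency.

    Applied to the ten-type expert re-annotation this retains the six
    trainable classes (classes with fewer than five images cannot survive a
    train/validation split).
    """
    kept = [c for c, n in counts.items() if n >= min_count]
    return sorted(kept, key=lambda c: (-counts[c], c))


def save_dataset(dataset: LabeledDataset, outdir: str | Path) -> Path:
    """Write PNGs plus ``labels.csv``; returns the labels path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in dataset.samples:
        fname = f"{s.sample_id}.png"
        arr = np.clip(np.round(s.pixels * 255.0), 0, 255).astype(np.uint8)
        iio.imwrite(outdir / fname, arr)
        rows.append((fname, s.label))
    table = LabelsTable(rows=rows, class_order=dataset.class_order)
    labels_path = outdir / "labels.csv"
    table.to_csv(labels_path)
    return labels_path


def _fit_to_size(arr: np.ndarray, size: int) -> np.ndarray:
    """Center-crop or zero-pad an (H, W, 3) array to (size, size, 3)."""
    out = np.zeros((size, size, 3), dtype=arr.dtype)
    h, w = arr.shape[:2]
    src_y = max(0, (h - size) // 2)
    src_x = max(0, (w - size) // 2)
    dst_y = max(0, (size - h) // 2)
    dst_x = max(0, (size - w) // 2)
    ch = min(h, size)
    cw = min(w, size)
    out[dst_y : dst_y + ch, dst_x : dst_x + cw] = arr[src_y : src_y + ch, src_x : src_x + cw]
    return out


def load_dataset(
    image_dir: str | Path,
    labels_csv: str | Path | None = None,
    expected_size: int | None = None,
    *,
    size_policy: str = "error",
    min_class_count: int | None = None,
) -> LabeledDataset:
    """Load a PNG/TIFF directory plus labels CSV into a :class:`LabeledDataset`.

    Parameters
    ----------
    image_dir : path
        Directory holding the image files named in the labels table.
    labels_csv : path, optional
        Defaults to ``image_dir/labels.csv``.
    expected_size : int, optional
        Required square image side; mismatches are rejected
        (``size_policy='error'``) or center-cropped/zero-padded
        (``size_policy='fit'``).
    min_class_count : int, optional
        Drop classes with fewer images than this (the trainable-class filter).
    """
    image_dir = Path(image_dir)
    if labels_csv is None:
        labels_csv = image_dir / "labels.csv"
    if size_policy not in ("error", "fit"):
        raise ValueError(f"unknown size_policy {size_policy!r}")
    table = LabelsTable.from_csv(labels_csv)

    samples = []
    for fname, label in table.rows:
        path = image_dir / fname
        if not path.exists():
            raise DatasetError(f"labels row references missing file: {path}")
        try:
            arr = np.asarray(iio.imread(path))
        except Exception as exc:  # pragma: no cover - backend specific
            raise DatasetError(f"unreadable image {path}: {exc}") from exc
        if arr.ndim == 2:
            arr = np.stack([arr] * 3, axis=-1)
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        pixels = arr.astype(np.float64) / 255.0
        if expected_size is not None and pixels.shape[:2] != (expected_size, expected_size):
            if size_policy == "error":
                raise DatasetError(
                    f"{path}: image is {pixels.shape[1]}x{pixels.shape[0]}, "
                    f"expected {expected_size}x{expected_size}"
                )
            pixels = _fit_to_size(pixels, expected_size)
        samples.append(ImageSample(pixels=pixels, label=label, sample_id=Path(fname).stem))

    class_order = table.class_order
    if min_class_count is not None:
        counts: dict[str, int] = {}
        for s in samples:
            counts[s.label] = counts.get(s.label, 0) + 1
        keep = {c for c in class_order if counts.get(c, 0) >= min_class_count}
        samples = [s for s in samples if s.label in keep]
        class_order = [c for c in class_order if c in keep]
    return LabeledDataset(samples, class_order=class_order)


def find_exact_duplicates(dataset: LabeledDataset) -> list[tuple[str, str]]:
    """Pairs (kept_id, duplicate_id) of byte-identical images.

    Utility mirroring duplicate screening done when curating small slide
    collections; exact pixel equality only, no perceptual hashing.
    """
    seen: dict[str, str] = {}
    dups: list[tuple[str, str]] = []
    for s in dataset.samples:
        digest = hashlib.sha256(
            np.ascontiguousarray(np.round(s.pixels * 255).astype(np.uint8))
        ).hexdigest()
        if digest in seen:
            dups.append((seen[digest], s.sample_id))
        else:
            seen[digest] = s.sample_id
    return dups
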