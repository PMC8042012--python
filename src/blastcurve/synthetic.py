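"""Seeded synthetic single-leukocyte image generator.

Emulates the class-conditional morphology of stained blood-smear single-cell
crops so that classifier training, learning-curve protocols and
interpretability analyses can be exercised end-to-end without access to the
original clinical image collections.  The morphological axes modeled are the
ones cytologists use to tell the classes apart:

* nucleus:cytoplasm area ratio (high and round for blasts),
* nuclear lobation (segmented neutrophils have 2-5 lobes),
* chromatin texture contrast (fine in blasts, coarse in mature cells),
* stain colors of nucleus, cytoplasm and background,
* overall cell size (thrombocytes are small anucleate fragments).

An ``effect_size`` dial interpolates every class parameter between the pooled
across-class mean (0: classes indistinguishable by construction) and the full
class-specific values (1: the stated morphology).  Rendering is purely
procedural (ellipse lobes, filtered-noise chromatin, optional red-cell-like
background distractors) and bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .datasets import ImageSample, LabeledDataset

__all__ = [
    "MorphologyClassSpec",
    "SyntheticConfig",
    "MorphologyStats",
    "RenderedCell",
    "two_class_specs",
    "six_class_specs",
    "render_cell",
    "generate_dataset",
    "generate_rendered",
    "measure_morphology",
]

RGB = tuple[float, float, float]
Dist = tuple[float, float]  # (mean, sd)


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class MorphologyClassSpec:
    """Class-conditional morphology distribution of one leukocyte type.

    Distributions are (mean, sd) of truncated normals.  ``nucleus_area_fraction``
    is nucleus area over cell area (the N:C ratio proxy); ``cell_radius_fraction``
    is cell radius over image half-width; ``lobe_count`` is rounded and clipped
    to [1, 6] at sampling time.  Colors are RGB means in [0, 1] with a shared
    per-channel sd.
    """

    class_name: str
    nucleus_area_fraction: Dist = (0.5, 0.05)
    lobe_count: Dist = (1.0, 0.0)
    chromatin_texture_amplitude: float = 0.1
    cytoplasm_color: RGB = (0.70, 0.75, 0.92)
    nucleus_color: RGB = (0.35, 0.15, 0.45)
    background_color: RGB = (0.88, 0.85, 0.80)
    color_sd: float = 0.03
    cell_radius_fraction: Dist = (0.5, 0.05)
    has_nucleus: bool = True

    def __post_init__(self) -> None:
        if self.has_nucleus and not (0.0 < self.nucleus_area_fraction[0] < 1.0):
            raise ConfigurationError(
                f"{self.class_name}: nucleus_area_fraction mean must lie in (0, 1)"
            )
        if self.lobe_count[0] < 1 and self.has_nucleus:
            raise ConfigurationError(f"{self.class_name}: lobe_count mean must be >= 1")
        if self.chromatin_texture_amplitude < 0:
            raise ConfigurationError(f"{self.class_name}: negative chromatin amplitude")
        for name in ("cytoplasm_color", "nucleus_color", "background_color"):
            col = getattr(self, name)
            if not all(0.0 <= v <= 1.0 for v in col):
                raise ConfigurationError(f"{self.class_name}: {name} outside [0, 1]")


def two_class_specs() -> list[MorphologyClassSpec]:
    """Blast-like vs. non-blast default specs (binary mode).

    The blast class has the classic high N:C ratio (~0.75), a round nucleus
    and fine (low-contrast) chromatin; the non-blast class is a typical
    mature lymphocyte (~0.45 N:C, coarser chromatin, smaller cell).
    """
    return [
        MorphologyClassSpec(
            class_name="blast",
            nucleus_area_fraction=(0.75, 0.05),
            lobe_count=(1.0, 0.0),
            chromatin_texture_amplitude=0.05,
            nucleus_color=(0.35, 0.15, 0.50),
            cytoplasm_color=(0.62, 0.68, 0.90),
            cell_radius_fraction=(0.55, 0.04),
        ),
        MorphologyClassSpec(
            class_name="non_blast",
            nucleus_area_fraction=(0.45, 0.06),
            lobe_count=(1.0, 0.0),
            chromatin_texture_amplitude=0.16,
            nucleus_color=(0.28, 0.10, 0.40),
            cytoplasm_color=(0.72, 0.78, 0.93),
            cell_radius_fraction=(0.45, 0.04),
        ),
    ]


def six_class_specs() -> list[MorphologyClassSpec]:
    """Six-class defaults: the trainable leukocyte types of the ALL setting."""
    return [
        MorphologyClassSpec(
            class_name="lymphoblast",
            nucleus_area_fraction=(0.75, 0.05),
            lobe_count=(1.0, 0.0),
            chromatin_texture_amplitude=0.05,
            nucleus_color=(0.35, 0.15, 0.50),
            cytoplasm_color=(0.62, 0.68, 0.90),
            cell_radius_fraction=(0.55, 0.04),
        ),
        MorphologyClassSpec(
            class_name="lymphocyte_atypical",
            nucleus_area_fraction=(0.58, 0.06),
            lobe_count=(1.0, 0.0),
            chromatin_texture_amplitude=0.12,
            nucleus_color=(0.30, 0.12, 0.42),
            cytoplasm_color=(0.68, 0.74, 0.92),
            cell_radius_fraction=(0.52, 0.05),
        ),
        MorphologyClassSpec(
            class_name="lymphocyte_typical",
            nucleus_area_fraction=(0.45, 0.05),
            lobe_count=(1.0, 0.0),
            chromatin_texture_amplitude=0.16,
            nucleus_color=(0.28, 0.10, 0.40),
            cytoplasm_color=(0.72, 0.78, 0.93),
            cell_radius_fraction=(0.42, 0.04),
        ),
        MorphologyClassSpec(
            class_name="monocyte",
            nucleus_area_fraction=(0.55, 0.05),
            lobe_count=(2.0, 0.3),  # indented / kidney-shaped nucleus
            chromatin_texture_amplitude=0.10,
            nucleus_color=(0.40, 0.25, 0.55),
            cytoplasm_color=(0.70, 0.72, 0.85),
            cell_radius_fraction=(0.62, 0.05),
        ),
        MorphologyClassSpec(
            class_name="neutrophil_segmented",
            nucleus_area_fraction=(0.35, 0.05),
            lobe_count=(3.2, 0.8),
            chromatin_texture_amplitude=0.20,
            nucleus_color=(0.30, 0.12, 0.45),
            cytoplasm_color=(0.90, 0.80, 0.85),
            cell_radius_fraction=(0.52, 0.04),
        ),
        MorphologyClassSpec(
            class_name="thrombocyte",
            nucleus_area_fraction=(0.5, 0.0),  # ignored: anucleate
            lobe_count=(1.0, 0.0),
            chromatin_texture_amplitude=0.05,
            cytoplasm_color=(0.76, 0.70, 0.86),
            cell_radius_fraction=(0.16, 0.03),
            has_nucleus=False,
        ),
    ]


@dataclass
class SyntheticConfig:
    """Full generator configuration; the stated world of one synthetic run."""

    classes: list[MorphologyClassSpec] = field(default_factory=two_class_specs)
    image_size: int = 257
    n_per_class: int = 125
    effect_size: float = 1.0
    distractors: bool = True
    noise_sd: float = 0.02  # global pixel noise added after rendering
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ConfigurationError(
                f"image_size {self.image_size} too small to render a cell (minimum 32)"
            )
        if self.n_per_class < 1:
            raise ConfigurationError("n_per_class must be >= 1")
        if not (0.0 <= self.effect_size <= 1.0):
            raise ConfigurationError("effect_size must lie in [0, 1]")
        if not self.classes:
            raise ConfigurationError("at least one class spec required")


@dataclass
class MorphologyStats:
    """Measurements taken on a rendered cell, for generator validation."""

    measured_nucleus_area_fraction: float
    measured_lobe_count: int
    mean_cell_color: np.ndarray


@dataclass
class RenderedCell:
    """A rendered sample together with its ground-truth masks."""

    sample: ImageSample
    cell_mask: np.ndarray
    nucleus_mask: np.ndarray


def _lerp(a: float, b: float, t: float) -> float:
    return a + t * (b - a)


def _lerp_rgb(a: Sequence[float], b: Sequence[float], t: float) -> RGB:
    return tuple(_lerp(x, y, t) for x, y in zip(a, b))  # type: ignore[return-value]


def _pooled_spec(classes: Sequence[MorphologyClassSpec]) -> MorphologyClassSpec:
    """Across-class parameter mean; anucleate classes contribute 0 N:C."""
    n = len(classes)

    def mean(vals: Sequence[float]) -> float:
        return float(sum(vals)) / n

    frac_means = [c.nucleus_area_fraction[0] if c.has_nucleus else 0.0 for c in classes]
    pooled_frac = mean(frac_means)
    return MorphologyClassSpec(
        class_name="pooled",
        nucleus_area_fraction=(max(pooled_frac, 1e-3), mean([c.nucleus_area_fraction[1] for c in classes])),
        lobe_count=(mean([c.lobe_count[0] for c in classes]), mean([c.lobe_count[1] for c in classes])),
        chromatin_texture_amplitude=mean([c.chromatin_texture_amplitude for c in classes]),
        cytoplasm_color=tuple(mean([c.cytoplasm_color[i] for c in classes]) for i in range(3)),
        nucleus_color=tuple(mean([c.nucleus_color[i] for c in classes]) for i in range(3)),
        background_color=tuple(mean([c.background_color[i] for c in classes]) for i in range(3)),
        color_sd=mean([c.color_sd for c in classes]),
        cell_radius_fraction=(mean([c.cell_radius_fraction[0] for c in classes]), mean([c.cell_radius_fraction[1] for c in classes])),
        has_nucleus=pooled_frac > 0.02,
    )


def _effective_spec(
    spec: MorphologyClassSpec, pooled: MorphologyClassSpec, effect: float
) -> MorphologyClassSpec:
    """Interpolate a class spec toward the pooled spec (effect 0 = pooled)."""
    if effect == 1.0:
        return spec
    own_frac = spec.nucleus_area_fraction[0] if spec.has_nucleus else 0.0
    frac_mean = _lerp(pooled.nucleus_area_fraction[0], own_frac, effect)
    return dataclasses.replace(
        spec,
        nucleus_area_fraction=(
            max(frac_mean, 1e-3),
            _lerp(pooled.nucleus_area_fraction[1], spec.nucleus_area_fraction[1], effect),
        ),
        lobe_count=(
            _lerp(pooled.lobe_count[0], spec.lobe_count[0], effect),
            _lerp(pooled.lobe_count[1], spec.lobe_count[1], effect),
        ),
        chromatin_texture_amplitude=_lerp(
            pooled.chromatin_texture_amplitude, spec.chromatin_texture_amplitude, effect
        ),
        cytoplasm_color=_lerp_rgb(pooled.cytoplasm_color, spec.cytoplasm_color, effect),
        nucleus_color=_lerp_rgb(pooled.nucleus_color, spec.nucleus_color, effect),
        background_color=_lerp_rgb(pooled.background_color, spec.background_color, effect),
        color_sd=_lerp(pooled.color_sd, spec.color_sd, effect),
        cell_radius_fraction=(
            _lerp(pooled.cell_radius_fraction[0], spec.cell_radius_fraction[0], effect),
            _lerp(pooled.cell_radius_fraction[1], spec.cell_radius_fraction[1], effect),
        ),
        has_nucleus=frac_mean > 0.02,
    )


def _ellipse_mask(size: int, cy: float, cx: float, ry: float, rx: float, theta: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    y = yy - cy
    x = xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * x + st * y
    v = -st * x + ct * y
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def _sample_color(mean: RGB, sd: float, rng: np.random.Generator) -> np.ndarray:
    return np.clip(np.asarray(mean) + sd * rng.standard_normal(3), 0.0, 1.0)


def render_cell(
    class_spec: MorphologyClassSpec,
    image_size: int,
    rng: np.random.Generator,
    *,
    distractors: bool = True,
    noise_sd: float = 0.02,
) -> RenderedCell:
    """Render one centered cell on a smear-like background.

    The cell body is an ellipse whose radius is drawn from
    ``cell_radius_fraction``; the nucleus is ``lobe_count`` ellipses placed on
    a ring (spread out so that modest lobe counts yield disjoint lobes) whose
    total area matches the drawn nucleus area fraction; chromatin is
    low-pass-filtered noise confined to the nucleus mask.  Background
    distractor discs mimic out-of-focus red cells.  Pixels are clipped to
    [0, 1]; the sample_id is left empty for the caller to assign.
    """
    if image_size < 32:
        raise ConfigurationError(f"image_size {image_size} < 32")
    size = image_size
    half = size / 2.0

    bg = _sample_color(class_spec.background_color, class_spec.color_sd, rng)
    img = np.ones((size, size, 3)) * bg

    if distractors:
        n_distr = int(rng.poisson(6))
        for _ in range(n_distr):
            dy, dx = rng.uniform(0, size, 2)
            dr = rng.uniform(0.06, 0.12) * size
            dmask = _ellipse_mask(size, dy, dx, dr, dr * rng.uniform(0.85, 1.0), rng.uniform(0, np.pi))
            dcol = _sample_color((0.86, 0.58, 0.56), 0.04, rng)
            img[dmask] = 0.6 * dcol + 0.4 * img[dmask]

    # cell body
    r_cell = float(np.clip(rng.normal(*class_spec.cell_radius_fraction), 0.08, 0.92)) * half
    ratio = rng.uniform(0.85, 1.0)
    theta = rng.uniform(0, np.pi)
    jitter = 0.03 * size
    cy = half + rng.uniform(-jitter, jitter)
    cx = half + rng.uniform(-jitter, jitter)
    cell_mask = _ellipse_mask(size, cy, cx, r_cell, r_cell * ratio, theta)
    img[cell_mask] = _sample_color(class_spec.cytoplasm_color, class_spec.color_sd, rng)

    # nucleus lobes
    nucleus_mask = np.zeros((size, size), dtype=bool)
    if class_spec.has_nucleus:
        frac = float(np.clip(rng.normal(*class_spec.nucleus_area_fraction), 0.03, 0.92))
        k = int(np.clip(round(rng.normal(*class_spec.lobe_count)), 1, 6))
        cell_area = np.pi * r_cell * (r_cell * ratio)
        lobe_area = frac * cell_area / k
        a = np.sqrt(lobe_area / np.pi)  # lobe radius (circular)
        if k == 1:
            nucleus_mask = _ellipse_mask(
                size, cy, cx, a / np.sqrt(ratio), a * np.sqrt(ratio) * rng.uniform(0.9, 1.0),
                rng.uniform(0, np.pi),
            )
        else:
            # ring radius: keep lobes inside the cell, push them apart
            ring = min(0.92 * r_cell * ratio - a, max(1.15 * a / np.sin(np.pi / k), 1.3 * a))
            ring = max(ring, 0.0)
            phase = rng.uniform(0, 2 * np.pi)
            for i in range(k):
                ang = phase + 2 * np.pi * i / k + rng.normal(0, 0.08)
                ly = cy + ring * np.sin(ang)
                lx = cx + ring * np.cos(ang)
                nucleus_mask |= _ellipse_mask(
                    size, ly, lx, a * rng.uniform(0.95, 1.05), a * rng.uniform(0.95, 1.05),
                    rng.uniform(0, np.pi),
                )
        nucleus_mask &= cell_mask
        img[nucleus_mask] = _sample_color(class_spec.nucleus_color, class_spec.color_sd, rng)

        if class_spec.chromatin_texture_amplitude > 0 and nucleus_mask.any():
            noise = rng.standard_normal((size, size))
            noise = ndimage.gaussian_filter(noise, sigma=1.5)
            sd = noise.std()
            if sd > 0:
                noise /= sd
            img[nucleus_mask] += (
                class_spec.chromatin_texture_amplitude * noise[nucleus_mask, None]
            )

    if noise_sd > 0:
        img += noise_sd * rng.standard_normal(img.shape)
    img = np.clip(img, 0.0, 1.0)
    sample = ImageSample(pixels=img, label=class_spec.class_name, sample_id="unassigned")
    return RenderedCell(sample=sample, cell_mask=cell_mask, nucleus_mask=nucleus_mask)


def generate_rendered(config: SyntheticConfig) -> list[RenderedCell]:
    """Render the full configured dataset, keeping ground-truth masks."""
    rng = np.random.default_rng(config.seed)
    pooled = _pooled_spec(config.classes)
    out: list[RenderedCell] = []
    for spec in config.classes:
        eff = _effective_spec(spec, pooled, config.effect_size)
        for i in range(config.n_per_class):
            rc = render_cell(
                eff, config.image_size, rng,
                distractors=config.distractors, noise_sd=config.noise_sd,
            )
            rc.sample.sample_id = f"{spec.class_name}_{i:04d}"
            rc.sample.label = spec.class_name  # label by nominal class, not pooled
            out.append(rc)
    return out


def generate_dataset(config: SyntheticConfig) -> LabeledDataset:
    """Generate a balanced labeled dataset (``n_per_class`` per class)."""
    rendered = generate_rendered(config)
    return LabeledDataset(
        [rc.sample for rc in rendered],
        class_order=[c.class_name for c in config.classes],
    )


def measure_morphology(
    sample: ImageSample, nucleus_mask: np.ndarray, cell_mask: np.ndarray
) -> MorphologyStats:
    """Measure N:C area fraction, lobe count and mean cell color.

    The lobe count is the number of 8-connected components of the nucleus
    mask; the fraction is nucleus pixels over cell pixels.
    """
    if nucleus_mask.shape != sample.pixels.shape[:2]:
        raise ValueError("nucleus mask shape does not match image")
    if cell_mask.shape != sample.pixels.shape[:2]:
        raise ValueError("cell mask shape does not match image")
    n_cell = int(cell_mask.sum())
    if n_cell == 0:
        raise ValueError("empty cell mask: nucleus area fraction undefined")
    n_nuc = int(nucleus_mask.sum())
    _, n_lobes = ndimage.label(nucleus_mask, structure=np.ones((3, 3), dtype=int))
    mean_color = (
        sample.pixels[cell_mask].mean(axis=0) if n_cell else np.zeros(3)
    )
    return MorphologyStats(
        measured_nucleus_area_fraction=n_nuc / n_cell,
        measured_lobe_count=int(n_lobes),
        mean_cell_color=mean_color,
    )
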