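"""Synthetic dermoscopy-like fixtures with exact ground truth.

Generates elliptical-lesion images on uniform skin, dark hair-stroke
overlays with pixel-exact ground-truth masks, and patient metadata
tables — everything the rest of the toolkit needs for testing without
real data. Hair strokes are rasterized as hard-edged quadratic Bezier
polylines (no anti-aliasing) so the changed-pixel set is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import imageio.v3 as iio
import numpy as np
import pandas as pd

from dermokit.labels import CLASS_NAMES
from dermokit.metadata import (
    AGE_CATEGORIES,
    SEX_CATEGORIES,
    SITE_CATEGORIES,
    MetadataRecord,
)

__all__ = [
    "LesionImageSpec",
    "HairOverlaySpec",
    "SyntheticSample",
    "generate_lesion_image",
    "overlay_hair",
    "generate_metadata",
    "generate_dataset",
    "write_dataset",
]


@dataclass(frozen=True)
class LesionImageSpec:
    """Parameters of a synthetic lesion image."""

    height: int = 128
    width: int = 128
    skin_level: Tuple[int, int, int] = (200, 170, 150)
    lesion_center: Optional[Tuple[int, int]] = None
    lesion_axes: Tuple[int, int] = (25, 20)
    lesion_level: Tuple[int, int, int] = (120, 80, 70)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("image dimensions must be positive")
        for level in (self.skin_level, self.lesion_level):
            if not all(0 <= v <= 255 for v in level):
                raise ValueError(f"intensity levels must be in [0, 255], got {level}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        ay, ax = self.lesion_axes
        if ay < 0 or ax < 0:
            raise ValueError("lesion axes must be >= 0")
        cy, cx = self.center
        if ay > 0 and ax > 0:
            if not (cy - ay >= 0 and cy + ay < self.height and cx - ax >= 0 and cx + ax < self.width):
                raise ValueError("lesion ellipse must fit inside the image")

    @property
    def center(self) -> Tuple[int, int]:
        if self.lesion_center is not None:
            return self.lesion_center
        return (self.height // 2, self.width // 2)


@dataclass(frozen=True)
class HairOverlaySpec:
    """Parameters of the dark hair-stroke overlay."""

    n_strokes: int = 5
    stroke_width_range: Tuple[int, int] = (1, 3)
    stroke_darkness: int = 120
    curvature: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.stroke_width_range
        if lo < 1 or hi < lo:
            raise ValueError(f"bad stroke_width_range {self.stroke_width_range}")
        if self.n_strokes < 0:
            raise ValueError("n_strokes must be >= 0")
        if self.stroke_darkness <= 0:
            raise ValueError("stroke_darkness must be > 0 (hair is darker than skin)")


@dataclass
class SyntheticSample:
    """One labeled synthetic sample."""

    image: np.ndarray
    hair_mask_truth: np.ndarray
    label: str
    metadata: MetadataRecord


def lesion_interior_mask(spec: LesionImageSpec) -> np.ndarray:
    """Boolean mask of the discrete ellipse interior (inclusive boundary)."""
    ay, ax = spec.lesion_axes
    if ay <= 0 or ax <= 0:
        return np.zeros((spec.height, spec.width), dtype=bool)
    cy, cx = spec.center
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def generate_lesion_image(spec: LesionImageSpec) -> np.ndarray:
    """Render the lesion image: ellipse interior at lesion_level, exterior
    at skin_level, plus optional Gaussian noise; uint8, deterministic."""
    rng = np.random.default_rng(spec.seed)
    inside = lesion_interior_mask(spec)
    img = np.empty((spec.height, spec.width, 3), dtype=np.float64)
    for c in range(3):
        img[:, :, c] = np.where(inside, spec.lesion_level[c], spec.skin_level[c])
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def _stamp_offsets(width: int) -> np.ndarray:
    """Offsets of a width x width square stamp centered on the stroke path."""
    half = width // 2
    rng = np.arange(width) - half
    dy, dx = np.meshgrid(rng, rng, indexing="ij")
    return np.stack([dy.ravel(), dx.ravel()], axis=1)


def _rasterize_stroke(shape: Tuple[int, int], rng: np.random.Generator, spec: HairOverlaySpec) -> np.ndarray:
    """Rasterize one quadratic Bezier stroke; returns its boolean mask."""
    H, W = shape
    diag = float(np.hypot(H, W))
    p0 = rng.uniform([0, 0], [H - 1, W - 1])
    angle = rng.uniform(0, 2 * np.pi)
    length = rng.uniform(0.6, 1.2) * diag
    p2 = p0 + length * np.array([np.sin(angle), np.cos(angle)])
    mid = (p0 + p2) / 2
    perp = np.array([-np.cos(angle), np.sin(angle)])
    p1 = mid + perp * spec.curvature * length * rng.uniform(-1, 1)

    t = np.linspace(0.0, 1.0, max(int(2 * length), 16))[:, None]
    pts = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2

    width = int(rng.integers(spec.stroke_width_range[0], spec.stroke_width_range[1] + 1))
    stamped = pts[:, None, :] + _stamp_offsets(width)[None, :, :]
    stamped = np.round(stamped.reshape(-1, 2)).astype(np.int64)
    valid = (
        (stamped[:, 0] >= 0) & (stamped[:, 0] < H) & (stamped[:, 1] >= 0) & (stamped[:, 1] < W)
    )
    mask = np.zeros(shape, dtype=bool)
    mask[stamped[valid, 0], stamped[valid, 1]] = True
    return mask


def overlay_hair(image: np.ndarray, spec: HairOverlaySpec) -> Tuple[np.ndarray, np.ndarray]:
    """Darken hair-stroke pixels by ``stroke_darkness`` (clipped at 0).

    Returns (overlaid image, ground-truth mask). The mask is exactly the
    set of pixels whose value changed in at least one channel; strokes
    over already-black pixels cannot darken and are excluded.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 image, got shape {image.shape}")
    rng = np.random.default_rng(spec.seed)
    stroke_mask = np.zeros(image.shape[:2], dtype=bool)
    for _ in range(spec.n_strokes):
        stroke_mask |= _rasterize_stroke(image.shape[:2], rng, spec)
    out = image.astype(np.int64)
    out[stroke_mask] = np.clip(out[stroke_mask] - spec.stroke_darkness, 0, 255)
    out = out.astype(np.uint8)
    changed = np.any(out != image, axis=2)
    return out, changed


def generate_metadata(
    n: int,
    seed: int = 0,
    sex_probs: Optional[Sequence[float]] = None,
    site_probs: Optional[Sequence[float]] = None,
    age_probs: Optional[Sequence[float]] = None,
) -> List[MetadataRecord]:
    """Draw n metadata records from the legal category sets.

    Marginals default to uniform; pass probability vectors to emulate a
    skewed cohort (e.g. male-dominated, posterior-torso-heavy).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    sexes = rng.choice(SEX_CATEGORIES, size=n, p=sex_probs)
    sites = rng.choice(SITE_CATEGORIES, size=n, p=site_probs)
    ages = rng.choice(AGE_CATEGORIES, size=n, p=age_probs)
    return [
        MetadataRecord(sex=str(s), anatom_site=str(a), age=int(g))
        for s, a, g in zip(sexes, sites, ages)
    ]


def _class_appearance(class_index: int, height: int, width: int) -> Tuple[Tuple[int, int, int], Tuple[int, int]]:
    """Fixed class -> appearance coupling: lesion mean level decreases and
    axes vary with class index, making the label learnable from pixels."""
    level = (
        max(0, 160 - 12 * class_index),
        max(0, 120 - 9 * class_index),
        max(0, 100 - 6 * class_index),
    )
    axes = (
        height // 5 + class_index,
        width // 6 + (3 * class_index) % 7,
    )
    return level, axes


def generate_dataset(
    n_per_class: int,
    classes: Optional[Sequence[str]] = None,
    seed: int = 0,
    height: int = 128,
    width: int = 128,
    hair: Optional[HairOverlaySpec] = None,
    noise_sd: float = 3.0,
) -> List[SyntheticSample]:
    """Class-balanced labeled dataset with optional hair overlays.

    Appearance is coupled to the class index (see ``_class_appearance``)
    and the metadata age group is weakly coupled too, so a small model
    can overfit the labels.
    """
    classes = tuple(classes) if classes is not None else CLASS_NAMES
    unknown = [c for c in classes if c not in CLASS_NAMES]
    if unknown:
        raise ValueError(f"unknown class names: {unknown}")
    rng = np.random.default_rng(seed)
    samples: List[SyntheticSample] = []
    for label in classes:
        k = CLASS_NAMES.index(label)
        level, axes = _class_appearance(k, height, width)
        # clamp so the ellipse plus center jitter always fits in the image
        axes = (min(axes[0], height // 2 - 6), min(axes[1], width // 2 - 6))
        jy = min(4, height // 2 - axes[0] - 1)
        jx = min(4, width // 2 - axes[1] - 1)
        for i in range(n_per_class):
            jitter = (int(rng.integers(-jy, jy + 1)), int(rng.integers(-jx, jx + 1)))
            center = (height // 2 + jitter[0], width // 2 + jitter[1])
            spec = LesionImageSpec(
                height=height,
                width=width,
                lesion_center=center,
                lesion_axes=axes,
                lesion_level=level,
                noise_sd=noise_sd,
                seed=int(rng.integers(0, 2**31)),
            )
            img = generate_lesion_image(spec)
            if hair is not None and hair.n_strokes > 0:
                hspec = HairOverlaySpec(
                    n_strokes=hair.n_strokes,
                    stroke_width_range=hair.stroke_width_range,
                    stroke_darkness=hair.stroke_darkness,
                    curvature=hair.curvature,
                    seed=int(rng.integers(0, 2**31)),
                )
                img, mask = overlay_hair(img, hspec)
            else:
                mask = np.zeros((height, width), dtype=bool)
            meta = MetadataRecord(
                sex=SEX_CATEGORIES[int(rng.integers(0, 2))],
                anatom_site=SITE_CATEGORIES[int(rng.integers(0, len(SITE_CATEGORIES)))],
                age=AGE_CATEGORIES[(2 * k + int(rng.integers(0, 2))) % len(AGE_CATEGORIES)],
            )
            samples.append(
                SyntheticSample(image=img, hair_mask_truth=mask, label=label, metadata=meta)
            )
    return samples


def write_dataset(samples: Sequence[SyntheticSample], out_dir: Union[str, Path]) -> pd.DataFrame:
    """Write PNG images, 0/255 mask PNGs and a CSV manifest.

    Manifest columns: filename, label, sex, age, anatom_site, mask_filename.
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(samples):
        name = f"sample_{i:05d}.png"
        iio.imwrite(out_dir / "images" / name, s.image)
        iio.imwrite(out_dir / "masks" / name, (s.hair_mask_truth.astype(np.uint8) * 255))
        rows.append(
            {
                "filename": f"images/{name}",
                "label": s.label,
                "sex": s.metadata.sex,
                "age": s.metadata.age,
                "anatom_site": s.metadata.anatom_site,
                "mask_filename": f"masks/{name}",
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
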