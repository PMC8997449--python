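"""Affine augmentation, resizing, class balancing and the train/val split.

Right-angle rotations and reflections use exact index permutations;
arbitrary angles, shifts and scalings go through bilinear warps with
edge filling. Balancing appends affine-transformed copies (never raw
duplicates) until every class matches the largest class count.
Augmentation is applied after splitting, to training data only.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from skimage import transform as sktransform

from dermokit.synthetic import SyntheticSample

__all__ = [
    "AffineSpec",
    "SplitSpec",
    "apply_affine",
    "resize_for_backbone",
    "balance_classes",
    "split_train_val",
    "random_affine_spec",
]

_KINDS = ("rotation", "shift", "reflection", "scaling", "crop")


@dataclass(frozen=True)
class AffineSpec:
    """One affine transform: kind plus its parameter.

    rotation    angle in degrees (counter-clockwise)
    shift       (dy, dx) in pixels, edge fill
    reflection  axis: "horizontal" (left-right) or "vertical" (up-down)
    scaling     factor > 0; output re-cropped/padded to the input size
    crop        (y0, x0, y1, x1) box, half-open
    """

    kind: str
    angle: float = 0.0
    shift: Tuple[int, int] = (0, 0)
    axis: str = "horizontal"
    factor: float = 1.0
    box: Optional[Tuple[int, int, int, int]] = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown transform kind {self.kind!r}; choose from {_KINDS}")
        if self.kind == "scaling" and self.factor <= 0:
            raise ValueError("scaling factor must be > 0")
        if self.kind == "reflection" and self.axis not in ("horizontal", "vertical"):
            raise ValueError(f"unknown reflection axis {self.axis!r}")
        if self.kind == "crop" and self.box is None:
            raise ValueError("crop requires a box")


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation split parameters."""

    train_fraction: float = 0.8
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


def _warp(image: np.ndarray, fn) -> np.ndarray:
    """Apply a float-image warp and restore the uint8 range."""
    out = fn(image.astype(np.float64))
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def _center_fit(image: np.ndarray, target: Tuple[int, int]) -> np.ndarray:
    """Center-crop or edge-pad a (possibly multichannel) array to target."""
    H, W = image.shape[:2]
    th, tw = target
    # crop
    y0 = max(0, (H - th) // 2)
    x0 = max(0, (W - tw) // 2)
    out = image[y0 : y0 + th, x0 : x0 + tw]
    # pad
    ph, pw = th - out.shape[0], tw - out.shape[1]
    if ph > 0 or pw > 0:
        pads = [(ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2)]
        pads += [(0, 0)] * (image.ndim - 2)
        out = np.pad(out, pads, mode="edge")
    return out


def apply_affine(image: np.ndarray, spec: AffineSpec) -> np.ndarray:
    """Apply one affine transform to an H x W x C (or H x W) uint8 image.

    Deterministic; right-angle rotations and reflections are exact
    permutations of pixels.
    """
    image = np.asarray(image)
    if spec.kind == "rotation":
        angle = spec.angle % 360.0
        if angle == 0.0:
            return image.copy()
        if angle % 90.0 == 0.0:
            return np.ascontiguousarray(np.rot90(image, k=int(angle // 90)))
        return _warp(
            image,
            lambda im: sktransform.rotate(
                im, spec.angle, resize=True, mode="edge", order=1, preserve_range=True
            ),
        )
    if spec.kind == "shift":
        dy, dx = spec.shift
        if dy == 0 and dx == 0:
            return image.copy()
        H, W = image.shape[:2]
        ys = np.clip(np.arange(H) - dy, 0, H - 1)
        xs = np.clip(np.arange(W) - dx, 0, W - 1)
        return image[np.ix_(ys, xs)] if image.ndim == 2 else image[np.ix_(ys, xs)].copy()
    if spec.kind == "reflection":
        axis = 1 if spec.axis == "horizontal" else 0
        return np.ascontiguousarray(np.flip(image, axis=axis))
    if spec.kind == "scaling":
        if spec.factor == 1.0:
            return image.copy()
        target = image.shape[:2]
        scaled = _warp(
            image,
            lambda im: sktransform.rescale(
                im,
                spec.factor,
                channel_axis=2 if im.ndim == 3 else None,
                mode="edge",
                order=1,
                preserve_range=True,
                anti_aliasing=False,
            ),
        )
        return _center_fit(scaled, target)
    if spec.kind == "crop":
        y0, x0, y1, x1 = spec.box
        H, W = image.shape[:2]
        if not (0 <= y0 < y1 <= H and 0 <= x0 < x1 <= W):
            raise ValueError(f"crop box {spec.box} outside image of shape {(H, W)}")
        return image[y0:y1, x0:x1].copy()
    raise AssertionError(spec.kind)


def resize_for_backbone(image: np.ndarray, target: Tuple[int, int]) -> np.ndarray:
    """Bilinear resize to target (H, W), preserving the channel axis."""
    th, tw = target
    if th < 1 or tw < 1:
        raise ValueError("target size must be >= 1x1")
    image = np.asarray(image)
    out_shape = (th, tw) + image.shape[2:]
    out = sktransform.resize(
        image.astype(np.float64),
        out_shape,
        order=1,
        mode="edge",
        preserve_range=True,
        anti_aliasing=False,
    )
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def random_affine_spec(rng: np.random.Generator, image_shape: Tuple[int, int]) -> AffineSpec:
    """Draw a random augmentation spec from the documented default ranges:
    rotation +/-30 deg, shift +/-10%, scale 0.9-1.1, horizontal/vertical flip."""
    H, W = image_shape
    kind = rng.choice(["rotation", "shift", "reflection", "scaling"])
    if kind == "rotation":
        return AffineSpec("rotation", angle=float(rng.uniform(-30, 30)))
    if kind == "shift":
        return AffineSpec(
            "shift",
            shift=(
                int(rng.integers(-H // 10, H // 10 + 1)),
                int(rng.integers(-W // 10, W // 10 + 1)),
            ),
        )
    if kind == "reflection":
        return AffineSpec("reflection", axis=str(rng.choice(["horizontal", "vertical"])))
    return AffineSpec("scaling", factor=float(rng.uniform(0.9, 1.1)))


def _transform_sample(sample: SyntheticSample, spec: AffineSpec) -> SyntheticSample:
    new_img = apply_affine(sample.image, spec)
    mask8 = sample.hair_mask_truth.astype(np.uint8) * 255
    new_mask = apply_affine(mask8, spec) > 127
    return SyntheticSample(
        image=new_img,
        hair_mask_truth=new_mask,
        label=sample.label,
        metadata=sample.metadata,
    )


def balance_classes(samples: Sequence[SyntheticSample], seed: int = 0) -> List[SyntheticSample]:
    """Oversample minority classes with affine-transformed copies until
    every class count equals the maximum original count.

    Every original sample is preserved; added samples are never raw
    duplicates (non-identity transforms only).
    """
    by_class: dict = {}
    for s in samples:
        by_class.setdefault(s.label, []).append(s)
    if not by_class:
        return []
    for label, group in by_class.items():
        if not group:
            raise ValueError(f"class {label!r} has no samples")
    target = max(len(g) for g in by_class.values())
    rng = np.random.default_rng(seed)
    out = list(samples)
    for label in sorted(by_class):
        group = by_class[label]
        deficit = target - len(group)
        for i in range(deficit):
            base = group[int(rng.integers(0, len(group)))]
            spec = random_affine_spec(rng, base.image.shape[:2])
            # reroll identity-ish draws so added samples are transformed copies
            while (
                (spec.kind == "rotation" and abs(spec.angle) < 1e-9)
                or (spec.kind == "shift" and spec.shift == (0, 0))
                or (spec.kind == "scaling" and abs(spec.factor - 1.0) < 1e-3)
            ):
                spec = random_affine_spec(rng, base.image.shape[:2])
            out.append(_transform_sample(base, spec))
    return out


def split_train_val(
    samples: Sequence[SyntheticSample], spec: Optional[SplitSpec] = None
) -> Tuple[List[SyntheticSample], List[SyntheticSample]]:
    """Disjoint train/validation partition; stratified keeps the per-class
    train fraction within one sample of the target."""
    spec = spec or SplitSpec()
    rng = np.random.default_rng(spec.seed)
    samples = list(samples)
    if not spec.stratified:
        order = rng.permutation(len(samples))
        n_train = int(round(spec.train_fraction * len(samples)))
        train_idx = set(order[:n_train].tolist())
        train = [s for i, s in enumerate(samples) if i in train_idx]
        val = [s for i, s in enumerate(samples) if i not in train_idx]
        return train, val
    by_class: dict = {}
    for i, s in enumerate(samples):
        by_class.setdefault(s.label, []).append(i)
    train_idx: set = set()
    for label in sorted(by_class):
        idx = by_class[label]
        if len(idx) < 2:
            raise ValueError(f"class {label!r} has {len(idx)} sample(s); cannot stratify")
        order = rng.permutation(len(idx))
        n_train = int(round(spec.train_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train_idx.update(idx[j] for j in order[:n_train])
    train = [s for i, s in enumerate(samples) if i in train_idx]
    val = [s for i, s in enumerate(samples) if i not in train_idx]
    return train, val
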