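"""Geometric augmentation for balancing per-class training counts.

Differential counts in peripheral blood are strongly imbalanced, so the
minority classes are topped up with geometric transforms that do not alter
the class identity of a cell: horizontal flip, vertical flip, random
rotation in [-90, +90] degrees, random rescale in [0.8, 1.2], and random
compositions of these.  All transforms keep the canvas size — rotation and
rescale resample with bilinear interpolation and fill exposed canvas with
the per-channel median (which, in a smear crop, is the background color).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import transform as _sktransform

__all__ = [
    "ROTATION_RANGE",
    "SCALE_RANGE",
    "AugmentSpec",
    "AugmentRecord",
    "hflip",
    "vflip",
    "rotate",
    "rescale",
    "augment_to_balance",
]

ROTATION_RANGE = (-90.0, 90.0)
SCALE_RANGE = (0.8, 1.2)

_BASE_TRANSFORMS = ("hflip", "vflip", "rotate", "scale")


@dataclass(frozen=True)
class AugmentSpec:
    """What to generate: enabled transforms, per-class target count, seed."""

    target_per_class: int
    seed: int = 0
    enabled: tuple[str, ...] = ("hflip", "vflip", "rotate", "scale", "compose")

    def __post_init__(self):
        allowed = set(_BASE_TRANSFORMS) | {"compose"}
        bad = set(self.enabled) - allowed
        if bad:
            raise ValueError(f"unknown transforms: {sorted(bad)}")
        if self.target_per_class < 1:
            raise ValueError("target_per_class must be positive")


@dataclass(frozen=True)
class AugmentRecord:
    """Provenance of one augmented image: source index + transform chain."""

    source_index: int
    transforms: tuple[str, ...] = field(default=())


def hflip(image: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(image[:, ::-1])


def vflip(image: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(image[::-1])


def _channel_medians(image: np.ndarray) -> np.ndarray:
    return np.median(image.reshape(-1, image.shape[2]), axis=0)


def rotate(image: np.ndarray, angle: float) -> np.ndarray:
    """Rotate about the center, bilinear, canvas kept, background-median fill."""
    fills = _channel_medians(image)
    out = np.empty_like(image)
    for c in range(image.shape[2]):
        rotated = _sktransform.rotate(
            image[..., c].astype(np.float64),
            angle,
            resize=False,
            order=1,
            mode="constant",
            cval=float(fills[c]),
            preserve_range=True,
        )
        out[..., c] = np.clip(np.rint(rotated), 0, 255).astype(image.dtype)
    return out


def rescale(image: np.ndarray, factor: float) -> np.ndarray:
    """Rescale then center-crop (factor > 1) or center-pad (factor < 1)."""
    h, w = image.shape[:2]
    scaled = _sktransform.rescale(
        image.astype(np.float64),
        factor,
        order=1,
        mode="edge",
        channel_axis=2,
        preserve_range=True,
        anti_aliasing=factor < 1.0,
    )
    scaled = np.clip(np.rint(scaled), 0, 255).astype(image.dtype)
    sh, sw = scaled.shape[:2]
    fills = _channel_medians(image)
    out = np.empty_like(image)
    for c in range(image.shape[2]):
        out[..., c] = fills[c]
    # overlap of the scaled raster with the original canvas, both centered
    top = max((sh - h) // 2, 0)
    left = max((sw - w) // 2, 0)
    oh, ow = min(sh, h), min(sw, w)
    dst_top = max((h - sh) // 2, 0)
    dst_left = max((w - sw) // 2, 0)
    out[dst_top : dst_top + oh, dst_left : dst_left + ow] = scaled[
        top : top + oh, left : left + ow
    ]
    return out


def _apply_named(image: np.ndarray, name: str, rng: np.random.Generator) -> np.ndarray:
    if name == "hflip":
        return hflip(image)
    if name == "vflip":
        return vflip(image)
    if name == "rotate":
        return rotate(image, float(rng.uniform(*ROTATION_RANGE)))
    if name == "scale":
        return rescale(image, float(rng.uniform(*SCALE_RANGE)))
    raise ValueError(f"unknown transform {name!r}")


def augment_to_balance(images, labels, spec: AugmentSpec):
    """Top every class up to exactly ``spec.target_per_class`` images.

    Originals are retained verbatim.  For each synthetic image a source is
    drawn uniformly from the class's originals and a transform is drawn
    uniformly from the enabled set ("compose" applies two distinct base
    transforms in draw order).  Returns ``(images, labels, records)`` where
    ``records[i]`` is ``None`` for originals and an :class:`AugmentRecord`
    otherwise.  Fully seeded: a given spec reproduces byte-identical output.
    """
    labels = list(labels)
    images = list(images)
    if len(images) != len(labels):
        raise ValueError("images and labels differ in length")
    classes = sorted(set(labels))
    by_class = {c: [i for i, lab in enumerate(labels) if lab == c] for c in classes}
    for c, idxs in by_class.items():
        if not idxs:
            raise ValueError(f"class {c!r} has no images")
        if len(idxs) > spec.target_per_class:
            raise ValueError(
                f"class {c!r} already exceeds the target count {spec.target_per_class}"
            )
    rng = np.random.default_rng(spec.seed)
    out_images = list(images)
    out_labels = list(labels)
    records: list[AugmentRecord | None] = [None] * len(images)
    compose_pool = [t for t in spec.enabled if t != "compose"] or list(_BASE_TRANSFORMS)
    for c in classes:
        needed = spec.target_per_class - len(by_class[c])
        for _ in range(needed):
            src = int(rng.choice(by_class[c]))
            choice = spec.enabled[int(rng.integers(len(spec.enabled)))]
            if choice == "compose":
                k = min(2, len(compose_pool))
                chain = tuple(
                    rng.choice(compose_pool, size=k, replace=False).tolist()
                )
            else:
                chain = (choice,)
            img = np.asarray(images[src])
            for name in chain:
                img = _apply_named(img, name, rng)
            out_images.append(img)
            out_labels.append(c)
            records.append(AugmentRecord(source_index=src, transforms=chain))
    return out_images, out_labels, records
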