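"""Parametric generator of Giemsa-like single-cell smear crops.

The generator renders the ingredients a stained peripheral-blood crop
shows — a pale background, salmon/grayish-pink red-blood-cell disks, a
pink-violet cytoplasm blob, and a dark purple nucleus (single for
lymphocytes/monocytes, a chain of overlapping lobes for neutrophils and
eosinophils, the whole granule-covered cell for basophils) — plus mild
per-channel illumination cast and uniform pixel noise.  Because the
nucleus geometry is rasterized directly, every crop carries an *exact*
ground-truth mask, which removes any dependency on downloaded datasets
for testing the segmentation and feature pipeline.

The essential color contract, mirrored from real Giemsa chemistry, is that
the nucleus is markedly lower in the G channel than the cytoplasm: that is
what makes the CMYK magenta component high on the nucleus, the property
the soft-map segmenter exploits.  RBCs and background are rendered with
low saturation so the min(M, S) plane suppresses them.

A second factory, :func:`make_feature_dataset`, emits 51-dimensional
Gaussian class clusters with a controllable separation for exercising the
classifier in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage import draw as _skdraw

from .features import N_FEATURES

__all__ = [
    "WBC_CLASSES",
    "InvalidSpecError",
    "SyntheticSpec",
    "LabeledCrop",
    "make_crop",
    "make_dataset",
    "make_feature_dataset",
]

WBC_CLASSES = ("lymphocyte", "monocyte", "neutrophil", "eosinophil", "basophil")


class InvalidSpecError(ValueError):
    """The requested geometry cannot fit the canvas."""


# Stain palette (scaffolding, tunable): chosen so that in the soft map the
# nucleus is bright while cytoplasm, RBCs and background fall near zero.
NUCLEUS_COLOR = (95, 45, 135)
MONOCYTE_NUCLEUS_COLOR = (115, 75, 155)
CYTOPLASM_COLOR = (205, 185, 208)
EOSINOPHIL_CYTOPLASM_COLOR = (214, 188, 182)
BASOPHIL_CELL_COLOR = (85, 50, 130)
RBC_COLOR = (205, 168, 162)
BACKGROUND_COLOR = (235, 230, 225)
GRANULE_DARK = (60, 30, 100)
GRANULE_RED = (210, 152, 138)


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterization of one rendered crop."""

    wbc_class: str
    canvas: int = 128
    lobes: int = 1
    nucleus_radius: float = 24.0
    lobe_spacing: float = 16.0
    indent_fraction: float = 0.0  # monocyte kidney-bite depth
    nucleus_roughness: float = 0.03  # radial waviness amplitude of the outline
    nucleus_harmonics: tuple[int, ...] = (2, 3)
    cytoplasm_radius: float = 34.0
    nucleus_color: tuple[int, int, int] = NUCLEUS_COLOR
    cytoplasm_color: tuple[int, int, int] = CYTOPLASM_COLOR
    rbc_count: int = 6
    rbc_color: tuple[int, int, int] = RBC_COLOR
    background_color: tuple[int, int, int] = BACKGROUND_COLOR
    granules: str = "none"  # none | red | dark
    noise_level: int = 3
    cast_range: tuple[float, float] = (0.95, 1.05)
    seed: int = 0

    def __post_init__(self):
        if self.wbc_class not in WBC_CLASSES:
            raise InvalidSpecError(f"unknown class {self.wbc_class!r}")
        if self.nucleus_color[1] >= self.cytoplasm_color[1]:
            raise InvalidSpecError(
                "nucleus must be darker than cytoplasm in the G channel"
            )
        if self.cytoplasm_radius + 6 > self.canvas / 2:
            raise InvalidSpecError(
                f"cell radius {self.cytoplasm_radius} does not fit a "
                f"{self.canvas}px canvas"
            )
        if self.lobes < 1:
            raise InvalidSpecError("at least one nucleus lobe required")


@dataclass(frozen=True)
class LabeledCrop:
    image: np.ndarray  # (H, W, 3) uint8
    truth: np.ndarray  # boolean nucleus mask (basophil: whole cell)
    label: str
    spec: SyntheticSpec


def _ellipse_mask(shape, center, radii, rotation) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    rr, cc = _skdraw.ellipse(
        center[0], center[1], radii[0], radii[1], shape=shape, rotation=rotation
    )
    mask[rr, cc] = True
    return mask


def _bumpy_blob(shape, center, radii, rotation, roughness, harmonics, rng) -> np.ndarray:
    """Ellipse-like polygon with low-frequency radial waviness.

    Real nuclear and cell outlines are never perfectly convex; the waviness
    leaves small concavities that the convex hull closes, so the ROC region
    downstream is small but non-empty, as it is on real cells.
    """
    theta = np.linspace(0, 2 * math.pi, 96, endpoint=False)
    mod = np.ones_like(theta)
    for k in harmonics:
        mod += roughness * rng.uniform(0.5, 1.0) * np.sin(
            k * theta + rng.uniform(0, 2 * math.pi)
        )
    ry = radii[0] * mod
    rx = radii[1] * mod
    ys = center[0] + ry * np.sin(theta + rotation)
    xs = center[1] + rx * np.cos(theta + rotation)
    mask = np.zeros(shape, dtype=bool)
    rr, cc = _skdraw.polygon(ys, xs, shape=shape)
    mask[rr, cc] = True
    return mask


def _nucleus_mask(spec: SyntheticSpec, center, rng) -> np.ndarray:
    shape = (spec.canvas, spec.canvas)
    r = spec.nucleus_radius
    if spec.lobes == 1:
        ratio = rng.uniform(0.85, 1.0)
        mask = _bumpy_blob(
            shape, center, (r, r * ratio), rng.uniform(0, math.pi),
            spec.nucleus_roughness, spec.nucleus_harmonics, rng,
        )
        if spec.indent_fraction > 0:
            ang = rng.uniform(0, 2 * math.pi)
            bite_r = spec.indent_fraction * r
            bite_c = (center[0] + r * math.sin(ang), center[1] + r * math.cos(ang))
            bite = _ellipse_mask(shape, bite_c, (bite_r, bite_r), 0.0)
            mask &= ~bite
        return mask
    # multi-lobed: a chain of overlapping ellipses with random turning,
    # recentered so its centroid sits at the requested cell center
    pts = [(0.0, 0.0)]
    heading = rng.uniform(0, 2 * math.pi)
    for _ in range(spec.lobes - 1):
        heading += rng.uniform(-1.1, 1.1)
        d = spec.lobe_spacing * rng.uniform(0.9, 1.1)
        pts.append((pts[-1][0] + d * math.sin(heading), pts[-1][1] + d * math.cos(heading)))
    pts = np.asarray(pts)
    pts -= pts.mean(axis=0)
    mask = np.zeros(shape, dtype=bool)
    for py, px in pts:
        ratio = rng.uniform(0.8, 1.0)
        mask |= _ellipse_mask(
            shape,
            (center[0] + py, center[1] + px),
            (r, r * ratio),
            rng.uniform(0, math.pi),
        )
    return mask


def _jitter_color(color, rng, amount=6):
    return np.clip(np.asarray(color, float) + rng.uniform(-amount, amount, 3), 0, 255)


def make_crop(spec: SyntheticSpec) -> LabeledCrop:
    """Render one crop with its exact ground-truth nucleus mask."""
    rng = np.random.default_rng(spec.seed)
    n = spec.canvas
    img = np.empty((n, n, 3), dtype=np.float64)
    img[:] = _jitter_color(spec.background_color, rng, 4)

    center = (n / 2 + rng.uniform(-3, 3), n / 2 + rng.uniform(-3, 3))
    cell_r = spec.cytoplasm_radius

    # red blood cells, kept clear of the white cell so ground truth is exact
    rbc_base = np.asarray(spec.rbc_color, float)
    placed = 0
    for _ in range(60 * spec.rbc_count):
        if placed >= spec.rbc_count:
            break
        rr = rng.uniform(10, 15)
        cy, cx = rng.uniform(0, n), rng.uniform(0, n)
        if math.hypot(cy - center[0], cx - center[1]) < cell_r + rr + 2:
            continue
        disk = _ellipse_mask((n, n), (cy, cx), (rr, rr * rng.uniform(0.85, 1.0)),
                             rng.uniform(0, math.pi))
        img[disk] = np.clip(rbc_base + rng.uniform(-8, 8, 3), 0, 255)
        # paler RBC center (biconcave look)
        pale = _ellipse_mask((n, n), (cy, cx), (rr * 0.45, rr * 0.45), 0.0)
        img[pale] = np.clip(rbc_base + 18 + rng.uniform(-4, 4, 3), 0, 255)
        placed += 1

    # cytoplasm blob; the basophil cell outline is shaggy (protruding
    # granules), so its whole-cell boundary uses the nucleus waviness
    cyto_radii = (cell_r * rng.uniform(0.92, 1.02), cell_r * rng.uniform(0.92, 1.02))
    if spec.wbc_class == "basophil":
        cyto = _bumpy_blob(
            (n, n), center, cyto_radii, rng.uniform(0, math.pi),
            spec.nucleus_roughness, spec.nucleus_harmonics, rng,
        )
    else:
        cyto = _ellipse_mask((n, n), center, cyto_radii, rng.uniform(0, math.pi))
    img[cyto] = _jitter_color(spec.cytoplasm_color, rng)

    # nucleus
    nucleus = _nucleus_mask(spec, center, rng) & cyto if spec.wbc_class == "basophil" \
        else _nucleus_mask(spec, center, rng)
    img[nucleus] = _jitter_color(spec.nucleus_color, rng)

    # granules
    if spec.granules != "none":
        g_color = GRANULE_RED if spec.granules == "red" else GRANULE_DARK
        if spec.granules == "red":
            # keep granules clear of the nucleus so they never merge with it
            from scipy import ndimage as _ndi

            region = cyto & ~_ndi.binary_dilation(nucleus, iterations=4)
        else:
            region = nucleus
        ys, xs = np.nonzero(region)
        if ys.size:
            k = min(ys.size, int(0.04 * region.sum()) + 10)
            pick = rng.choice(ys.size, size=k, replace=False)
            for j in pick:
                dot = _ellipse_mask((n, n), (ys[j], xs[j]),
                                    (rng.uniform(1, 2),) * 2, 0.0)
                img[dot & region] = np.clip(
                    np.asarray(g_color, float) + rng.uniform(-10, 10, 3), 0, 255
                )

    # global illumination cast + pixel noise
    img *= rng.uniform(*spec.cast_range, size=3)
    img += rng.integers(-spec.noise_level, spec.noise_level + 1, size=img.shape)
    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    truth = cyto if spec.wbc_class == "basophil" else nucleus
    if not truth.any():
        raise InvalidSpecError("rendered nucleus is empty")
    return LabeledCrop(image=image, truth=truth, label=spec.wbc_class, spec=spec)


def random_spec(wbc_class: str, rng: np.random.Generator, canvas: int = 128) -> SyntheticSpec:
    """Draw one class-appropriate spec from the documented parameter ranges."""
    seed = int(rng.integers(2**31))
    common = dict(canvas=canvas, rbc_count=int(rng.integers(4, 9)), seed=seed)
    if wbc_class == "lymphocyte":
        r = rng.uniform(20, 26)
        return SyntheticSpec(
            wbc_class, lobes=1, nucleus_radius=r, cytoplasm_radius=r + rng.uniform(5, 9),
            **common,
        )
    if wbc_class == "monocyte":
        r = rng.uniform(24, 29)
        return SyntheticSpec(
            wbc_class, lobes=1, nucleus_radius=r, indent_fraction=rng.uniform(0.45, 0.65),
            cytoplasm_radius=r + rng.uniform(8, 12),
            nucleus_color=MONOCYTE_NUCLEUS_COLOR, **common,
        )
    if wbc_class == "neutrophil":
        return SyntheticSpec(
            wbc_class, lobes=int(rng.integers(3, 6)),
            nucleus_radius=(r := rng.uniform(9, 12)),
            lobe_spacing=r * rng.uniform(1.3, 1.6), cytoplasm_radius=rng.uniform(34, 38),
            **common,
        )
    if wbc_class == "eosinophil":
        return SyntheticSpec(
            wbc_class, lobes=2, nucleus_radius=(r := rng.uniform(11, 14)),
            lobe_spacing=r * rng.uniform(1.3, 1.6), cytoplasm_radius=rng.uniform(33, 37),
            cytoplasm_color=EOSINOPHIL_CYTOPLASM_COLOR, granules="red", **common,
        )
    if wbc_class == "basophil":
        r = rng.uniform(26, 30)
        return SyntheticSpec(
            wbc_class, lobes=1, nucleus_radius=r - 2, cytoplasm_radius=r,
            nucleus_color=BASOPHIL_CELL_COLOR,
            cytoplasm_color=tuple(min(c + 25, 255) for c in BASOPHIL_CELL_COLOR),
            granules="dark",
            nucleus_roughness=0.09, nucleus_harmonics=(5, 7, 9),
            **common,
        )
    raise InvalidSpecError(f"unknown class {wbc_class!r}")


def make_dataset(n_per_class: int, seed: int = 0) -> list[LabeledCrop]:
    """Exactly ``5 * n_per_class`` crops, class-balanced and reproducible."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    crops = []
    for wbc_class in WBC_CLASSES:
        for _ in range(n_per_class):
            crops.append(make_crop(random_spec(wbc_class, rng)))
    return crops


def make_feature_dataset(
    n_per_class: int, separation: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian 51-D class clusters with inter-mean distance
    ``separation * within_class_std``.

    Class means sit at the vertices of a regular simplex spanned by random
    orthonormal directions, centered on a plausible feature-space base
    point; samples are clipped into plausible ranges (shape entries into
    [0, 2], color ratios into [0, 3]).
    """
    if separation < 0:
        raise ValueError("separation must be nonnegative")
    rng = np.random.default_rng(seed)
    sigma = 0.05
    base = np.concatenate([np.full(3, 1.0), np.full(N_FEATURES - 3, 1.2)])
    q, _ = np.linalg.qr(rng.normal(size=(N_FEATURES, len(WBC_CLASSES))))
    means = base + (separation * sigma / math.sqrt(2.0)) * q.T  # (5, 51)
    X, y = [], []
    for i, wbc_class in enumerate(WBC_CLASSES):
        X.append(means[i] + sigma * rng.normal(size=(n_per_class, N_FEATURES)))
        y.extend([wbc_class] * n_per_class)
    X = np.vstack(X)
    X[:, :3] = np.clip(X[:, :3], 0.0, 2.0)
    X[:, 3:] = np.clip(X[:, 3:], 0.0, 3.0)
    return X, np.asarray(y)
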