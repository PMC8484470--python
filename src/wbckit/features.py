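"""Shape and color features of a segmented white blood cell.

The feature vector has exactly 51 entries in a fixed, documented order:

* 3 shape descriptors of the nucleus —
  ``solidity  = area(nucleus) / area(hull)``,
  ``convexity = perimeter(hull) / perimeter(nucleus)``,
  ``circularity = perimeter(nucleus)^2 / (4 pi area(nucleus))``;
* 48 color ratios — for each of the 12 canonical color planes
  (:data:`wbckit.colorspaces.CHANNEL_NAMES`), the four ratios
  ``mean(nucleus)/mean(hull)``, ``std(nucleus)/std(hull)``,
  ``mean(ROC)/mean(hull)``, ``std(ROC)/std(hull)``.

Measurement conventions, fixed for reproducibility:

* area is the pixel count of a mask;
* perimeter is the length of the traced outer contour polygon through
  boundary *pixel centers* (Moore neighbor tracing; steps of 1 or sqrt 2),
  summed over 8-connected components — a 10x10 filled square measures 36;
* region statistics are population statistics (divide by n, not n - 1);
* a hull statistic below 1e-6 zeroes the ratio, and an empty ROC (perfectly
  convex nucleus) zeroes ratios 3 and 4: a convex nucleus genuinely has no
  cytoplasm-proxy signal, and the vector must stay finite for the SVM.

Color features are measured on the ORIGINAL crop, not the color-balanced
one: balancing is part of segmentation only, and raw stain color carries
class information (e.g. eosinophil granules) that balancing would dampen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage import measure as _skmeasure

from .colorspaces import CHANNEL_NAMES, feature_channels
from .cytoplasm import CellRegions, EmptyRegionError
from .nucleus import segment_nucleus

__all__ = [
    "RegionTooSmallError",
    "ExtractionFailedError",
    "ShapeMeasure",
    "RegionStats",
    "FEATURE_NAMES",
    "N_FEATURES",
    "traced_perimeter",
    "shape_measures",
    "shape_features",
    "region_stats",
    "color_features",
    "extract_features",
]

#: Smallest nucleus (in pixels) for which shape measures are meaningful.
MIN_REGION_AREA = 16

#: Hull statistics below this are treated as zero denominators.
STAT_EPS = 1e-6

RATIO_NAMES = (
    "mean_nuc_over_hull",
    "std_nuc_over_hull",
    "mean_roc_over_hull",
    "std_roc_over_hull",
)

SHAPE_FEATURE_NAMES = ("solidity", "convexity", "circularity")

#: Fixed order of the 51 features: 3 shape entries, then for each canonical
#: channel the 4 ratios in :data:`RATIO_NAMES` order.
FEATURE_NAMES: tuple[str, ...] = SHAPE_FEATURE_NAMES + tuple(
    f"{ch}_{ratio}" for ch in CHANNEL_NAMES for ratio in RATIO_NAMES
)

N_FEATURES = len(FEATURE_NAMES)  # 51


class RegionTooSmallError(ValueError):
    """Nucleus below the minimum measurable area."""


class ExtractionFailedError(RuntimeError):
    """Feature extraction failed (typically: empty nucleus segmentation)."""


# ---------------------------------------------------------------------------
# perimeter estimator: Moore-neighbor outer contour tracing
# ---------------------------------------------------------------------------

# 8 neighbor offsets in clockwise order starting due west.
_DIRS = ((0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1))
_DIR_INDEX = {d: i for i, d in enumerate(_DIRS)}


def _trace_component_length(mask: np.ndarray) -> float:
    """Closed outer-boundary path length of one padded component."""
    rows, cols = np.nonzero(mask)
    start = (int(rows[0]), int(cols[0]))  # topmost, then leftmost
    if len(rows) == 1:
        return 0.0
    current = start
    back = (start[0], start[1] - 1)  # west neighbor of start is background
    first_move = None
    length = 0.0
    max_steps = 4 * len(rows) + 8
    for _ in range(max_steps):
        db = _DIR_INDEX[(back[0] - current[0], back[1] - current[1])]
        nxt = None
        for k in range(1, 9):
            dy, dx = _DIRS[(db + k) % 8]
            cand = (current[0] + dy, current[1] + dx)
            if mask[cand]:
                nxt = cand
                break
            back = cand
        if nxt is None:  # isolated pixel (cannot happen for len > 1)
            return 0.0
        move = (current, nxt)
        if first_move is None:
            first_move = move
        elif move == first_move:
            break
        length += math.hypot(nxt[0] - current[0], nxt[1] - current[1])
        current = nxt
    return length


def traced_perimeter(mask) -> float:
    """Perimeter of a mask: summed traced outer contours of its components."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return 0.0
    labels = _skmeasure.label(m, connectivity=2)
    total = 0.0
    for region in _skmeasure.regionprops(labels):
        r0, c0, r1, c1 = region.bbox
        comp = np.zeros((r1 - r0 + 2, c1 - c0 + 2), dtype=bool)
        comp[1:-1, 1:-1] = labels[r0:r1, c0:c1] == region.label
        total += _trace_component_length(comp)
    return total


# ---------------------------------------------------------------------------
# shape features
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShapeMeasure:
    area_nucleus: float
    perimeter_nucleus: float
    area_hull: float
    perimeter_hull: float


def shape_measures(regions: CellRegions) -> ShapeMeasure:
    """Areas (pixel counts) and traced perimeters of nucleus and hull."""
    area_n = int(np.count_nonzero(regions.nucleus))
    if area_n == 0:
        raise EmptyRegionError("cannot measure an empty nucleus")
    if area_n < MIN_REGION_AREA:
        raise RegionTooSmallError(
            f"nucleus area {area_n} px is below the minimum {MIN_REGION_AREA}"
        )
    return ShapeMeasure(
        area_nucleus=float(area_n),
        perimeter_nucleus=traced_perimeter(regions.nucleus),
        area_hull=float(np.count_nonzero(regions.hull)),
        perimeter_hull=traced_perimeter(regions.hull),
    )


def shape_features(m: ShapeMeasure) -> tuple[float, float, float]:
    """(solidity, convexity, circularity) from a ShapeMeasure."""
    solidity = m.area_nucleus / m.area_hull
    convexity = m.perimeter_hull / m.perimeter_nucleus
    circularity = m.perimeter_nucleus**2 / (4.0 * math.pi * m.area_nucleus)
    return solidity, convexity, circularity


# ---------------------------------------------------------------------------
# color features
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionStats:
    """Population mean/std of one color plane over the three cell regions.

    ``mean_roc``/``std_roc`` are ``None`` when the ROC is empty
    (``roc_defined`` is False).
    """

    mean_nucleus: float
    std_nucleus: float
    mean_hull: float
    std_hull: float
    mean_roc: float | None
    std_roc: float | None
    roc_defined: bool


def region_stats(plane, regions: CellRegions) -> RegionStats:
    p = np.asarray(plane, dtype=np.float64)
    nuc = p[regions.nucleus]
    hull = p[regions.hull]
    if nuc.size == 0 or hull.size == 0:
        raise EmptyRegionError("region statistics need a non-empty nucleus and hull")
    roc = p[regions.roc]
    roc_defined = roc.size > 0
    return RegionStats(
        mean_nucleus=float(nuc.mean()),
        std_nucleus=float(nuc.std()),
        mean_hull=float(hull.mean()),
        std_hull=float(hull.std()),
        mean_roc=float(roc.mean()) if roc_defined else None,
        std_roc=float(roc.std()) if roc_defined else None,
        roc_defined=roc_defined,
    )


def _ratio(num: float | None, den: float) -> float:
    if num is None or den < STAT_EPS:
        return 0.0
    return num / den


def color_features(stack: dict[str, np.ndarray], regions: CellRegions) -> np.ndarray:
    """The 48 color ratios, channel-major in canonical channel order."""
    out = np.empty(4 * len(CHANNEL_NAMES))
    for i, name in enumerate(CHANNEL_NAMES):
        st = region_stats(stack[name], regions)
        out[4 * i + 0] = _ratio(st.mean_nucleus, st.mean_hull)
        out[4 * i + 1] = _ratio(st.std_nucleus, st.std_hull)
        out[4 * i + 2] = _ratio(st.mean_roc, st.mean_hull)
        out[4 * i + 3] = _ratio(st.std_roc, st.std_hull)
    return out


# ---------------------------------------------------------------------------
# end-to-end extraction
# ---------------------------------------------------------------------------

def extract_features(
    image,
    keep_all_components: bool = False,
    image_id: str | None = None,
) -> np.ndarray:
    """Segment a crop and return its 51-entry feature vector.

    Raises :class:`ExtractionFailedError` (naming ``image_id`` if given)
    when segmentation produces an empty or too-small nucleus.
    """
    nucleus_mask = segment_nucleus(image, keep_all_components=keep_all_components)
    name = image_id if image_id is not None else "<image>"
    if not nucleus_mask.any():
        raise ExtractionFailedError(f"empty nucleus segmentation for {name}")
    try:
        regions = CellRegions.from_nucleus(nucleus_mask)
        measures = shape_measures(regions)
    except (EmptyRegionError, RegionTooSmallError) as exc:
        raise ExtractionFailedError(f"feature extraction failed for {name}: {exc}")
    stack = feature_channels(image)
    vec = np.concatenate([np.asarray(shape_features(measures)), color_features(stack, regions)])
    assert vec.shape == (N_FEATURES,)
    return vec
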