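"""Nucleus segmentation from a single-cell smear crop.

The segmenter is training-free.  It builds a single-channel *soft map* in
which nucleus pixels are bright and everything else (red blood cells,
cytoplasm, background) is driven toward zero, thresholds it with Otsu's
method, and cleans the binary result into one nucleus mask:

1. color-balance the crop (:func:`wbckit.colorspaces.balance_colors`);
2. ``KM = clip(K - M, 0, 1)`` — high on RBCs/cytoplasm, ~0 on the nucleus;
3. ``MS = min(M, S)`` — high on the nucleus, ~0 on RBCs and background;
4. soft map ``= clip(MS - KM, 0, 1)``;
5. Otsu threshold over a 256-bin histogram of the map;
6. hole filling, small-component removal, and selection of the component
   closest to the crop center.

Negative values of the two subtractions are clipped at zero: a negative
difference carries no nucleus evidence, and clipping keeps the map a
nonnegative evidence image on which Otsu is well posed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import measure as _skmeasure

from .colorspaces import balance_colors, cmyk_planes, hls_saturation

__all__ = [
    "SoftMap",
    "DegenerateSoftMapError",
    "soft_map",
    "otsu_threshold",
    "binarize",
    "postprocess",
    "segment_nucleus",
]

logger = logging.getLogger(__name__)

#: Number of histogram bins used by the Otsu search (8-bit convention).
OTSU_BINS = 256

#: Connected components smaller than this fraction of the image area are
#: discarded during post-processing.
MIN_COMPONENT_FRACTION = 0.01


class DegenerateSoftMapError(ValueError):
    """The soft map occupies a single histogram bin; no threshold exists."""


@dataclass(frozen=True)
class SoftMap:
    """Nucleus evidence map plus its two intermediate planes.

    Attributes
    ----------
    values : float64 array in [0, 1], ``clip(ms - km, 0, 1)``
    km : float64 array, ``clip(K - M, 0, 1)`` (RBC/cytoplasm evidence)
    ms : float64 array, ``min(M, S)`` (nucleus evidence)
    """

    values: np.ndarray
    km: np.ndarray
    ms: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def soft_map(image) -> SoftMap:
    """Compute the nucleus soft map of an RGB cell crop."""
    balanced = balance_colors(image)
    k, m = cmyk_planes(balanced)
    s = hls_saturation(balanced)
    km = np.clip(k - m, 0.0, 1.0)
    ms = np.minimum(m, s)
    values = np.clip(ms - km, 0.0, 1.0)
    return SoftMap(values=values, km=km, ms=ms)


def _quantize(values: np.ndarray) -> np.ndarray:
    """Map unit-interval values to bin indices 0..255 (value 1.0 -> 255)."""
    v = np.clip(np.asarray(values, dtype=np.float64), 0.0, 1.0)
    return np.minimum((v * OTSU_BINS).astype(np.int64), OTSU_BINS - 1)


def otsu_threshold(values) -> float:
    """Otsu's threshold of a unit-interval map over 256 uniform bins.

    Scans every candidate split ``t`` (bins <= t vs > t), maximizing the
    between-class variance ``w0 * w1 * (mu0 - mu1)^2``; ties are broken by
    the lowest qualifying split.  Returns the bin edge ``(t + 1) / 256``;
    foreground pixels are those *strictly above* the returned edge.

    Raises
    ------
    DegenerateSoftMapError
        If all values fall into one bin (e.g. a constant map).
    """
    idx = _quantize(values)
    hist = np.bincount(idx.ravel(), minlength=OTSU_BINS).astype(np.float64)
    if np.count_nonzero(hist) <= 1:
        raise DegenerateSoftMapError("soft map occupies a single bin")
    p = hist / hist.sum()
    centers = (np.arange(OTSU_BINS) + 0.5) / OTSU_BINS
    w0 = np.cumsum(p)
    mu = np.cumsum(p * centers)
    mu_total = mu[-1]
    w1 = 1.0 - w0
    valid = (w0 > 0) & (w1 > 0)
    bcv = np.zeros(OTSU_BINS)
    bcv[valid] = (mu_total * w0[valid] - mu[valid]) ** 2 / (w0[valid] * w1[valid])
    t = int(np.argmax(bcv))  # argmax returns the first (lowest) maximizer
    return (t + 1) / OTSU_BINS


def binarize(values, threshold: float) -> np.ndarray:
    """Boolean foreground mask: pixels strictly above *threshold*."""
    return np.asarray(values, dtype=np.float64) > threshold


def postprocess(raw, keep_all_components: bool = False) -> np.ndarray:
    """Clean a raw thresholded mask into the final nucleus mask.

    Fills interior holes, drops connected components smaller than 1% of the
    image area, and — because the input is a single-cell crop whose target
    cell sits centrally — keeps the surviving component whose centroid is
    nearest the image center.  ``keep_all_components=True`` instead retains
    every surviving component (useful for heavily lobed nuclei whose lobes
    disconnect).  An empty input yields an empty output.
    """
    mask = np.asarray(raw, dtype=bool)
    if not mask.any():
        return np.zeros_like(mask)
    filled = ndi.binary_fill_holes(mask)
    labels = _skmeasure.label(filled, connectivity=2)
    min_area = MIN_COMPONENT_FRACTION * mask.size
    regions = [r for r in _skmeasure.regionprops(labels) if r.area >= min_area]
    if not regions:
        return np.zeros_like(mask)
    if keep_all_components:
        keep = {r.label for r in regions}
        return np.isin(labels, list(keep))
    center = ((mask.shape[0] - 1) / 2.0, (mask.shape[1] - 1) / 2.0)
    best = min(
        regions,
        key=lambda r: (
            (r.centroid[0] - center[0]) ** 2 + (r.centroid[1] - center[1]) ** 2,
            r.label,
        ),
    )
    return labels == best.label


def segment_nucleus(image, keep_all_components: bool = False) -> np.ndarray:
    """Segment the nucleus of a single-cell crop; returns a boolean mask.

    Deterministic composition of :func:`soft_map`, :func:`otsu_threshold`
    and :func:`postprocess`.  A degenerate soft map (no contrast at all,
    e.g. a blank image) produces an empty mask with a logged warning.
    """
    sm = soft_map(image)
    try:
        thr = otsu_threshold(sm.values)
    except DegenerateSoftMapError:
        logger.warning("degenerate soft map: returning an empty nucleus mask")
        return np.zeros(sm.shape, dtype=bool)
    return postprocess(binarize(sm.values, thr), keep_all_components=keep_all_components)
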