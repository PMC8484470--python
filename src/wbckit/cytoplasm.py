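"""Cytoplasm proxy via the convex hull of the nucleus.

Segmenting the cytoplasm boundary of a leukocyte is hard and error-prone;
this package sidesteps it.  The convex hull of the nucleus mask is
computed, and the pixels inside the hull but outside the nucleus form the
*representative of the cytoplasm* (ROC).  The less convex the nucleus, the
larger the ROC: a round lymphocyte nucleus yields almost none, while the
lobed nucleus of a neutrophil traps substantial inter-lobe cytoplasm.  The
hull is taken over the union of all nucleus pixels (not per component) so
that disconnected lobes contribute the cytoplasm between them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import morphology as _skmorph

__all__ = [
    "EmptyRegionError",
    "InconsistentRegionsError",
    "CellRegions",
    "convex_hull_mask",
    "roc_mask",
]


class EmptyRegionError(ValueError):
    """Raised when an operation requires a non-empty mask."""


class InconsistentRegionsError(ValueError):
    """Raised when a nucleus mask is not contained in its hull mask."""


def convex_hull_mask(nucleus) -> np.ndarray:
    """Filled convex hull of a non-empty nucleus mask.

    A pixel belongs to the hull if its center lies inside or on the convex
    polygon of the nucleus pixel set; the result always contains the input.
    """
    mask = np.asarray(nucleus, dtype=bool)
    if not mask.any():
        raise EmptyRegionError("cannot take the convex hull of an empty mask")
    # pixel-center rasterization: a pixel is in the hull iff its center lies
    # inside or on the convex polygon of the nucleus pixel centers
    hull = _skmorph.convex_hull_image(mask, offset_coordinates=False)
    # rasterization safety: the hull must cover the input pixel set
    return hull | mask


def roc_mask(nucleus, hull) -> np.ndarray:
    """Pixels inside the hull but outside the nucleus (may be empty)."""
    n = np.asarray(nucleus, dtype=bool)
    h = np.asarray(hull, dtype=bool)
    if n.shape != h.shape:
        raise InconsistentRegionsError("nucleus and hull shapes differ")
    if np.any(n & ~h):
        raise InconsistentRegionsError("nucleus mask is not a subset of the hull")
    return h & ~n


@dataclass(frozen=True)
class CellRegions:
    """Nucleus mask, its convex hull, and the ROC (hull minus nucleus)."""

    nucleus: np.ndarray
    hull: np.ndarray
    roc: np.ndarray

    @classmethod
    def from_nucleus(cls, nucleus) -> "CellRegions":
        """Build all three regions from a non-empty nucleus mask."""
        n = np.asarray(nucleus, dtype=bool)
        hull = convex_hull_mask(n)
        return cls(nucleus=n, hull=hull, roc=roc_mask(n, hull))

    def __post_init__(self):
        if np.any(self.nucleus & ~self.hull):
            raise InconsistentRegionsError("nucleus exceeds hull")
        if np.any(self.roc & self.nucleus):
            raise InconsistentRegionsError("ROC overlaps nucleus")
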