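"""Raster and table I/O for the command-line pipeline.

Images are 8-bit RGB rasters (PNG/JPEG/TIFF/BMP); masks are 8-bit
single-channel PNGs where any nonzero value means membership and writes
emit {0, 255}.  Feature tables are CSV with the documented 51-column
feature order; a fingerprint of that order travels with saved models so
column permutations are caught at load time.  Images are never resized:
every stage runs at the input's native resolution.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .colorspaces import as_rgb_array
from .features import FEATURE_NAMES

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "feature_frame",
    "write_features_csv",
    "read_features_csv",
]

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = [f"f{i + 1:02d}" for i in range(len(FEATURE_NAMES))]


def read_image(path) -> np.ndarray:
    """Load an 8-bit RGB image; alpha channels are stripped with a warning."""
    with Image.open(path) as im:
        if im.mode in ("RGBA", "LA", "PA"):
            logger.warning("%s: alpha channel stripped", path)
        if im.mode != "RGB":
            im = im.convert("RGB")
        arr = np.asarray(im, dtype=np.uint8)
    return as_rgb_array(arr)


def write_image(image, path) -> None:
    Image.fromarray(as_rgb_array(image), mode="RGB").save(path)


def read_mask(path) -> np.ndarray:
    """Load a binary mask PNG: nonzero means member.

    Multi-channel mask files are collapsed with any-nonzero (warned).
    """
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim == 3:
        logger.warning("%s: multi-channel mask collapsed by any-nonzero", path)
        return arr.any(axis=2)
    return arr != 0


def write_mask(mask, path) -> None:
    """Write a boolean mask as an 8-bit {0, 255} PNG (lossless round-trip)."""
    arr = (np.asarray(mask, dtype=bool).astype(np.uint8)) * 255
    Image.fromarray(arr, mode="L").save(path)


def feature_frame(ids, vectors, labels=None) -> pd.DataFrame:
    """Assemble a feature table: image id, optional label, f01..f51."""
    X = np.atleast_2d(np.asarray(vectors, dtype=np.float64))
    if X.shape[1] != len(FEATURE_COLUMNS):
        raise ValueError(f"expected {len(FEATURE_COLUMNS)} features, got {X.shape[1]}")
    frame = pd.DataFrame(X, columns=FEATURE_COLUMNS)
    frame.insert(0, "image", list(ids))
    if labels is not None:
        frame.insert(1, "label", list(labels))
    return frame


def write_features_csv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def read_features_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in FEATURE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"feature CSV {path} lacks columns {missing[:3]}...")
    return frame


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
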