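"""Color balancing and color-plane computations for stained smear crops.

Giemsa-type stains render the leukocyte nucleus dark purple, the cytoplasm
pale pink-violet, red blood cells salmon, and the background near-white.
The segmentation strategy downstream leans on the fact that, in a
color-balanced image, the nucleus is *bright* in the CMYK magenta plane and
in HLS saturation while red blood cells and background are not.  This
module provides:

* :func:`balance_colors` — per-channel gain correction that equalizes the
  R, G, B channel means to the grayscale mean, removing global stain casts;
* :func:`cmyk_planes` / :func:`hls_saturation` — the K, M and S planes used
  to build the nucleus soft map;
* :func:`feature_channels` — the 12 canonical color planes
  (RGB, HSV, LAB, YCrCb) from which color features are measured.

All derived planes are float64 on the unit interval [0, 1] so that the
plane arithmetic in :mod:`wbckit.nucleus` happens on one common scale.
"""

from __future__ import annotations

import numpy as np
from skimage import color as _skcolor

__all__ = [
    "InvalidImageError",
    "CHANNEL_NAMES",
    "LUMA_WEIGHTS",
    "as_rgb_array",
    "grayscale",
    "balance_colors",
    "cmyk_planes",
    "hls_saturation",
    "feature_channels",
]

#: ITU-R BT.601 luma weights; also used as the "grayscale" of the
#: color-balancing step.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

#: Canonical, fixed order of the 12 feature planes.
CHANNEL_NAMES = (
    "R", "G", "B",
    "H", "S_hsv", "V",
    "L_lab", "a_lab", "b_lab",
    "Y", "Cr", "Cb",
)

#: Minimum accepted height/width of an input crop.
MIN_IMAGE_SIDE = 8


class InvalidImageError(ValueError):
    """Raised when an input raster is not a valid 8-bit RGB cell crop."""


def as_rgb_array(image) -> np.ndarray:
    """Validate and return *image* as an (H, W, 3) uint8 array.

    Accepts any array-like whose values are integers in [0, 255].  Images
    smaller than 8 pixels on either side are rejected: they cannot hold a
    measurable cell.
    """
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise InvalidImageError(
            f"expected an (H, W, 3) RGB raster, got shape {arr.shape}"
        )
    if arr.shape[0] < MIN_IMAGE_SIDE or arr.shape[1] < MIN_IMAGE_SIDE:
        raise InvalidImageError(
            f"image {arr.shape[0]}x{arr.shape[1]} is below the minimum "
            f"{MIN_IMAGE_SIDE}x{MIN_IMAGE_SIDE} crop size"
        )
    if arr.dtype != np.uint8:
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise InvalidImageError("channel values must be integer-valued")
        if arr.min() < 0 or arr.max() > 255:
            raise InvalidImageError("channel values must lie in [0, 255]")
        arr = arr.astype(np.uint8)
    return arr


def grayscale(image) -> np.ndarray:
    """Luma-weighted grayscale plane, float64 on the 8-bit scale [0, 255]."""
    arr = as_rgb_array(image).astype(np.float64)
    wr, wg, wb = LUMA_WEIGHTS
    return wr * arr[..., 0] + wg * arr[..., 1] + wb * arr[..., 2]


def balance_colors(image) -> np.ndarray:
    """Equalize the R, G, B channel means to the grayscale mean.

    Each channel is multiplied by ``mean(grayscale) / mean(channel)``, then
    rounded and clipped back into [0, 255].  A channel whose mean is zero is
    returned unchanged (no gain is defined for it).  The transform removes
    the global color cast that staining and illumination impose, so that
    the CMYK/HLS planes computed afterwards are comparable across smears.
    """
    arr = as_rgb_array(image)
    out = arr.astype(np.float64)
    target = grayscale(arr).mean()
    for c in range(3):
        m = out[..., c].mean()
        if m > 0:
            out[..., c] *= target / m
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def cmyk_planes(image) -> tuple[np.ndarray, np.ndarray]:
    """K (black) and M (magenta) planes of the naive CMYK transform.

    With unit-scaled channels R', G', B':

    * ``K = 1 - max(R', G', B')``
    * ``M = (1 - G' - K) / (1 - K)`` where ``K < 1``, and ``M = 0`` where
      ``K = 1`` (a pure-black pixel carries no magenta evidence).

    Returns ``(K, M)`` as float64 planes in [0, 1].
    """
    arr = as_rgb_array(image).astype(np.float64) / 255.0
    mx = arr.max(axis=2)
    k = 1.0 - mx
    g = arr[..., 1]
    m = np.zeros_like(k)
    nonblack = k < 1.0
    m[nonblack] = (1.0 - g[nonblack] - k[nonblack]) / (1.0 - k[nonblack])
    return k, np.clip(m, 0.0, 1.0)


def hls_saturation(image) -> np.ndarray:
    """S plane of the standard HSL/HLS color model, float64 in [0, 1].

    With mx = max(R', G', B'), mn = min and lightness L = (mx + mn) / 2:
    S = 0 where mx = mn, else (mx - mn) / (1 - |2L - 1|).
    """
    arr = as_rgb_array(image).astype(np.float64) / 255.0
    mx = arr.max(axis=2)
    mn = arr.min(axis=2)
    ell = (mx + mn) / 2.0
    denom = 1.0 - np.abs(2.0 * ell - 1.0)
    s = np.zeros_like(mx)
    chroma = mx > mn
    s[chroma] = (mx[chroma] - mn[chroma]) / denom[chroma]
    return np.clip(s, 0.0, 1.0)


def _ycrcb_planes(arr01: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    # BT.601 full-range: Y on [0,1]; Cr, Cb centered at 0.5.
    r, g, b = arr01[..., 0], arr01[..., 1], arr01[..., 2]
    y = 0.299 * r + 0.587 * g + 0.114 * b
    cr = (r - y) * 0.713 + 0.5
    cb = (b - y) * 0.564 + 0.5
    return y, cr, cb


def feature_channels(image) -> dict[str, np.ndarray]:
    """The 12 canonical color planes, each float64 in [0, 1].

    Order and scaling (fixed; see :data:`CHANNEL_NAMES`):

    * R, G, B — channels / 255
    * H, S_hsv, V — HSV with hue rescaled from [0°, 360°) to [0, 1)
    * L_lab, a_lab, b_lab — CIE LAB under D65, with the 8-bit convention
      L*/100, (a* + 128)/255, (b* + 128)/255
    * Y, Cr, Cb — ITU-R BT.601 full-range, Cr/Cb offset to center at 0.5
    """
    arr = as_rgb_array(image).astype(np.float64) / 255.0
    hsv = _skcolor.rgb2hsv(arr)
    lab = _skcolor.rgb2lab(arr)  # D65 / 2deg observer
    y, cr, cb = _ycrcb_planes(arr)
    planes = {
        "R": arr[..., 0],
        "G": arr[..., 1],
        "B": arr[..., 2],
        "H": hsv[..., 0],
        "S_hsv": hsv[..., 1],
        "V": hsv[..., 2],
        "L_lab": lab[..., 0] / 100.0,
        "a_lab": (lab[..., 1] + 128.0) / 255.0,
        "b_lab": (lab[..., 2] + 128.0) / 255.0,
        "Y": y,
        "Cr": cr,
        "Cb": cb,
    }
    return {name: np.clip(planes[name], 0.0, 1.0) for name in CHANNEL_NAMES}
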