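"""Image preparation: grayscale conversion, CLAHE, and median filtering.

All routines operate on and return 8-bit rasters so that downstream
quantization sees the full [0, 255] intensity scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from skimage import exposure

__all__ = [
    "FundusImage",
    "to_grayscale",
    "clahe",
    "median_filter",
]

#: ITU-R BT.601 luma weights (R, G, B).
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass
class FundusImage:
    """An 8-bit RGB fundus photograph with its group label.

    Attributes
    ----------
    pixels : ndarray of uint8, shape (H, W, 3)
        Raw image data.
    group : str
        Cohort label (e.g. ``"healthy"``).
    id : str
        Image identifier, used in reports and file names.
    fov_mask : ndarray of bool, shape (H, W), optional
        Mask of the circular imaged field; ``None`` if unknown.
    """

    pixels: np.ndarray
    group: str = ""
    id: str = ""
    fov_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected an (H, W, 3) raster, got shape {px.shape}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("pixel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


def _as_gray_array(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale raster, got shape {arr.shape}")
    return arr


def to_grayscale(img: FundusImage | np.ndarray) -> np.ndarray:
    """Convert an RGB image to 8-bit grayscale using BT.601 luma.

    Each pixel maps to ``0.299 R + 0.587 G + 0.114 B``, rounded half-up
    and clipped to [0, 255].

    Parameters
    ----------
    img : FundusImage or ndarray of shape (H, W, 3)

    Returns
    -------
    ndarray of uint8, shape (H, W)
    """
    px = img.pixels if isinstance(img, FundusImage) else np.asarray(img)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) raster, got shape {px.shape}")
    luma = px.astype(np.float64) @ np.asarray(LUMA_WEIGHTS)
    # round half-up, not banker's rounding
    return np.clip(np.floor(luma + 0.5), 0, 255).astype(np.uint8)


def clahe(
    img: np.ndarray,
    tiles: tuple[int, int] = (8, 8),
    clip_limit: float = 0.01,
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on an 8-bit image.

    Per-tile histogram equalization with clipped histograms and bilinear
    interpolation of the tile mappings.

    Parameters
    ----------
    img : ndarray of uint8, shape (H, W)
    tiles : (rows, cols)
        Tile grid; each must be >= 2.
    clip_limit : float in (0, 1]
        Clipping limit as a fraction of tile pixel count.

    Returns
    -------
    ndarray of uint8, same shape, values in [0, 255].
    """
    arr = _as_gray_array(img)
    rows, cols = tiles
    if rows < 2 or cols < 2:
        raise ValueError("tile grid must be at least 2x2")
    if not 0 < clip_limit <= 1:
        raise ValueError("clip_limit must lie in (0, 1]")
    h, w = arr.shape
    if h < rows or w < cols:
        raise ValueError(f"image {arr.shape} smaller than tile grid {tiles}")
    if arr.min() == arr.max():
        # no contrast to redistribute
        return arr.astype(np.uint8).copy()
    kernel = (max(1, h // rows), max(1, w // cols))
    out = exposure.equalize_adapthist(
        arr.astype(np.uint8), kernel_size=kernel, clip_limit=clip_limit
    )
    return np.clip(np.floor(out * 255.0 + 0.5), 0, 255).astype(np.uint8)


def median_filter(img: np.ndarray, k: int = 3) -> np.ndarray:
    """k-by-k median filter with reflection padding at the borders.

    Parameters
    ----------
    img : ndarray of uint8, shape (H, W)
    k : int
        Odd window size, >= 3.
    """
    arr = _as_gray_array(img)
    if k % 2 == 0 or k < 3:
        raise ValueError("window size k must be odd and >= 3")
    return ndi.median_filter(arr, size=k, mode="reflect")
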