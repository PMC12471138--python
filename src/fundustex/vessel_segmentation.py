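"""Vessel segmentation: oriented matched filtering plus iterative
(isodata) thresholding, with Dice validation against ground truth.

The matched filter bank uses zero-mean kernels with a Gaussian
cross-profile, rotated over ``n_orientations`` directions spanning 180
degrees; the pixel-wise maximum response over orientations is
thresholded by an iterative foreground/background class-mean update.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi

from .preprocess import FundusImage, clahe, median_filter

__all__ = [
    "MatchedFilterParams",
    "ThresholdResult",
    "matched_filter_response",
    "isodata_threshold",
    "estimate_fov",
    "segment_vessels",
    "dice_coefficient",
]

#: Area of the reference high-resolution fundus images used to scale the
#: small-component cutoff to other image sizes.
REFERENCE_AREA = 3504 * 2336

#: Small-component cutoff (pixels) at the reference image size.
MIN_COMPONENT_REFERENCE = 50


@dataclass(frozen=True)
class MatchedFilterParams:
    """Parameters of the oriented matched-filter bank.

    sigma
        Gaussian cross-profile standard deviation in pixels.
    length
        Kernel extent along the vessel direction in pixels.
    n_orientations
        Number of directions; angular spacing is 180 deg / n.
    """

    sigma: float = 2.0
    length: int = 9
    n_orientations: int = 12

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.length < 3:
            raise ValueError("length must be >= 3")
        if self.n_orientations < 4:
            raise ValueError("n_orientations must be >= 4")

    @property
    def angles(self) -> np.ndarray:
        """Orientation angles in radians, spanning [0, pi)."""
        return np.arange(self.n_orientations) * (np.pi / self.n_orientations)


@dataclass(frozen=True)
class ThresholdResult:
    threshold: float
    degenerate: bool = False
    n_iterations: int = 0


def _matched_kernel(sigma: float, length: int, theta: float) -> np.ndarray:
    """Zero-mean matched-filter kernel for vessel direction ``theta``.

    The cross-profile is a Gaussian truncated at |u| <= 3 sigma, extended
    over ``length`` pixels along the vessel axis, then mean-subtracted so
    the kernel annihilates constant images.  Applied to the *inverted*
    image (vessels bright), an aligned bright line yields the maximal
    positive response.
    """
    half = int(np.ceil(max(3.0 * sigma, length / 2.0)))
    coords = np.arange(-half, half + 1, dtype=np.float64)
    xx, yy = np.meshgrid(coords, coords)  # xx: col offset, yy: row offset
    # u: signed distance perpendicular to the vessel axis; v: along it
    u = -xx * np.sin(theta) + yy * np.cos(theta)
    v = xx * np.cos(theta) + yy * np.sin(theta)
    support = (np.abs(u) <= 3.0 * sigma) & (np.abs(v) <= length / 2.0)
    kernel = np.zeros_like(xx)
    kernel[support] = np.exp(-u[support] ** 2 / (2.0 * sigma**2))
    kernel[support] -= kernel[support].mean()
    return kernel


def matched_filter_response(
    img: np.ndarray, params: MatchedFilterParams | None = None
) -> np.ndarray:
    """Maximum oriented matched-filter response, scaled to [0, 255].

    The 8-bit input is inverted (vessels are dark in fundus images) and
    correlated with each zero-mean oriented kernel; the response is the
    pixel-wise maximum over orientations, then affinely rescaled to
    [0, 255].  A constant input produces an all-zero response.

    Returns
    -------
    ndarray of float64, same shape as ``img``.
    """
    params = params or MatchedFilterParams()
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D grayscale raster")
    inverted = 255.0 - arr
    response = None
    for theta in params.angles:
        k = _matched_kernel(params.sigma, params.length, theta)
        r = ndi.correlate(inverted, k, mode="reflect")
        response = r if response is None else np.maximum(response, r)
    lo, hi = response.min(), response.max()
    if hi - lo < 1e-12:
        return np.zeros_like(response)
    return (response - lo) * (255.0 / (hi - lo))


def per_orientation_responses(
    img: np.ndarray, params: MatchedFilterParams
) -> np.ndarray:
    """Raw (unscaled) responses for each orientation, shape (n, H, W)."""
    inverted = 255.0 - np.asarray(img, dtype=np.float64)
    return np.stack(
        [
            ndi.correlate(
                inverted, _matched_kernel(params.sigma, params.length, t), mode="reflect"
            )
            for t in params.angles
        ]
    )


def isodata_threshold(values: np.ndarray, tol: float = 0.5, max_iter: int = 100) -> ThresholdResult:
    """Iterative class-mean (isodata / Ridler-Calvard) threshold.

    Starts at the global mean; each update sets the threshold to the
    midpoint of the foreground and background class means, stopping when
    the change drops below ``tol`` gray levels or after ``max_iter``
    iterations.

    Returns
    -------
    ThresholdResult
        ``degenerate`` is set when one class is empty (e.g. all values
        identical), in which case the threshold equals the common value.
    """
    vals = np.asarray(values, dtype=np.float64).ravel()
    if vals.size == 0:
        raise ValueError("cannot threshold an empty collection")
    t = float(vals.mean())
    for it in range(1, max_iter + 1):
        hi = vals[vals > t]
        lo = vals[vals <= t]
        if hi.size == 0 or lo.size == 0:
            return ThresholdResult(threshold=t, degenerate=True, n_iterations=it)
        t_new = 0.5 * (hi.mean() + lo.mean())
        if abs(t_new - t) < tol:
            return ThresholdResult(threshold=float(t_new), degenerate=False, n_iterations=it)
        t = float(t_new)
    return ThresholdResult(threshold=t, degenerate=False, n_iterations=max_iter)


def estimate_fov(img: np.ndarray, red_threshold: int = 20) -> np.ndarray:
    """Estimate the circular field-of-view mask from the red channel.

    Keeps the largest connected component of ``R > red_threshold`` and
    fills holes, excluding the dark surround of fundus photographs.
    """
    px = img.pixels if isinstance(img, FundusImage) else np.asarray(img)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) raster")
    bright = px[:, :, 0] > red_threshold
    labels, n = ndi.label(bright)
    if n == 0:
        return np.zeros(px.shape[:2], dtype=bool)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    fov = labels == sizes.argmax()
    return ndi.binary_fill_holes(fov)


def default_min_component(shape: tuple[int, int]) -> int:
    """Small-component cutoff scaled from the reference image area."""
    area = shape[0] * shape[1]
    return max(1, round(MIN_COMPONENT_REFERENCE * area / REFERENCE_AREA))


def segment_vessels(
    img: FundusImage | np.ndarray,
    mf_params: MatchedFilterParams | None = None,
    min_component_px: int | None = None,
    fov: np.ndarray | None = None,
    clahe_tiles: tuple[int, int] = (8, 8),
    clahe_clip: float = 0.01,
    median_k: int = 3,
) -> np.ndarray:
    """Segment the vascular tree of a color fundus image.

    Pipeline: green channel -> CLAHE -> median filter -> oriented matched
    filter -> isodata threshold over in-FOV response values -> binarize ->
    drop components smaller than ``min_component_px`` -> restrict to FOV.

    Parameters
    ----------
    img : FundusImage or (H, W, 3) uint8 array
    fov : bool array, optional
        Field-of-view mask; estimated from the red channel when omitted
        (the image's own ``fov_mask`` takes precedence if present).

    Returns
    -------
    ndarray of uint8 in {0, 1}, shape (H, W).
    """
    if isinstance(img, FundusImage):
        px = img.pixels
        if fov is None:
            fov = img.fov_mask
    else:
        px = np.asarray(img)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) raster")
    if fov is None:
        fov = estimate_fov(px)
    fov = np.asarray(fov, dtype=bool)
    if fov.shape != px.shape[:2]:
        raise ValueError("FOV mask dimensions do not match the image")

    green = px[:, :, 1]
    prepped = median_filter(clahe(green, tiles=clahe_tiles, clip_limit=clahe_clip), k=median_k)
    response = matched_filter_response(prepped, mf_params)

    in_fov = response[fov]
    if in_fov.size == 0:
        warnings.warn("empty FOV; returning an empty vessel mask", stacklevel=2)
        return np.zeros(px.shape[:2], dtype=np.uint8)
    result = isodata_threshold(in_fov)
    if result.degenerate:
        warnings.warn("degenerate threshold (constant response); empty mask", stacklevel=2)
        return np.zeros(px.shape[:2], dtype=np.uint8)

    mask = (response > result.threshold) & fov
    if min_component_px is None:
        min_component_px = default_min_component(px.shape[:2])
    if min_component_px > 1:
        labels, n = ndi.label(mask)
        if n:
            sizes = np.bincount(labels.ravel())
            sizes[0] = 0
            mask = sizes[labels] >= min_component_px
    return mask.astype(np.uint8)


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity 2|A n B| / (|A| + |B|); 1.0 when both are empty."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask dimensions differ: {a.shape} vs {b.shape}")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / total
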