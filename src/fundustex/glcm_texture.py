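"""Gray-level co-occurrence matrices and Haralick texture features.

The texture profile of an image is computed from 16-level quantized
intensities: one co-occurrence matrix per orientation (0, 45, 90, 135
degrees) at pixel distance ``d``, normalized to probabilities, eight
scalar features per matrix, and a feature-wise average over the four
orientations.

Feature definitions
-------------------
With ``P(i, j)`` the normalized co-occurrence probability over levels
``i, j = 1..N``, marginals ``Px(i) = sum_j P(i, j)`` and
``Py(j) = sum_i P(i, j)``, marginal means/SDs ``mu_x, mu_y, sigma_x,
sigma_y``, and the diagonal-sum distribution
``P_{x+y}(k) = sum_{i+j=k} P(i, j)`` for ``k = 2..2N``:

=============  =====================================================
energy         sum_ij P(i,j)^2
contrast       sum_ij (i-j)^2 P(i,j)
correlation    sum_ij ((i-mu_x)(j-mu_y)/(sigma_x sigma_y)) P(i,j)
variance       sum_ij (i-mu_x)^2 P(i,j)
sum_average    sum_k k P_{x+y}(k)
sum_variance   sum_k (k - mu_{x+y})^2 P_{x+y}(k),  mu_{x+y} = sum_average
sum_entropy    -sum_k P_{x+y}(k) log P_{x+y}(k)
entropy        -sum_ij P(i,j) log P(i,j)
=============  =====================================================

Logarithms default to base 2 (entropy maximum ``log2`` of the level
count); ``0 log 0`` is taken as 0.  Correlation is defined as 0 when
``sigma_x sigma_y = 0``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np

from .preprocess import FundusImage, to_grayscale

__all__ = [
    "ANGLES",
    "FEATURE_NAMES",
    "QuantizedImage",
    "CoocMatrix",
    "HaralickVector",
    "quantize",
    "cooccurrence",
    "haralick_features",
    "directional_average",
    "vessel_texture_profile",
]

#: Standard GLCM orientations in degrees.
ANGLES = (0, 45, 90, 135)

#: (row, col) pixel offsets per orientation for distance d.
def _offset(theta: int, d: int) -> tuple[int, int]:
    try:
        dr, dc = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}[theta]
    except KeyError:
        raise ValueError(f"orientation must be one of {ANGLES}, got {theta}") from None
    return dr * d, dc * d


FEATURE_NAMES = (
    "energy",
    "contrast",
    "correlation",
    "variance",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
)


@dataclass(frozen=True)
class QuantizedImage:
    """2-D raster of integer levels in [1, n_levels]."""

    levels: np.ndarray
    n_levels: int = 16

    def __post_init__(self) -> None:
        arr = np.asarray(self.levels)
        if arr.ndim != 2:
            raise ValueError("levels must be a 2-D raster")
        if arr.size and (arr.min() < 1 or arr.max() > self.n_levels):
            raise ValueError(f"levels must lie in [1, {self.n_levels}]")
        object.__setattr__(self, "levels", arr)


@dataclass(frozen=True)
class CoocMatrix:
    """Normalized co-occurrence matrix for one (distance, orientation)."""

    probabilities: np.ndarray
    distance: int
    orientation: int
    pair_count: int

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=np.float64)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("probabilities must be a square matrix")
        object.__setattr__(self, "probabilities", p)

    @property
    def n_levels(self) -> int:
        return self.probabilities.shape[0]

    def is_normalized(self, tol: float = 1e-9) -> bool:
        p = self.probabilities
        return bool(p.min() >= 0 and abs(p.sum() - 1.0) <= tol)


@dataclass(frozen=True)
class HaralickVector:
    energy: float
    contrast: float
    correlation: float
    variance: float
    sum_average: float
    sum_variance: float
    sum_entropy: float
    entropy: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)], dtype=np.float64)

    def as_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}


def quantize(
    img: np.ndarray,
    n_levels: int = 16,
    gray_limits: tuple[float, float] = (0, 255),
) -> QuantizedImage:
    """Equal-width quantization of [lo, hi] into ``n_levels`` bins.

    Value ``v`` maps to ``min(floor((v - lo) * N / (hi - lo + 1)), N-1) + 1``,
    so levels run from 1 to N and the default limits (0, 255) split the
    8-bit range into bins of width 256 / N.
    """
    lo, hi = gray_limits
    if lo >= hi:
        raise ValueError("gray_limits must satisfy lo < hi")
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    arr = np.asarray(img, dtype=np.float64)
    idx = np.floor((arr - lo) * n_levels / (hi - lo + 1))
    idx = np.clip(idx, 0, n_levels - 1)
    return QuantizedImage(levels=idx.astype(np.int64) + 1, n_levels=n_levels)


def cooccurrence(q: QuantizedImage, d: int = 1, theta: int = 0) -> CoocMatrix:
    """Single-offset (non-symmetric) co-occurrence matrix.

    Counts pairs ``(x, y)`` and ``(x, y) + offset`` whose second member
    falls inside the raster, then normalizes the counts to probabilities.
    Offsets in (row, col) convention: 0 deg -> (0, d); 45 -> (-d, d);
    90 -> (-d, 0); 135 -> (-d, -d).
    """
    if d < 1:
        raise ValueError("distance d must be >= 1")
    dr, dc = _offset(theta, d)
    levels = q.levels
    n = q.n_levels
    h, w = levels.shape
    r0, r1 = max(0, -dr), h - max(0, dr)
    c0, c1 = max(0, -dc), w - max(0, dc)
    if r1 <= r0 or c1 <= c0:
        raise ValueError(f"image {levels.shape} too small for offset ({dr}, {dc})")
    first = levels[r0:r1, c0:c1]
    second = levels[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    flat = (first.ravel() - 1) * n + (second.ravel() - 1)
    counts = np.bincount(flat, minlength=n * n).reshape(n, n).astype(np.float64)
    pairs = int(counts.sum())
    return CoocMatrix(
        probabilities=counts / pairs, distance=d, orientation=theta, pair_count=pairs
    )


def _xlogx(p: np.ndarray, log_base: float) -> np.ndarray:
    """p * log(p) with the 0 log 0 = 0 convention."""
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * (np.log(p[nz]) / np.log(log_base))
    return out


def haralick_features(P: CoocMatrix | np.ndarray, log_base: float = 2.0) -> HaralickVector:
    """The eight texture features of a normalized co-occurrence matrix.

    Raises
    ------
    ValueError
        If the matrix is not normalized (entries >= 0 summing to 1
        within 1e-9).
    """
    if isinstance(P, CoocMatrix):
        if not P.is_normalized():
            raise ValueError("co-occurrence matrix is not normalized")
        p = P.probabilities
    else:
        p = np.asarray(P, dtype=np.float64)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("expected a square matrix")
        if p.min() < 0 or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("co-occurrence matrix is not normalized")
    n = p.shape[0]
    i = np.arange(1, n + 1, dtype=np.float64)
    ii = i[:, None]
    jj = i[None, :]

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(np.dot(i, px))
    mu_y = float(np.dot(i, py))
    sigma_x = float(np.sqrt(np.dot((i - mu_x) ** 2, px)))
    sigma_y = float(np.sqrt(np.dot((i - mu_y) ** 2, py)))

    energy = float((p**2).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    denom = sigma_x * sigma_y
    if denom > 0:
        correlation = float((((ii - mu_x) * (jj - mu_y)) * p).sum() / denom)
    else:
        warnings.warn("degenerate marginals (sigma_x * sigma_y = 0); correlation set to 0",
                      stacklevel=2)
        correlation = 0.0
    variance = float(((ii - mu_x) ** 2 * p).sum())

    # diagonal-sum distribution over k = 2 .. 2N
    ksum = (ii + jj).astype(np.int64)
    p_xpy = np.bincount(ksum.ravel(), weights=p.ravel(), minlength=2 * n + 1)[2:]
    k = np.arange(2, 2 * n + 1, dtype=np.float64)
    sum_average = float(np.dot(k, p_xpy))
    sum_variance = float(np.dot((k - sum_average) ** 2, p_xpy))
    sum_entropy = float(-_xlogx(p_xpy, log_base).sum())
    entropy = float(-_xlogx(p, log_base).sum())

    return HaralickVector(
        energy=energy,
        contrast=contrast,
        correlation=correlation,
        variance=variance,
        sum_average=sum_average,
        sum_variance=sum_variance,
        sum_entropy=sum_entropy,
        entropy=entropy,
    )


def directional_average(vectors: list[HaralickVector]) -> HaralickVector:
    """Feature-wise arithmetic mean over the four orientations."""
    if len(vectors) != 4:
        raise ValueError(f"expected exactly 4 orientation vectors, got {len(vectors)}")
    stacked = np.stack([v.as_array() for v in vectors]).mean(axis=0)
    return HaralickVector(*map(float, stacked))


def vessel_texture_profile(
    img: FundusImage | np.ndarray,
    mask: np.ndarray,
    n_levels: int = 16,
    distance: int = 1,
    log_base: float = 2.0,
    gray_limits: tuple[float, float] = (0, 255),
) -> HaralickVector:
    """Directionally averaged texture features of the masked vasculature.

    The image is converted to grayscale, non-vessel pixels are set to 0
    (masked grayscale convention: vessel pixels keep their intensities,
    the background contributes a dominant zero level), quantized, and
    co-occurrence pairs are enumerated over the full raster.

    Parameters
    ----------
    img : FundusImage, RGB array, or 2-D grayscale array
    mask : binary array matching the image dimensions
    """
    px = img.pixels if isinstance(img, FundusImage) else np.asarray(img)
    gray = to_grayscale(px) if px.ndim == 3 else px
    m = np.asarray(mask).astype(bool)
    if m.shape != gray.shape:
        raise ValueError("mask dimensions do not match the image")
    if not m.any():
        warnings.warn("empty vessel mask; texture computed on an all-zero raster",
                      stacklevel=2)
    masked = np.where(m, gray, 0)
    q = quantize(masked, n_levels=n_levels, gray_limits=gray_limits)
    per_angle = [
        haralick_features(cooccurrence(q, d=distance, theta=t), log_base=log_base)
        for t in ANGLES
    ]
    return directional_average(per_angle)
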