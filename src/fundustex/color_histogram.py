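"""Global fundus color analysis: per-channel 256-bin histograms, group
averages, Mahalanobis group separability, and bivariate channel
histograms.
"""

from __future__ import annotations

import numpy as np

from .preprocess import FundusImage

__all__ = [
    "CHANNELS",
    "channel_histogram",
    "image_histograms",
    "frequencies",
    "average_histogram",
    "mahalanobis_separation",
    "mahalanobis_distance",
    "bivariate_histogram",
]

CHANNELS = ("R", "G", "B")
_CHANNEL_INDEX = {"R": 0, "G": 1, "B": 2}


def _channel_index(channel: str | int) -> int:
    if isinstance(channel, str):
        try:
            return _CHANNEL_INDEX[channel.upper()]
        except KeyError:
            raise ValueError(f"channel must be one of {CHANNELS}") from None
    if channel not in (0, 1, 2):
        raise ValueError("channel index must be 0, 1 or 2")
    return int(channel)


def _pixels(img: FundusImage | np.ndarray) -> np.ndarray:
    px = img.pixels if isinstance(img, FundusImage) else np.asarray(img)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) raster")
    return px


def channel_histogram(
    img: FundusImage | np.ndarray,
    channel: str | int,
    fov_only: bool = False,
    fov: np.ndarray | None = None,
) -> np.ndarray:
    """Exact 256-bin count histogram of one color channel.

    The counts sum to the number of pixels considered (the whole raster,
    or the field of view when ``fov_only`` is set).

    Returns
    -------
    ndarray of int64, shape (256,)
    """
    px = _pixels(img)
    values = px[:, :, _channel_index(channel)]
    if fov_only:
        if fov is None and isinstance(img, FundusImage):
            fov = img.fov_mask
        if fov is None:
            raise ValueError("fov_only requested but no FOV mask available")
        values = values[np.asarray(fov, dtype=bool)]
    return np.bincount(values.ravel(), minlength=256).astype(np.int64)


def image_histograms(
    img: FundusImage | np.ndarray, fov_only: bool = False, fov: np.ndarray | None = None
) -> np.ndarray:
    """Stacked (3, 256) count histograms in R, G, B order."""
    return np.stack(
        [channel_histogram(img, c, fov_only=fov_only, fov=fov) for c in CHANNELS]
    )


def frequencies(counts: np.ndarray) -> np.ndarray:
    """Normalize count histograms to frequencies along the last axis."""
    counts = np.asarray(counts, dtype=np.float64)
    totals = counts.sum(axis=-1, keepdims=True)
    if np.any(totals == 0):
        raise ValueError("cannot normalize an empty histogram")
    return counts / totals


def average_histogram(hists: np.ndarray) -> np.ndarray:
    """Bin-wise mean of per-image frequency histograms.

    Parameters
    ----------
    hists : ndarray, shape (n_images, 256)
        Per-image count (or frequency) histograms for one channel; counts
        are normalized per image before averaging.
    """
    hists = np.atleast_2d(np.asarray(hists, dtype=np.float64))
    if hists.shape[0] < 1:
        raise ValueError("need at least one image histogram")
    return frequencies(hists).mean(axis=0)


def _feature_matrix(hists: np.ndarray, channels: tuple[str, ...]) -> np.ndarray:
    """Per-image feature vectors: concatenated per-channel frequencies."""
    hists = np.asarray(hists, dtype=np.float64)
    if hists.ndim != 3 or hists.shape[1] != 3 or hists.shape[2] != 256:
        raise ValueError("expected histograms of shape (n_images, 3, 256)")
    idx = [_channel_index(c) for c in channels]
    freq = frequencies(hists)
    return np.concatenate([freq[:, i, :] for i in idx], axis=1)


def mahalanobis_separation(
    hists_a: np.ndarray,
    hists_b: np.ndarray,
    channels: tuple[str, ...] = ("R", "G", "B"),
    covariance: str = "pinv",
    shrinkage: float = 0.1,
    eig_tol: float = 1e-10,
) -> float:
    """Mahalanobis distance between two groups of channel histograms.

    Each image contributes a feature vector built by concatenating the
    frequency histograms of the selected channels (256 dims per channel).
    The distance is ``sqrt((mu_a - mu_b)^T S+ (mu_a - mu_b))`` with ``S``
    the pooled within-group covariance.

    Because group sizes are far smaller than the dimension, ``S`` is
    rank-deficient; its inverse is taken as:

    - ``"pinv"`` (default): eigendecomposition with eigenvalues below
      ``eig_tol`` times the largest truncated to zero (Moore-Penrose
      pseudo-inverse on the retained subspace);
    - ``"shrinkage"``: ``(1 - lam) S + lam diag(S)`` before the
      pseudo-inverse, ``lam = shrinkage``;
    - ``"identity"``: the identity matrix (distance reduces to the
      Euclidean norm of the mean difference).

    Parameters
    ----------
    hists_a, hists_b : ndarray, shape (n_images, 3, 256)
        Per-image count histograms for each group; n_images >= 2.
    """
    xa = _feature_matrix(hists_a, channels)
    xb = _feature_matrix(hists_b, channels)
    return mahalanobis_distance(
        xa, xb, covariance=covariance, shrinkage=shrinkage, eig_tol=eig_tol
    )


def mahalanobis_distance(
    xa: np.ndarray,
    xb: np.ndarray,
    covariance: str = "pinv",
    shrinkage: float = 0.1,
    eig_tol: float = 1e-10,
) -> float:
    """Pooled-covariance Mahalanobis distance between two point clouds.

    ``xa`` and ``xb`` are (n_samples, n_features) matrices with at least
    two samples each; see :func:`mahalanobis_separation` for the
    covariance inversion modes.
    """
    xa = np.atleast_2d(np.asarray(xa, dtype=np.float64))
    xb = np.atleast_2d(np.asarray(xb, dtype=np.float64))
    if xa.shape[0] < 2 or xb.shape[0] < 2:
        raise ValueError("each group needs >= 2 samples (covariance undefined)")
    diff = xa.mean(axis=0) - xb.mean(axis=0)

    if covariance == "identity":
        return float(np.linalg.norm(diff))
    if covariance not in ("pinv", "shrinkage"):
        raise ValueError("covariance must be 'pinv', 'shrinkage' or 'identity'")

    na, nb = xa.shape[0], xb.shape[0]
    ca = np.atleast_2d(np.cov(xa, rowvar=False))
    cb = np.atleast_2d(np.cov(xb, rowvar=False))
    pooled = ((na - 1) * ca + (nb - 1) * cb) / (na + nb - 2)
    if covariance == "shrinkage":
        pooled = (1.0 - shrinkage) * pooled + shrinkage * np.diag(np.diag(pooled))

    w, v = np.linalg.eigh(pooled)
    keep = w > eig_tol * w.max() if w.max() > 0 else np.zeros_like(w, dtype=bool)
    if not keep.any():
        # zero covariance: distance undefined unless means coincide
        return 0.0 if np.allclose(diff, 0) else float("inf")
    proj = v[:, keep].T @ diff
    return float(np.sqrt(np.sum(proj**2 / w[keep])))


def bivariate_histogram(img: FundusImage | np.ndarray, pair: str = "RG") -> np.ndarray:
    """Exact 256x256 joint histogram of an ordered channel pair.

    ``pair`` is two of "RGB", e.g. ``"RG"``; rows index the first
    channel, columns the second.  Row sums reproduce the first channel's
    univariate histogram, column sums the second's.
    """
    if len(pair) != 2:
        raise ValueError("pair must name exactly two channels, e.g. 'RG'")
    px = _pixels(img)
    c1 = px[:, :, _channel_index(pair[0])].ravel().astype(np.int64)
    c2 = px[:, :, _channel_index(pair[1])].ravel().astype(np.int64)
    counts = np.bincount(c1 * 256 + c2, minlength=256 * 256)
    return counts.reshape(256, 256)
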