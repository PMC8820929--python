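"""CfitK-means canopy extraction and baseline segmenters.

CfitK-means is a hybrid segmenter for chlorophyll-fluorescence canopy
frames: a dynamic curve-fit threshold first removes background and pot
pixels, then a two-cluster intensity K-means — initialized from the
histogram of the surviving pixels rather than randomly — separates the
retained mass into a dim residual cluster and the bright canopy
cluster.  The mask labels the higher-centroid cluster as canopy.

Histogram initialization (on the 0-255 level grid, ``cutoff`` = the
elimination threshold):

    levels  = occupied intensity levels strictly above cutoff
    mean0   = mean(levels)   (sits inside the canopy intensity mass)
    mean1   = min(levels)    (the dimmest retained level)

Baselines: global static threshold (GST), global automatic/Otsu
threshold (GAT), and a 4-centroid intensity K-means whose lowest
cluster is treated as background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .preprocessing import normalize, standardize, DEFAULT_FRAME
from .thresholding import (
    ThresholdModel, DEFAULT_MODEL, apply_threshold, dynamic_threshold,
    otsu_threshold,
)

logger = logging.getLogger(__name__)

#: Default global static threshold: top of the pot-elimination range.
DEFAULT_GST = 17.0


@dataclass(frozen=True)
class CentroidPair:
    """Histogram-derived initial centroids, on the 0-255 intensity scale."""

    initial_mean0: float  # mean of occupied levels above cutoff
    initial_mean1: float  # min of occupied levels above cutoff

    def __post_init__(self):
        if self.initial_mean1 > self.initial_mean0:
            raise ValueError("initial_mean1 (min level) cannot exceed "
                             "initial_mean0 (mean level)")


def initial_centroids(img: np.ndarray, cutoff: float) -> CentroidPair:
    """Histogram-based centroid initialization.

    Builds the 0-255 histogram of pixels with intensity strictly above
    ``cutoff``; the occupied levels form the ``Histogram_means`` set
    whose mean and minimum seed the two K-means centroids.

    Raises
    ------
    ValueError
        If no pixel lies above the cutoff (callers fall back to an
        all-background mask).
    """
    img = np.asarray(img)
    hist = np.bincount(img.ravel().astype(np.int64), minlength=256)[:256]
    levels = np.flatnonzero(hist)
    levels = levels[levels > cutoff]
    if levels.size == 0:
        raise ValueError(f"no pixel above cutoff {cutoff}; degenerate input")
    return CentroidPair(initial_mean0=float(levels.mean()),
                        initial_mean1=float(levels.min()))


def kmeans_intensity(img: np.ndarray, centroids, *, max_iter: int = 20,
                     return_centroids: bool = False):
    """Lloyd iteration on pixel intensities with fixed initial centroids.

    Pixels are assigned to the nearest centroid by 1-D Euclidean
    distance; centroids are updated to cluster means; iteration stops
    when assignments no longer change or after ``max_iter`` rounds.  An
    empty cluster keeps its previous centroid.  Fully deterministic for
    a given initialization.

    Parameters
    ----------
    img : numpy.ndarray
        Intensity image; expected normalized to [0, 1] (centroids on
        the same scale).
    centroids : CentroidPair or sequence of float
        Initial centroid values.
    return_centroids : bool
        Also return the final centroid array.

    Returns
    -------
    numpy.ndarray
        Mask of {0, 1}: label 1 is the cluster with the larger final
        centroid (the canopy with K=2, the merged foreground with more
        centroids).
    """
    img = np.asarray(img, dtype=np.float64)
    if isinstance(centroids, CentroidPair):
        c = np.array([centroids.initial_mean1, centroids.initial_mean0],
                     dtype=np.float64)
    else:
        c = np.asarray(centroids, dtype=np.float64).copy()
    flat = img.ravel()
    assign = np.full(flat.shape, -1, dtype=np.int64)
    for _ in range(max_iter):
        d = np.abs(flat[:, None] - c[None, :])
        new_assign = np.argmin(d, axis=1)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for k in range(c.size):
            members = flat[assign == k]
            if members.size:
                c[k] = members.mean()
            else:
                logger.info("empty cluster %d: keeping previous centroid %.4f",
                            k, c[k])
    order = np.argsort(c)
    lowest = order[0]
    mask = (assign != lowest).astype(np.uint8).reshape(img.shape)
    if return_centroids:
        return mask, c
    return mask


def cfitkmeans(img: np.ndarray, x: int = 0,
               model: ThresholdModel = DEFAULT_MODEL,
               frame: tuple[int, int] | None = None) -> np.ndarray:
    """Curve-fit threshold + histogram-initialized 2-means canopy mask.

    Pipeline: standardize -> dynamic threshold T(x) -> remove pixels
    below T -> histogram centroid init (cutoff = T) -> normalize ->
    2-cluster intensity K-means.  Pixels removed by the threshold can
    never be labelled canopy.

    Parameters
    ----------
    img : numpy.ndarray
        0-255 intensity image.
    x : int
        Sequence index of the image in capture order (drives the
        dynamic threshold).
    frame : (width, height), optional
        Standardization frame; None keeps the input dimensions.

    Returns
    -------
    numpy.ndarray
        uint8 canopy mask {0, 1} at the (standardized) frame.
    """
    if frame is not None:
        img = standardize(img, frame)
    img = np.asarray(img)
    t = dynamic_threshold(x, model)
    survivors = img >= t
    thresholded = apply_threshold(img, t)
    try:
        pair = initial_centroids(thresholded, cutoff=t)
    except ValueError:
        logger.warning("threshold %.3f removed every pixel; "
                       "returning all-background mask", t)
        return np.zeros(img.shape, dtype=np.uint8)
    scaled = CentroidPair(initial_mean0=pair.initial_mean0 / 255.0,
                          initial_mean1=pair.initial_mean1 / 255.0)
    mask = kmeans_intensity(normalize(thresholded), scaled)
    mask &= survivors.astype(np.uint8)
    logger.debug("cfitkmeans x=%d T=%.3f init=(%.1f, %.1f)",
                 x, t, pair.initial_mean0, pair.initial_mean1)
    return mask


def _kmeans4_init(img: np.ndarray) -> np.ndarray:
    """Quartile midpoints of the image's intensity range (on [0,1])."""
    flat = normalize(img).ravel()
    lo, hi = float(flat.min()), float(flat.max())
    edges = np.linspace(lo, hi, 5)
    return (edges[:-1] + edges[1:]) / 2.0


def baseline_segment(img: np.ndarray, method: str, *,
                     gst_t: float = DEFAULT_GST) -> np.ndarray:
    """Baseline segmenters: ``gst``, ``gat`` (Otsu) or ``kmeans4``.

    gst: pixels >= the fixed threshold are foreground.
    gat: pixels strictly above the Otsu threshold are foreground.
    kmeans4: 4-centroid intensity K-means (quartile-midpoint init);
    the lowest-centroid cluster is background, the rest are merged.
    """
    img = np.asarray(img)
    if method == "gst":
        return (img >= gst_t).astype(np.uint8)
    if method == "gat":
        t = otsu_threshold(img)
        return (img > t).astype(np.uint8)
    if method == "kmeans4":
        return kmeans_intensity(normalize(img), _kmeans4_init(img))
    raise ValueError(f"unknown baseline method {method!r}; "
                     "expected gst, gat or kmeans4")
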