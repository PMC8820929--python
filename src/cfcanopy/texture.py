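"""Grey-level cooccurrence matrices and the 23-trait canopy texture panel.

The canopy's morphological response to water stress is summarized by 23
scalar Haralick-style texture traits computed from a quantized grey
level cooccurrence matrix (GLCM).  Intensities are binned into ``Ng``
equal-width levels (default 9) over [0, 255]; cooccurrence is counted
at a single pixel offset (default one step to the right), accumulated
symmetrically, and restricted to pixel pairs that both lie inside the
canopy mask.

Grey levels are 1-based (i, j = 1..Ng) throughout, which matters for
the level-weighted traits (autocorrelation, sum average, ...).

Marginal quantities of the normalized matrix p(i, j):

    px(i) = sum_j p(i,j)            py(j) = sum_i p(i,j)
    p_{x+y}(k) = sum_{i+j=k} p      k = 2..2Ng
    p_{x-y}(k) = sum_{|i-j|=k} p    k = 0..Ng-1

with base-2 entropies HX, HY, HXY, HXY1, HXY2 (a small epsilon is added
inside every logarithm, so a zero cell contributes nothing).

Two printed-formula conventions are kept switchable via ``GLCMConfig``:
``sosvh_standard`` (sum of squares uses (i - mu)^2; the alternative is
the literal (1 - mu)^2) and ``inf2h_sqrt`` (apply the square root that
bounds inf2h into [0, 1]; off by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical order of the 23 trait names (CSV column order).
FEATURE_NAMES = (
    "autoc", "contr", "corrm", "corrp", "cprom", "cshad", "dissi",
    "energ", "entro", "homom", "homop", "maxpr", "sosvh", "savgh",
    "svarh", "senth", "dvarh", "denth", "inf1h", "inf2h", "homom1",
    "indnc", "idmnc",
)


@dataclass(frozen=True)
class GLCMConfig:
    """Quantization and cooccurrence settings for the texture panel."""

    ng: int = 9
    offset: tuple[int, int] = (0, 1)
    symmetric: bool = True
    epsilon: float = float(np.finfo(np.float64).eps)
    sosvh_standard: bool = True   # (i - mu)^2 instead of the literal (1 - mu)^2
    inf2h_sqrt: bool = False      # sqrt(1 - exp(-2(HXY2 - HXY)))

    def __post_init__(self):
        if self.ng < 2:
            raise ValueError(f"ng must be >= 2, got {self.ng}")
        if self.offset == (0, 0):
            raise ValueError("offset (0, 0) pairs every pixel with itself")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class MarginalStats:
    """Marginals, their moments, and the entropy terms of a GLCM."""

    px: np.ndarray
    py: np.ndarray
    mu_x: float
    mu_y: float
    var_x: float
    var_y: float
    p_xplusy: np.ndarray    # k = 2..2Ng  (index 0 <-> k = 2)
    p_xminusy: np.ndarray   # k = 0..Ng-1
    mu_xplusy: float
    mu_xminusy: float
    hx: float
    hy: float
    hxy: float
    hxy1: float
    hxy2: float


def quantize(img: np.ndarray, mask: np.ndarray | None = None,
             ng: int = 9) -> np.ndarray:
    """Bin 0-255 intensities into equal-width levels 1..Ng.

    Off-mask pixels are flagged level 0 and excluded from cooccurrence
    pairing.  Level = floor(v / (256 / Ng)) + 1, clipped to Ng.

    Raises
    ------
    ValueError
        If the mask selects no pixel.
    """
    img = np.asarray(img)
    q = np.minimum(np.floor(img / (256.0 / ng)), ng - 1).astype(np.int64) + 1
    if mask is not None:
        mask = np.asarray(mask).astype(bool)
        if not mask.any():
            raise ValueError("empty mask: no pixel to quantize")
        q = np.where(mask, q, 0)
    return q


def glcm(q: np.ndarray, config: GLCMConfig = GLCMConfig()) -> np.ndarray:
    """Normalized cooccurrence matrix of a quantized image.

    Counts ordered level pairs (q[r, c], q[r+dr, c+dc]) for the
    configured offset (dr, dc), skipping pairs where either pixel is
    flagged 0 (off-mask); with ``symmetric`` the reverse offset is
    accumulated as well.  The count matrix is normalized to sum to 1.

    Returns
    -------
    numpy.ndarray
        (Ng, Ng) float matrix; entry [i-1, j-1] is p(i, j).

    Raises
    ------
    ValueError
        If the offset yields no valid in-mask pair.
    """
    q = np.asarray(q, dtype=np.int64)
    ng = config.ng
    dr, dc = config.offset
    h, w = q.shape
    if abs(dr) >= h or abs(dc) >= w:
        raise ValueError(f"offset {config.offset} exceeds image size {q.shape}")
    # source/destination windows for the displacement (dr, dc)
    src = q[max(0, -dr):h - max(0, dr), max(0, -dc):w - max(0, dc)]
    dst = q[max(0, dr):h + min(0, dr), max(0, dc):w + min(0, dc)]
    valid = (src > 0) & (dst > 0)
    i, j = src[valid], dst[valid]
    counts = np.bincount((i - 1) * ng + (j - 1), minlength=ng * ng)
    p = counts.reshape(ng, ng).astype(np.float64)
    if config.symmetric:
        p = p + p.T
    total = p.sum()
    if total == 0:
        raise ValueError("no valid in-mask pixel pair at the configured offset")
    return p / total


def marginals(g: np.ndarray, epsilon: float | None = None) -> MarginalStats:
    """Marginal distributions, moments, and entropies of a GLCM.

    Entropies use base-2 logarithms with ``epsilon`` added inside each
    log (default: float64 machine epsilon).
    """
    g = np.asarray(g, dtype=np.float64)
    if epsilon is None:
        epsilon = float(np.finfo(np.float64).eps)
    ng = g.shape[0]
    levels = np.arange(1, ng + 1, dtype=np.float64)
    px = g.sum(axis=1)
    py = g.sum(axis=0)
    mu_x = float(levels @ px)
    mu_y = float(levels @ py)
    var_x = float(((levels - mu_x) ** 2) @ px)
    var_y = float(((levels - mu_y) ** 2) @ py)

    ii, jj = np.meshgrid(levels, levels, indexing="ij")
    sums = (ii + jj).astype(np.int64)        # 2..2Ng
    diffs = np.abs(ii - jj).astype(np.int64)  # 0..Ng-1
    p_xplusy = np.bincount((sums - 2).ravel(), weights=g.ravel(),
                           minlength=2 * ng - 1)
    p_xminusy = np.bincount(diffs.ravel(), weights=g.ravel(), minlength=ng)
    k_plus = np.arange(2, 2 * ng + 1, dtype=np.float64)
    k_minus = np.arange(0, ng, dtype=np.float64)
    mu_xplusy = float(k_plus @ p_xplusy)
    mu_xminusy = float(k_minus @ p_xminusy)

    def h(dist):
        return float(-np.sum(dist * np.log2(dist + epsilon)))

    pxpy = np.outer(px, py)
    hx = h(px)
    hy = h(py)
    hxy = h(g)
    hxy1 = float(-np.sum(g * np.log2(pxpy + epsilon)))
    hxy2 = h(pxpy)
    return MarginalStats(px=px, py=py, mu_x=mu_x, mu_y=mu_y,
                         var_x=var_x, var_y=var_y,
                         p_xplusy=p_xplusy, p_xminusy=p_xminusy,
                         mu_xplusy=mu_xplusy, mu_xminusy=mu_xminusy,
                         hx=hx, hy=hy, hxy=hxy, hxy1=hxy1, hxy2=hxy2)


def features(g: np.ndarray, m: MarginalStats | None = None,
             config: GLCMConfig = GLCMConfig()) -> dict[str, float]:
    """Compute the 23 texture traits from a normalized GLCM.

    When the marginal standard deviations vanish (constant texture) the
    two correlation traits are undefined and returned as NaN rather
    than dividing by zero.

    Returns
    -------
    dict
        Trait name -> value, in ``FEATURE_NAMES`` order.
    """
    g = np.asarray(g, dtype=np.float64)
    if m is None:
        m = marginals(g, config.epsilon)
    ng = g.shape[0]
    eps = config.epsilon
    levels = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(levels, levels, indexing="ij")
    k_plus = np.arange(2, 2 * ng + 1, dtype=np.float64)
    k_minus = np.arange(0, ng, dtype=np.float64)

    out: dict[str, float] = {}
    out["autoc"] = float(np.sum(ii * jj * g))
    out["contr"] = float(np.sum((ii - jj) ** 2 * g))
    sigma = np.sqrt(m.var_x * m.var_y)
    if sigma == 0:
        logger.info("zero marginal variance: correlation traits undefined")
        out["corrm"] = float("nan")
        out["corrp"] = float("nan")
    else:
        out["corrm"] = float(np.sum((ii - m.mu_x) * (jj - m.mu_y) * g) / sigma)
        out["corrp"] = float((out["autoc"] - m.mu_x * m.mu_y) / sigma)
    centered = ii + jj - m.mu_x - m.mu_y
    out["cprom"] = float(np.sum(centered ** 4 * g))
    out["cshad"] = float(np.sum(centered ** 3 * g))
    out["dissi"] = float(np.sum(np.abs(ii - jj) * g))
    out["energ"] = float(np.sum(g ** 2))
    out["entro"] = float(-np.sum(g * np.log2(g + eps)))
    out["homom"] = float(np.sum(g / (1.0 + (ii - jj) ** 2)))
    out["homop"] = float(np.sum(g / (1.0 + np.abs(ii - jj))))
    out["maxpr"] = float(g.max())
    if config.sosvh_standard:
        out["sosvh"] = float(np.sum((ii - m.mu_x) ** 2 * g))
    else:
        out["sosvh"] = float(np.sum((1.0 - m.mu_x) ** 2 * g))
    out["savgh"] = float(np.sum(k_plus * m.p_xplusy))
    out["svarh"] = float(np.sum((k_plus - m.mu_xplusy) ** 2 * m.p_xplusy))
    out["senth"] = float(-np.sum(m.p_xplusy * np.log2(m.p_xplusy + eps)))
    out["dvarh"] = float(np.sum((k_minus - m.mu_xminusy) ** 2 * m.p_xminusy))
    out["denth"] = float(-np.sum(m.p_xminusy * np.log2(m.p_xminusy + eps)))
    denom = max(m.hx, m.hy)
    out["inf1h"] = float((m.hxy - m.hxy1) / denom) if denom != 0 else 0.0
    v = 1.0 - np.exp(-2.0 * (m.hxy2 - m.hxy))
    out["inf2h"] = float(np.sqrt(max(v, 0.0))) if config.inf2h_sqrt else float(v)
    out["homom1"] = out["homop"]
    out["indnc"] = float(np.sum(g / (1.0 + np.abs(ii - jj) / ng)))
    out["idmnc"] = float(np.sum(g / (1.0 + (ii - jj) ** 2 / ng)))
    return out


def extract_features(img: np.ndarray, mask: np.ndarray | None = None,
                     config: GLCMConfig = GLCMConfig()) -> dict[str, float]:
    """Quantize, build the GLCM, and compute the 23-trait vector."""
    q = quantize(img, mask, config.ng)
    g = glcm(q, config)
    return features(g, marginals(g, config.epsilon), config)


def extract_table(images, config: GLCMConfig = GLCMConfig()) -> pd.DataFrame:
    """Trait table over a sequence of (image, mask, condition) entries.

    One row per image: the 23 trait columns plus a ``condition`` label.
    Images whose masked region is degenerate (empty mask, no valid
    pixel pair) are skipped with a logged reason.
    """
    rows = []
    for idx, (img, mask, condition) in enumerate(images):
        try:
            row = extract_features(img, mask, config)
        except ValueError as exc:
            logger.warning("image %d skipped: %s", idx, exc)
            continue
        row["condition"] = condition
        rows.append(row)
    if not rows:
        raise ValueError("no image yielded a valid trait vector")
    return pd.DataFrame(rows, columns=list(FEATURE_NAMES) + ["condition"])
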