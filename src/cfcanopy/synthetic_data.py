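"""Synthetic chlorophyll-fluorescence canopy scenes and trait tables.

Real fluorescence frames of potted wheat contain three intensity
populations: zero background, a dimly fluorescing pot at low
intensities (the 11-17 elimination range), and the canopy itself,
which brightens over the 60-day capture timeline and is depressed
under water stress, where more of the pot is also exposed.  This
module generates images with that structure — plus exact ground-truth
canopy and pot masks — so the segmentation, texture and evaluation
layers can be exercised end-to-end without the original image set.

Construction guarantees (before noise): pot intensities lie in 11-17
and canopy intensities at 18 or above, so their supports are disjoint
and with ``noise_sd = 0`` the canopy is exactly recoverable — the
curve-fit threshold removes background and most of the pot, and the
K-means stage relegates any surviving pot pixels (e.g. the 17-valued
ones a static threshold at 17 would keep) to the background cluster.

Blob geometry (randomly oriented ellipses) is fixture design, not a
claim about real canopies.  The default frame is a 4x-downscaled
347 x 260; the native 1388 x 1038 is one argument away.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .texture import FEATURE_NAMES

#: Default scaled-down frame (width, height); native frame is 1388 x 1038.
DEFAULT_FRAME = (347, 260)

#: Default partition of the 23 traits into three correlated blocks,
#: mirroring the variance/homogeneity/information grouping the traits
#: fall into empirically.
DEFAULT_BLOCKS = (
    ("autoc", "contr", "corrm", "corrp", "cprom", "cshad", "dissi",
     "entro", "sosvh", "savgh", "svarh", "senth", "dvarh", "denth",
     "idmnc"),
    ("energ", "homom", "homop", "maxpr", "homom1", "indnc"),
    ("inf1h", "inf2h"),
)


def canopy_mean_schedule(day: int, condition: str) -> float:
    """Mean canopy fluorescence intensity for a capture day.

    Canopies start dim and brighten over the 60-day timeline; water
    stress depresses the signal throughout.
    """
    if condition == "control":
        return 32.0 + 0.8 * day
    if condition == "drought":
        return 26.0 + 0.55 * day
    raise ValueError(f"unknown condition {condition!r}")


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic canopy scene.

    ``canopy_mean``/``n_leaf_blobs`` default (None) to the
    condition-and-day schedule: canopy mean from
    :func:`canopy_mean_schedule`, 6 leaf blobs for control and 4 for
    drought (stress reduces canopy cover, exposing more pot).
    """

    frame: tuple[int, int] = DEFAULT_FRAME
    condition: str = "control"
    day: int = 0
    seed: int = 0
    pot_intensity_range: tuple[int, int] = (11, 17)
    canopy_mean: float | None = None
    canopy_sd: float = 4.0
    n_leaf_blobs: int | None = None
    noise_sd: float = 0.0

    def __post_init__(self):
        if not 0 <= self.day <= 59:
            raise ValueError(f"day must be in 0..59, got {self.day}")
        lo, hi = self.pot_intensity_range
        if not (0 < lo <= hi <= 17):
            raise ValueError("pot intensities must lie in (0, 17]")
        if self.resolved_canopy_mean <= 17:
            raise ValueError("canopy mean must exceed 17 (pot range) to be "
                             "distinguishable from the pot")

    @property
    def resolved_canopy_mean(self) -> float:
        if self.canopy_mean is not None:
            return self.canopy_mean
        return canopy_mean_schedule(self.day, self.condition)

    @property
    def resolved_n_blobs(self) -> int:
        if self.n_leaf_blobs is not None:
            return self.n_leaf_blobs
        return 6 if self.condition == "control" else 4


def _ellipse_mask(h: int, w: int, cy: float, cx: float, a: float, b: float,
                  theta: float) -> np.ndarray:
    """Boolean mask of a rotated ellipse (semi-axes a, b, angle theta)."""
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    ct, st = math.cos(theta), math.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def make_canopy_image(spec: SceneSpec
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render one scene: image plus ground-truth canopy and pot masks.

    Background is exactly 0.  The pot is a band across the bottom of
    the frame (taller under drought) with uniform integer intensities
    over 11-17.  The canopy is a union of elliptical leaf blobs
    with truncated-Gaussian intensities bounded below at 18.  Additive
    Gaussian noise (``noise_sd``) perturbs pot and canopy pixels only
    and is clipped to [0, 255]; the masks always refer to the noiseless
    geometry.

    Returns
    -------
    (image, canopy_mask, pot_mask)
        uint8 image and two uint8 {0, 1} masks of the same shape.
    """
    rng = np.random.default_rng(spec.seed)
    w, h = spec.frame
    img = np.zeros((h, w), dtype=np.float64)

    # pot band at the bottom; drought exposes more of it
    pot_frac = 0.10 if spec.condition == "control" else 0.16
    pot_h = max(2, int(round(pot_frac * h)))
    pot = np.zeros((h, w), dtype=bool)
    pot[h - pot_h:, :] = True
    lo, hi = spec.pot_intensity_range
    img[pot] = rng.integers(lo, hi + 1, size=int(pot.sum()))

    # canopy blobs in the upper part of the frame
    canopy = np.zeros((h, w), dtype=bool)
    scale = 0.16 if spec.condition == "control" else 0.12
    for _ in range(spec.resolved_n_blobs):
        cy = rng.uniform(0.15, 0.60) * h
        cx = rng.uniform(0.15, 0.85) * w
        a = rng.uniform(0.6, 1.0) * scale * w
        b = rng.uniform(0.35, 0.8) * a
        theta = rng.uniform(0, math.pi)
        canopy |= _ellipse_mask(h, w, cy, cx, a, b, theta)
    n_canopy = int(canopy.sum())
    if n_canopy:
        mean = spec.resolved_canopy_mean
        sd = spec.canopy_sd
        a_std = (18.0 - mean) / sd
        b_std = (255.0 - mean) / sd
        values = truncnorm.rvs(a_std, b_std, loc=mean, scale=sd,
                               size=n_canopy, random_state=rng)
        img[canopy] = values

    if spec.noise_sd > 0:
        active = pot | canopy
        img[active] += rng.normal(0.0, spec.noise_sd, size=int(active.sum()))
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    pot_mask = (pot & ~canopy).astype(np.uint8)
    return img, canopy.astype(np.uint8), pot_mask


def make_timeline(n_days: int, condition: str = "control", seed: int = 0,
                  frame: tuple[int, int] = DEFAULT_FRAME,
                  noise_sd: float = 0.0):
    """Day-by-day capture sequence for one condition.

    Returns a list of ``(image, canopy_mask, x)`` with ``x`` the
    capture-order index feeding the dynamic threshold.  Control canopy
    mean intensity increases monotonically with the day.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    out = []
    base = np.random.default_rng(seed)
    for day in range(min(n_days, 60)):
        spec = SceneSpec(frame=frame, condition=condition, day=day,
                         seed=int(base.integers(2 ** 31)), noise_sd=noise_sd)
        img, canopy, _pot = make_canopy_image(spec)
        out.append((img, canopy, day))
    # extend beyond 60 days by cycling the day schedule if asked
    day = 0
    while len(out) < n_days:
        spec = SceneSpec(frame=frame, condition=condition, day=day % 60,
                         seed=int(base.integers(2 ** 31)), noise_sd=noise_sd)
        img, canopy, _pot = make_canopy_image(spec)
        out.append((img, canopy, len(out)))
        day += 1
    return out


def make_feature_table(n_rows: int, blocks=DEFAULT_BLOCKS,
                       within_r: float = 0.9, between_r: float = 0.0,
                       seed: int = 0, include_condition: bool = True,
                       ) -> pd.DataFrame:
    """Multivariate-Gaussian trait table with planted block correlation.

    Traits inside a block correlate at ``within_r``; traits in
    different blocks at ``between_r``.  Used to exercise the statistics
    layer with a known cluster structure.

    Raises
    ------
    ValueError
        If the requested block correlation matrix is not positive
        definite, or the blocks do not partition the 23 trait names.
    """
    if not within_r > between_r >= 0:
        raise ValueError("need within_r > between_r >= 0")
    names = [t for block in blocks for t in block]
    if sorted(names) != sorted(FEATURE_NAMES):
        raise ValueError("blocks must partition the 23 trait names")
    p = len(names)
    corr = np.full((p, p), between_r)
    start = 0
    for block in blocks:
        stop = start + len(block)
        corr[start:stop, start:stop] = within_r
        start = stop
    np.fill_diagonal(corr, 1.0)
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("block correlation matrix is not positive "
                         "definite") from exc
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((n_rows, p)) @ chol.T
    table = pd.DataFrame(data, columns=names)[list(FEATURE_NAMES)]
    if include_condition:
        half = n_rows // 2
        table["condition"] = ["control"] * half + \
            ["drought"] * (n_rows - half)
    return table
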