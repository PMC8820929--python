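"""Dynamic curve-fit elimination threshold and global thresholds.

Low-intensity pixels in a fluorescence canopy frame belong to the pot
(intensities roughly 11-17) or to background (0) rather than to
photosynthetically active tissue.  The elimination threshold drifts over
the capture timeline as the canopy brightens, so it is modelled as a
cubic polynomial of the image's position ``x`` in capture order:

    T(x) = p1*x^3 + p2*x^2 + p3*x + p4

with coefficients fitted (externally) against hit-and-trial thresholds.
The raw polynomial value is clamped into the empirical elimination range
[11, 17] as a guard.  Static and Otsu global thresholds are provided for
baseline comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ThresholdModel:
    """Cubic threshold polynomial with clamp bounds.

    Defaults are the published fit; ``clamp_lo``/``clamp_hi`` bound the
    returned threshold to the empirical pot-elimination range.
    """

    p1: float = 2.273e-08
    p2: float = -4.118e-05
    p3: float = 0.01699
    p4: float = 11.95
    clamp_lo: float = 11.0
    clamp_hi: float = 17.0

    def __post_init__(self):
        coeffs = (self.p1, self.p2, self.p3, self.p4)
        if not all(math.isfinite(c) for c in coeffs):
            raise ValueError(f"non-finite polynomial coefficients: {coeffs}")
        if self.clamp_lo > self.clamp_hi:
            raise ValueError("clamp_lo must not exceed clamp_hi")


DEFAULT_MODEL = ThresholdModel()


def dynamic_threshold(x: int, model: ThresholdModel = DEFAULT_MODEL,
                      *, clamp: bool = True) -> float:
    """Evaluate the elimination threshold at sequence index ``x``.

    Parameters
    ----------
    x : int
        Non-negative position of the image in capture order.
    model : ThresholdModel
        Polynomial coefficients and clamp bounds.
    clamp : bool
        If True (default) clip the raw polynomial value into
        ``[model.clamp_lo, model.clamp_hi]``; if False return the raw
        value.

    Returns
    -------
    float
        Threshold in intensity units (0-255 scale).
    """
    if x < 0:
        raise ValueError(f"sequence index must be non-negative, got {x}")
    # Horner evaluation of p1*x^3 + p2*x^2 + p3*x + p4
    raw = ((model.p1 * x + model.p2) * x + model.p3) * x + model.p4
    if not clamp:
        return raw
    return float(min(max(raw, model.clamp_lo), model.clamp_hi))


def apply_threshold(img: np.ndarray, t: float) -> np.ndarray:
    """Zero out every pixel strictly below ``t``; leave the rest unchanged.

    "Pixels below T are removed" is read strictly, so a pixel exactly at
    the threshold survives.  Idempotent for a fixed ``t``.
    """
    img = np.asarray(img)
    out = img.copy()
    out[img < t] = 0
    return out


def otsu_threshold(img: np.ndarray) -> int:
    """Between-class-variance-maximizing threshold over the 256-bin histogram.

    The candidate thresholds are the 256 intensity levels on the fixed
    0-255 grid; pixels <= t form the background class.  Returns the
    (lowest) maximizing level.

    Raises
    ------
    ValueError
        If the image is constant (no threshold can separate one class).
    """
    img = np.asarray(img)
    hist = np.bincount(img.ravel().astype(np.int64), minlength=256)[:256]
    total = hist.sum()
    if np.count_nonzero(hist) < 2:
        raise ValueError("Otsu threshold undefined for a constant image")
    w = hist / total
    omega0 = np.cumsum(w)                      # class-0 mass for t = 0..255
    mu_t = np.cumsum(w * np.arange(256))       # first moment up to t
    mu_total = mu_t[-1]
    omega1 = 1.0 - omega0
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_total * omega0 - mu_t) ** 2 / (omega0 * omega1)
    sigma_b[~np.isfinite(sigma_b)] = 0.0
    return int(np.argmax(sigma_b))
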