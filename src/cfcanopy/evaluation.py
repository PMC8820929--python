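"""IoU scoring and the random-sampling segmentation evaluation protocol.

A segmenter is scored against hand-curated (here: generated) ground
truth by intersection-over-union of the binary canopy masks.  The
evaluation protocol draws seeded random samples of increasing size
(default 25/50/75/100), runs every algorithm on each sampled image,
counts the images whose IoU clears an acceptability cutoff (0.5), and
reports the mean IoU as a percentage — both per sampling round and
pooled over all evaluated images.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_SAMPLE_SIZES = (25, 50, 75, 100)


def iou(target: np.ndarray, prediction: np.ndarray) -> float:
    """Intersection-over-union of two binary masks.

    |target AND prediction| / |target OR prediction|, in [0, 1].
    Symmetric in its arguments.  Two empty masks agree perfectly on
    absence, so that degenerate case returns 1.0 (with a warning).

    Raises
    ------
    ValueError
        On mask dimension mismatch.
    """
    target = np.asarray(target).astype(bool)
    prediction = np.asarray(prediction).astype(bool)
    if target.shape != prediction.shape:
        raise ValueError(
            f"mask shapes differ: {target.shape} vs {prediction.shape}")
    union = np.count_nonzero(target | prediction)
    if union == 0:
        warnings.warn("both masks empty: IoU defined as 1.0", stacklevel=2)
        return 1.0
    inter = np.count_nonzero(target & prediction)
    return inter / union


@dataclass
class IoUReport:
    """Per-algorithm acceptability counts and IoU summaries."""

    sample_sizes: tuple[int, ...]
    cutoff: float
    #: algorithm -> list of acceptable-image counts, one per sample size
    counts: dict[str, list[int]] = field(default_factory=dict)
    #: algorithm -> mean IoU (percent) per sampling round
    round_means: dict[str, list[float]] = field(default_factory=dict)
    #: algorithm -> mean IoU (percent) pooled over all evaluated images
    average_iou: dict[str, float] = field(default_factory=dict)
    #: algorithm -> every per-image IoU value, in evaluation order
    per_image: dict[str, list[float]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Table-shaped summary: one row per algorithm."""
        rows = []
        for name in self.counts:
            row = {"algorithm": name}
            for size, count in zip(self.sample_sizes, self.counts[name]):
                row[f"n{size}"] = count
            row["average_iou"] = self.average_iou[name]
            rows.append(row)
        return pd.DataFrame(rows)


def evaluate(algorithms: dict, dataset, *,
             sample_sizes=DEFAULT_SAMPLE_SIZES, cutoff: float = 0.5,
             seed: int = 0) -> IoUReport:
    """Run the sampling evaluation protocol.

    Parameters
    ----------
    algorithms : dict
        Name -> callable ``f(image, x) -> mask``.
    dataset : sequence of (image, x, truth_mask)
        Pool of evaluation images with their capture-order index and
        ground-truth canopy mask.
    sample_sizes : sequence of int
        Evaluation rounds, each drawing this many images.  Rounds are
        mutually exclusive (one seeded shuffle, consecutive slices)
        when the pool is large enough; otherwise each round is an
        independent seeded draw without replacement within the round.
    cutoff : float
        IoU above this value counts the image as acceptably segmented.
    seed : int
        Seed for the sampling; fixed seed gives an identical report.

    Returns
    -------
    IoUReport
    """
    dataset = list(dataset)
    n = len(dataset)
    sizes = tuple(sample_sizes)
    if n < max(sizes):
        raise ValueError(f"dataset of {n} images cannot fill a sample "
                         f"of {max(sizes)}")
    rng = np.random.default_rng(seed)
    if n >= sum(sizes):
        order = rng.permutation(n)
        pos, rounds = 0, []
        for size in sizes:
            rounds.append(order[pos:pos + size])
            pos += size
    else:
        logger.info("pool of %d images cannot hold disjoint samples "
                    "totalling %d; rounds drawn independently", n, sum(sizes))
        rounds = [rng.choice(n, size=size, replace=False) for size in sizes]

    report = IoUReport(sample_sizes=sizes, cutoff=cutoff)
    for name, segment in algorithms.items():
        counts, round_means, scores = [], [], []
        for sample in rounds:
            round_scores = []
            for idx in sample:
                img, x, truth = dataset[idx]
                score = iou(truth, segment(img, x))
                round_scores.append(score)
            counts.append(int(sum(s > cutoff for s in round_scores)))
            round_means.append(100.0 * float(np.mean(round_scores)))
            scores.extend(round_scores)
        report.counts[name] = counts
        report.round_means[name] = round_means
        report.average_iou[name] = 100.0 * float(np.mean(scores))
        report.per_image[name] = scores
    return report
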