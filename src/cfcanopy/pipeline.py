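"""End-to-end pipeline: segment -> texture traits -> evaluation -> analysis.

``RunConfig`` gathers every tunable of the stages (frame, threshold
polynomial, GLCM settings, evaluation protocol, analysis options) and
round-trips through YAML/JSON so a run is reproducible from its config
file alone.  ``run_pipeline`` executes the stages over a manifest of
images, isolating per-image failures, and writes masks, the trait
table, evaluation and analysis CSVs, and a log of the parameters used
(including the dynamic threshold applied to each image).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import evaluation, segmentation, texture, trait_analysis
from .preprocessing import load_image, standardize
from .thresholding import ThresholdModel, dynamic_threshold

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    frame: tuple[int, int] = (347, 260)
    threshold: ThresholdModel = field(default_factory=ThresholdModel)
    gst_t: float = segmentation.DEFAULT_GST
    glcm: texture.GLCMConfig = field(default_factory=texture.GLCMConfig)
    sample_sizes: tuple[int, ...] = evaluation.DEFAULT_SAMPLE_SIZES
    iou_cutoff: float = 0.5
    seed: int = 0
    correlation_method: str = "pearson"
    linkage_methods: tuple[str, ...] = trait_analysis.LINKAGE_METHODS
    n_clusters: int = 3
    rgb_weights: tuple[float, float, float] = (0.299, 0.587, 0.114)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["threshold"] = dataclasses.asdict(self.threshold)
        d["glcm"] = dataclasses.asdict(self.glcm)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "threshold" in d:
            d["threshold"] = ThresholdModel(**d["threshold"])
        if "glcm" in d:
            g = dict(d["glcm"])
            if "offset" in g:
                g["offset"] = tuple(g["offset"])
            d["glcm"] = texture.GLCMConfig(**g)
        for key in ("frame", "sample_sizes", "linkage_methods", "rgb_weights"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def save(self, path) -> None:
        path = Path(path)
        text = (json.dumps(self.to_dict(), indent=2)
                if path.suffix == ".json"
                else yaml.safe_dump(self.to_dict(), sort_keys=False))
        path.write_text(text)

    @classmethod
    def load(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        d = (json.loads(text) if path.suffix == ".json"
             else yaml.safe_load(text))
        return cls.from_dict(d)


def write_mask(mask: np.ndarray, path) -> None:
    """Save a {0, 1} mask as a 0/255 grayscale PNG."""
    Image.fromarray((np.asarray(mask) * 255).astype(np.uint8)).save(path)


def read_mask(path) -> np.ndarray:
    """Load a 0/255 PNG mask back to {0, 1}."""
    return (np.asarray(Image.open(path)) > 127).astype(np.uint8)


def read_manifest(path) -> pd.DataFrame:
    """Manifest CSV: image_path, x, mask_path[, condition] per row."""
    manifest = pd.read_csv(path)
    required = {"image_path", "x"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if manifest.empty:
        raise ValueError("manifest lists no images")
    return manifest


def run_pipeline(config: RunConfig, manifest: pd.DataFrame,
                 outdir) -> dict[str, Path]:
    """Execute segment -> features -> evaluate -> analyze over a manifest.

    Per-image failures are recorded and skipped; the run only fails if
    every image fails.  Deterministic for a fixed config (the only
    randomness, evaluation sampling, is seeded from the config).

    Returns a dict of output names to written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(exist_ok=True)
    log_lines: list[str] = [f"config: {json.dumps(config.to_dict())}"]
    outputs: dict[str, Path] = {}

    records, errors = [], []
    for row in manifest.itertuples(index=False):
        try:
            img = standardize(load_image(row.image_path), config.frame)
            x = int(row.x)
            t = dynamic_threshold(x, config.threshold)
            mask = segmentation.cfitkmeans(img, x, config.threshold)
            mask_path = outdir / "masks" / f"{Path(row.image_path).stem}_mask.png"
            write_mask(mask, mask_path)
            truth = None
            if getattr(row, "mask_path", None) and not pd.isna(row.mask_path):
                truth = standardize(read_mask(row.mask_path), config.frame,
                                    is_mask=True)
            condition = getattr(row, "condition", "unknown")
            records.append((row.image_path, img, x, t, mask, truth, condition))
            log_lines.append(f"{row.image_path}: x={x} threshold={t:.4f} "
                             f"canopy_px={int(mask.sum())}")
        except Exception as exc:  # isolate per-image failures
            errors.append((getattr(row, "image_path", "?"), str(exc)))
            log_lines.append(f"{getattr(row, 'image_path', '?')}: ERROR {exc}")
    if not records:
        raise RuntimeError(f"all {len(errors)} images failed; "
                           f"first error: {errors[0]}")

    table = texture.extract_table(
        [(img, mask, cond) for _, img, _, _, mask, _, cond in records],
        config.glcm)
    features_path = outdir / "features.csv"
    table.to_csv(features_path, index=False)
    outputs["features"] = features_path

    evaluable = [(img, x, truth) for _, img, x, _, _, truth, _ in records
                 if truth is not None]
    if len(evaluable) >= max(config.sample_sizes):
        algos = {
            "cfitkmeans": lambda im, x: segmentation.cfitkmeans(
                im, x, config.threshold),
            "gst": lambda im, x: segmentation.baseline_segment(
                im, "gst", gst_t=config.gst_t),
            "gat": lambda im, x: segmentation.baseline_segment(im, "gat"),
            "kmeans4": lambda im, x: segmentation.baseline_segment(
                im, "kmeans4"),
        }
        report = evaluation.evaluate(
            algos, evaluable, sample_sizes=config.sample_sizes,
            cutoff=config.iou_cutoff, seed=config.seed)
        report_path = outdir / "iou_report.csv"
        report.to_frame().to_csv(report_path, index=False)
        outputs["iou_report"] = report_path
        log_lines.append(f"evaluation: {report.average_iou}")
    else:
        log_lines.append("evaluation skipped: not enough ground-truth masks")

    if len(table) >= 3:
        summary = trait_analysis.correlations(table, config.correlation_method)
        cat_path = outdir / "correlation_categories.csv"
        pd.DataFrame(
            [{"category": label, "traits": ";".join(traits)}
             for label, traits in summary.categories.items()]
        ).to_csv(cat_path, index=False)
        outputs["correlation_categories"] = cat_path
        log_lines.append(f"correlation rule: {summary.membership_rule}")
        if len(table) > len(texture.FEATURE_NAMES):
            kmo_val = trait_analysis.kmo(table)
            chi2, df, pval = trait_analysis.bartlett_sphericity(table)
            log_lines.append(f"kmo={kmo_val:.4f} bartlett_chi2={chi2:.2f} "
                             f"df={df} p={pval:.3g}")
        schedule, _ = trait_analysis.agglomerate(table, "nearest",
                                                 config.n_clusters)
        schedule_path = outdir / "agglomeration_schedule.csv"
        schedule.to_csv(schedule_path, index=False)
        outputs["schedule"] = schedule_path
        membership = trait_analysis.compare_linkages(table, config.n_clusters)
        membership_path = outdir / "cluster_membership.csv"
        membership.to_csv(membership_path, index_label="trait")
        outputs["membership"] = membership_path

    log_path = outdir / "run.log"
    log_path.write_text("\n".join(log_lines) + "\n")
    outputs["log"] = log_path
    return outputs
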