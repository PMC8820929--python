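# cfcanopy

Segmentation and texture-trait analysis of chlorophyll-fluorescence (CF)
wheat-canopy images, for plant phenotyping under water stress.

In CF imaging the photosynthetically active canopy appears as bright
pixels on a dark background, but the pot in which the plant grows also
fluoresces weakly (intensities roughly 11–17) and contaminates naive
segmentations. `cfcanopy` implements the **CfitK-means** hybrid
segmenter and the downstream trait-analysis stack:

1. **Dynamic curve-fit threshold.** The pot-elimination threshold drifts
   over the capture timeline and is modelled as a cubic in the image's
   capture-order index *x*:

   *T(x) = p₁x³ + p₂x² + p₃x + p₄*,
   with p₁ = 2.273·10⁻⁸, p₂ = −4.118·10⁻⁵, p₃ = 0.01699, p₄ = 11.95,
   clamped into the empirical range [11, 17]. Pixels below *T* are
   removed.

2. **Histogram-initialized 2-means.** The surviving intensities are
   clustered with K = 2 (≤ 20 Lloyd iterations) on normalized
   intensities. Centroids are not random: with `levels` the occupied
   histogram levels above the cutoff, the initial centroids are
   `mean(levels)` and `min(levels)`. The higher-centroid cluster is the
   canopy.

3. **23-trait GLCM panel.** A symmetric grey-level cooccurrence matrix
   (Ng = 9 levels, offset (0, 1)) is built over the segmented canopy
   and summarized by 23 Haralick-style traits (`autoc`, `contr`,
   `corrm`, `corrp`, `cprom`, `cshad`, `dissi`, `energ`, `entro`,
   `homom`, `homop`, `maxpr`, `sosvh`, `savgh`, `svarh`, `senth`,
   `dvarh`, `denth`, `inf1h`, `inf2h`, `homom1`, `indnc`, `idmnc`).

4. **Evaluation.** Segmenters (CfitK-means plus static-threshold, Otsu,
   and 4-means baselines) are scored by intersection-over-union (IoU)
   against ground-truth masks under a seeded random-sampling protocol
   (samples of 25/50/75/100, acceptability cutoff IoU > 0.5).

5. **Trait statistics.** Correlation matrices (Pearson/Spearman/
   Kendall) with range categorization, the Kaiser–Meyer–Olkin sampling
   adequacy measure, Bartlett's test of sphericity, and agglomerative
   clustering of the traits themselves (squared-Euclidean distances on
   z-scored instances) under seven linkage rules, with an SPSS-style
   agglomeration schedule and cross-linkage membership comparison.

Because the original image set is external, the package ships a
synthetic scene generator (`cfcanopy.synthetic_data`) that reproduces
the dataset's structure — zero background, a 11–17 pot band that is
more exposed under drought, and a canopy of truncated-Gaussian
intensities that brightens over a 60-day timeline — with exact
ground-truth masks, plus a planted-block trait-table generator for the
statistics layer.

## Worked example

```python
import cfcanopy as c
from cfcanopy.thresholding import dynamic_threshold

spec = c.SceneSpec(condition="drought", day=25, seed=42)
img, canopy_truth, pot = c.make_canopy_image(spec)

t = dynamic_threshold(25)              # 12.3494
mask = c.cfitkmeans(img, x=25)
print(c.iou(canopy_truth, mask))       # 1.0

traits = c.extract_features(img, mask)
print(traits["contr"], traits["energ"])  # 0.0051 0.9899
```

The threshold at capture index 25 is 12.3494 intensity units; it strips
the background and the dim half of the pot, and the K-means stage
assigns the remaining pot pixels to the background cluster, so the
recovered mask matches the 8659-pixel ground-truth canopy exactly
(IoU = 1.0). The trait vector shows the near-uniform texture of a
noiseless synthetic canopy: very low contrast (0.0051), energy close
to 1 (0.9899).

For the statistics layer:

```python
table = c.make_feature_table(200, within_r=0.9, between_r=0.0, seed=11)
print(c.kmo(table))                    # 0.9663
print(c.bartlett_sphericity(table))    # (8210.7, 253, 0.0)
print(c.compare_linkages(table, k=3))  # identical membership, all 7 linkages
```

A planted three-block trait table (within-block correlation 0.9) is
highly factorable (KMO 0.97, Bartlett χ² = 8210.7 on 253 df, p ≈ 0) and
all seven linkage rules unanimously recover the planted 15/6/2 split.

The same pipeline is scriptable from the shell:

```sh
cfcanopy simulate --condition drought --days 60 --seed 7 outdir/
cfcanopy run outdir/manifest.csv results/
```

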