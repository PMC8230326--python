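# nucseg

Does image bit depth matter for deep-learning-style nuclei instance
segmentation of fluorescence-stained (e.g. DAPI) microscopy images?
`nucseg` is a tested, reusable pipeline for studying exactly that
question: it generates synthetic 16-bit fluorescence nuclei scenes with
exact ground truth, requantizes them to 2–16 bits, applies the four
standard intensity-normalization variants, segments nuclei with a
two-stage method merged by marker-controlled watershed, scores the
results with Dice / AJI / PQ, and runs paired Wilcoxon signed-rank
comparisons with Bonferroni correction across cross-validation folds.

It is aimed at microscopy image-analysis researchers who want a
desk-scale, fully reproducible harness for bit-depth and preprocessing
ablations, without needing the original datasets or GPU training.

## The method

**Preprocessing.** A raw b-bit image `X` is normalized four ways:

* D1: `X / (2^b − 1)`
* D2: D1 followed by 99th-percentile outlier clipping, rescaled to [0, 1]
* D3: min/max normalization `(X − X_min) / (X_max − X_min)`
* D4: 99th-percentile clipping on the raw image, then min/max normalization

Bit-depth reduction maps 16-bit to b-bit pixels by
`round(X / 2^(16−b))`, clamped into `[0, 2^b − 1]`.

**Segmentation.** Stage one predicts the foreground (background
detection); stage two regresses the per-object normalized Euclidean
distance transform (separating touching nuclei). The two maps are merged
by a watershed: threshold the foreground map, seed from the h-maxima of
the distance map, flood the negated distance map. A deterministic
classical backend (Otsu threshold + exact EDT) and a seeded trainable
backend satisfy the same predictor contract.

**Evaluation.** For ground truth `G` with instances `G_i` and prediction
`S` with instances `S_l`:

* Dice = `2|S∩G| / (|S| + |G|)`
* AJI = `Σ_i |G_i ∩ S̃(i)| / (Σ_i |G_i ∪ S̃(i)| + Σ_{l∈U} |S_l|)`, where
  `S̃(i)` maximises the Jaccard index with `G_i` and `U` indexes unused
  predictions
* PQ = `2·TP / (2·TP + FN + FP) × mean IoU over matches`, with matches at
  IoU > 0.5

An image with empty ground truth but a non-empty prediction scores 0 on
all three indices; study summaries flag such degenerate images.

**Statistics.** Per-image scores from two experiments run on identical
scenes, folds and seeds are compared with the two-sided Wilcoxon
signed-rank test per metric; with three metrics, the Bonferroni-adjusted
significance level is 0.05 / 3 ≈ 0.017.

## Worked example

Run the bit-depth study on 16 synthetic 63×-oil scenes (classical
backend, D4 preprocessing, five-fold cross-validation):

```sh
nucseg study --preset 63x_oil --n 16 --seed 7 --depths 2,4,8,16 --out study_out
```

prints

```
           dice_mean  dice_sd  aji_mean  aji_sd  pq_mean   pq_sd
bit_depth
2             0.8777   0.0519    0.7199  0.1004   0.7165  0.0950
4             0.9908   0.0123    0.8706  0.0905   0.9037  0.0629
8             0.9833   0.0060    0.8578  0.0860   0.8902  0.0589
16            0.9830   0.0061    0.8576  0.0862   0.8898  0.0593
8 vs 16 bit Wilcoxon p-values: {'dice': 0.083251953125, 'aji': 0.49542236328125, 'pq': 0.2978515625}
```

Reading it: 8-bit and 16-bit performance are statistically
indistinguishable (mean AJI differs by 0.0002; no p-value approaches the
0.017 Bonferroni level), while 2-bit quantization visibly degrades
instance segmentation (mean AJI drops from 0.86 to 0.72). The directory
also receives `sweep.csv`, `comparison.json` and
`difference_vs_count.csv` (per-image |ΔAJI| / |ΔPQ| against nuclei
count).

Single images work the same way through the library:

```python
from nucseg import PRESETS, classical_predictor, evaluate, make_variant, segment
from nucseg.synthetic import generate_scene

scene = generate_scene("63x_oil", (256, 256), seed=42)
norm = make_variant(scene.image, "D4")
pred = segment(norm, classical_predictor("foreground"), classical_predictor("distance"))
print(evaluate(scene.labels, pred))
# MetricsRecord(dice=0.988, aji=0.898, pq=0.928, n_gt=24, n_pred=23, degenerate_flag=False)
```

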