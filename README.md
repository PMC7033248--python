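# adenoquant

Semi-automated adenoma quantification in the *Apc*^Min^ mouse from
photographs of spread small-intestine (SI) tissue.

Tumour burden in *Apc*^Min^ mice is classically measured by counting
adenomas by eye under a stereomicroscope — slow, hard to standardise,
and blind to tumour size. `adenoquant` implements the alternative
workflow in which the opened SI is spread on blue card, photographed
with a ruler for scale, and processed automatically:

1. **Segmentation** — the blue background is subtracted (pixels whose
   blueness `B − max(R, G)` exceeds an adaptive cut are zeroed), the
   grey image is thresholded by iterative intermeans, despeckled with a
   3×3 median filter, and connected components over 0.2 mm² become
   candidate adenoma "image features".
2. **Morphometry** — each feature gets 22 particle-analysis measures:
   Area, Perim, Mean, StdDev, Mode, Min, Max, Median, Skew, Kurt,
   Major, Minor, Angle, Circ (`4πA/P²`), AR, Round (`4A/(π·Major²)`),
   Solidity (area / convex-hull area), Feret, FeretAngle, MinFeret,
   IntDen (`Area·Mean`), RawIntDen.
3. **Classification** — features verified by a researcher as adenoma
   (Ad) or not (nAd) train a linear discriminant on log-/shifted-log-
   transformed measures *and their squares* (so the boundary can be
   quadratic in the original measure space):
   `δ_k(x) = log π_k − ½ (x − μ_k)ᵀ S⁻¹ (x − μ_k)`, with pooled
   within-class covariance S and empirical priors π_k. A PCA-based QC
   flags mice whose per-mouse barycentre on PC1–PC2 indicates a
   batch-biased preparation.
4. **Validation** — mice (not features) are resampled with replacement
   until ≥ 12 draws and ≥ 750 features accumulate (datasets with < 30%
   of either class rejected); 4000 such datasets each train their own
   discriminant, and the quantiles (0/5/25/50/75/95/100%) of ACC,
   per-class TPR/PPV and the predicted-over-true count ratios
   (Ad.ratio, nAd.ratio) summarise stability.
5. **Method comparison** — per-mouse adenoma count and total area from
   the manual (DRAW), verified (CALL) and automatic (LDA) methods are
   compared by Deming regression at variance ratio 1 (errors in both
   variables) with BCa bootstrap confidence intervals (n = 999).

A synthetic-data module generates ground-truthed photographs (soft-edged
elliptical lesions on noisy blue card, plus rolled-edge streaks, fat
patches and reflections as distractors) and mouse-nested feature tables
at the scale of a 117-mouse study, so the whole stack is testable
without any image download.

## Worked example

```python
import adenoquant as aq

# a calibrated synthetic photograph with 10 planted lesions
img, truth = aq.generate_image(aq.SynthImageSpec(seed=1, n_lesions=10))
features, mask = aq.run_featurecounter(img)
print(len(features), round(features[0].Area, 3), round(features[0].Circ, 3))
# 10 0.753 0.968

# a study-scale feature table: 117 mice, ~27 features each, 40% Ad
table = aq.generate_table(aq.SynthTableSpec(seed=1))
spec = aq.default_spec(table)
X, y, mice = aq.build_design_matrix(table, spec)
model = aq.train_lda(X, y)
calls, posteriors = aq.predict(model, X)
ind = aq.compute_indicators(y.to_numpy(), calls.to_numpy())
print(round(ind.ACC, 3), round(ind.TPR_Ad, 3), round(ind.Ad_ratio, 3))
# 0.878 0.823 0.945
```

The first block finds all ten planted lesions; `Area` is in mm² and
`Circ` near 1 means a round lesion. In the second block the
discriminant reproduces the working point expected of this pipeline on
verified data: ≈ 88% of features correctly classified, ≈ 82% of true
adenomas detected, and a dataset-level Ad count within ≈ 6% of the
verified count (`Ad_ratio` 0.945).

The same stages are available as a command-line tool:

```bash
adenoquant simulate table --seed 1 --out table.csv
adenoquant validate --table table.csv --n-datasets 4000 --seed 1 --out quantiles.csv
adenoquant segment photo.png --scale-mm-per-px 0.05 --out features.csv --mask mask.png
```

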