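# fetalbrain

Multi-tissue fetal brain MRI segmentation and gestational-age estimation,
built to run end to end on synthetic phantoms.

Quantitative analysis of the developing fetal brain starts from multi-tissue
segmentation of T2-weighted MRI reconstructions — seven tissues: external
CSF (ECF), cortical gray matter (FGM), white matter (WM), ventricles (VC),
cerebellum (CBM), deep gray matter (DGM) and brainstem (BSTM) — and feeds
downstream estimates such as gestational age (GA, in weeks).  This package
implements:

* **Multi-view 2D segmentation.**  One encoder-decoder network per
  anatomical view (axial, sagittal, coronal), built from inception-residual
  encoder blocks (multi-scale 1x1 / 3x3 / 5x5 branches with batch norm and
  a residual path) and dense spatial attention gates
  (`out = x * gate * swish(x)`, the gate produced by a 12-block densely
  connected chain over channel-pooled maps), with multi-scale routing of
  stage features into the bottleneck.  Per-slice predictions are stacked
  into per-view score volumes and fused per voxel (score-sum argmax, or
  label voting).  Trained with the Combo loss
  `L = alpha * CE_beta - (1 - alpha) * Dice` (alpha = beta = 0.5 by
  default) using Adam.  The attention design has roughly *half* the
  parameters of a plain UNet at equal width.  The networks run on a small
  NumPy automatic-differentiation core — no GPU or deep-learning framework
  required.
* **Three GA feature families + regression.**  18 radiomics features
  (shape, first-order, GLCM, NGTDM), 3D-convolutional-autoencoder latents,
  and segmentation-encoder deep features (256 per view, concatenated to
  768); random-forest / regression-tree / linear / gradient-boosted
  regressors; evaluation by RMSE (weeks) and concordance index; permutation
  feature importance.
* **Evaluation metrics.**  Dice, 95th-percentile symmetric Hausdorff
  surface distance (mm), sensitivity, specificity — per tissue and macro —
  all tested against brute-force oracles.
* **Synthetic phantoms.**  Seven-tissue nested-ellipsoid volumes whose
  geometry grows affinely with a known GA (weeks 20-33), with T2-like
  tissue contrast and Gaussian noise, so the full pipeline is testable
  without any clinical data.

## Worked example

```python
import numpy as np
from fetalbrain import (MultiViewSegmenter, RadiomicsExtractor, GAPredictor,
                        make_cohort, evaluate_segmentation)

cohort = make_cohort(10, seed=0, shape=(48, 48, 48))   # (image, labels, ga)
train, test = cohort[:8], cohort[8:]

seg = MultiViewSegmenter(variant="full", base_width=8, epochs=6, lr=3e-3,
                         batch_size=12, head="softmax", bg_stride=4,
                         rare_boost=4, seed=0)
seg.fit([im for im, _, _ in train], [lb for _, lb, _ in train])
pred = seg.predict(test[0][0])
report = evaluate_segmentation(test[0][1].labels, pred)
print(round(report.macro["dsc"], 3))

feats = RadiomicsExtractor().transform([(im, lb) for im, lb, _ in cohort])
ga = np.array([g for _, _, g in cohort])
rf = GAPredictor(algo="rf", seed=0).fit(feats[:8], ga[:8])
print(np.round(rf.predict(feats[8:]), 1), np.round(ga[8:], 1))
```

Output (a few minutes on one CPU; `head="softmax"` and the rare-slice
oversampling are what make the smallest tissues learnable in six epochs —
see `docs/methods.md`):

```
0.982
[28.  30.5] [27.1 32.2]
```

The first number is the held-out macro Dice over the seven tissues for the
fused multi-view prediction of one test phantom; the last lines compare the
random forest's GA predictions (weeks) with the phantoms' true GAs.

A command-line interface covers the same pipeline for NIfTI files on disk:

```sh
fetalbrain simulate --n 10 --seed 1 --out data/
fetalbrain train --view coronal --data data/ --epochs 6 --out coronal.ckpt
fetalbrain segment --image data/sub-000_T2w.nii.gz \
    --models axial.ckpt sagittal.ckpt coronal.ckpt --out pred.nii.gz
fetalbrain evaluate --pred pred.nii.gz --truth data/sub-000_dseg.nii.gz
fetalbrain radiomics --data data/ --out features.csv
fetalbrain predict-ga --features features.csv --targets data/ga.csv --out ga/
```

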