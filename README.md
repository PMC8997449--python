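# dermokit

A toolkit for multimodal analysis of pigmented skin lesions in dermoscopic
images. It combines:

- **Hair removal** (`dermokit.hair_removal`) — per-channel grayscale
  morphological closing (disk element, radius `r1=5`) highlights dark thin
  structures; subtraction, threshold zeroing (`K=40`, strict `> K`), and a
  dilation (`r2=3`) produce a hair mask whose pixels are then replaced by
  solving the discrete Laplace equation with Dirichlet boundary data from
  the surrounding skin.
- **Metadata encoding** (`dermokit.metadata`) — one-hot encoding of sex (2),
  anatomic site (8) and 5-year age group (18) into a 28-dimensional binary
  vector; missing fields become zero blocks.
- **Fusion classifier** (`dermokit.fusion`) — a small CNN image branch and a
  linear+ReLU metadata branch joined on a concatenation layer, with a
  softmax head over 10 diagnostic categories. Pure numpy with handwritten
  gradients; deterministic for a fixed seed.
- **Augmentation** (`dermokit.augmentation`) — affine transforms (rotation,
  shift, reflection, scaling, crop), bilinear resizing, affine-based class
  balancing, and a stratified 80/20 train/validation split.
- **Evaluation** (`dermokit.evaluation`) — 10-class confusion matrices, the
  6-benign/4-malignant grouping, TPR/FPR, ROC curves with trapezoidal AUC,
  and the McNemar paired test `(b−c)²/(b+c)`.
- **Synthetic fixtures** (`dermokit.synthetic`) — lesion images, hair
  overlays with pixel-exact ground-truth masks, and metadata tables, so the
  whole pipeline is testable without any image archive.

## CLI

All commands live under one entry point:

```sh
# generate a synthetic dataset (images, masks, manifest.csv)
dermokit synth --out data/ --n-per-class 10 --classes nevus,melanoma --hair-strokes 5 --seed 0

# clean hair from one image
dermokit hairremove --input lesion.png --output clean.png --mask-out mask.png --r1 5 --r2 3 --threshold 40

# one-hot encode a metadata CSV (columns: sex, anatom_site, age)
dermokit encode --input meta.csv --output vectors.csv --codebook codebook.json

# train / predict / evaluate on a manifest dataset
dermokit train --data data/ --out model.bin --epochs 50 --seed 0
dermokit predict --model model.bin --data data/ --out preds.csv
dermokit eval --preds preds.csv --truth data/manifest.csv --out report.json --roc roc.csv
```

## Notes

- The detector targets dark hair on lighter skin (the closing-based scheme
  cannot see bright hair); this is a documented limitation.
- Morphology clips structuring-element footprints at image borders (extrema
  over in-image pixels only).
- Only the `small_cnn` backbone is provided; pretrained AlexNet/SqueezeNet/
  ResNet-101 replication is out of scope.
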