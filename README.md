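# abruptcut

Objective quantification of **abrupt pigment-pattern cutoff** along the border
of a skin lesion in dermoscopy images — the dermoscopic "B" criterion — and
SVM-based malignancy classification built on it.

Given an RGB dermoscopy image and a binary lesion mask, the pipeline:

1. **channels** — decomposes the image into ten scalar channels
   (Gra, Red, Gre, Blu, Y, Cb, Cr, Hue, Sat, V; full-range BT.601 + hexcone HSV);
2. **maskprep** — standardizes the mask: complement, symmetric margin
   clipping, morphological opening, central-cluster selection;
3. **boundary** — traces the lesion border as a Freeman chain code
   (clockwise Moore-neighbor tracing) and exposes the boundary path and
   centroid;
4. **sampling** — places circular sampling regions at radii {5, 7, 10, 15}
   using one of three methods: circles on the boundary itself (method 1),
   on a vector-contracted inner border (method 2, with its documented
   collapse failure mode detected and reported), or on a dynamically scaled
   inner border (method 3, the default), intersected with the lesion;
5. **glcm** — computes gray-level co-occurrence matrices, homogeneity, and
   mean/std over each region;
6. **features** — assembles 240 features per image
   (10 channels × 4 radii × {avg, min} × {homogeneity, mean, std}) and
   normalizes tables to [−1, 1];
7. **model** — SVM-RFE feature ranking, per-channel total scores,
   elimination curves, and evaluation under model / leave-one-out /
   10-fold schemes with precision, recall, F-measure, sensitivity and
   specificity;
8. **synthetic** — a seeded generator of dermoscopy-like images with
   per-sector border edge width ("virtual pie"), standing in for clinical
   data in all tests and benchmarks.

## CLI

```sh
# generate a synthetic labeled dataset (images/, masks/, labels.csv)
abruptcut simulate --n-benign 69 --n-malignant 31 --seed 1 --out data/

# extract the 240-column feature table
abruptcut extract --images data/images --masks data/masks --out out/

# SVM-RFE ranking and per-channel total scores
abruptcut rank --features out/features.csv --out out/

# evaluate a scheme, optionally on a channel subset
abruptcut evaluate --features out/features.csv --scheme loo --channels blue,cr,green

# everything end to end
abruptcut run --images data/images --masks data/masks --out out/
```

Masks pair with images by filename stem (`<stem>_mask.png`). Pass
`--complement` when masks are negatives (lesion encoded as background).
Exit codes: 0 success, 2 configuration error, 3 data error.

## Notes

- The clip-rectangle margin is implemented as `round(dim · p / 200)`; the
  literal published formula is available behind `literal_formula=True` but is
  dimensionally inconsistent and rejected at validation.
- GLCM homogeneity defaults to the standard 1/(1+|i−j|)-weighted form;
  `mode="paper_literal"` reproduces the unweighted printed formula (constant
  1 under probability normalization).
- Precision is the standard TP/(TP+FP).
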