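# cardiot1

Automated analysis of myocardial native T1 mapping images: fully
convolutional myocardium segmentation, shape quality control, implicit
motion alignment by polar resampling, pixel-wise inversion-recovery
fitting, and agreement statistics — validated end to end on a synthetic
cardiac phantom with exact ground truth.

## The problem

Native T1 mapping quantifies diffuse myocardial fibrosis from a set of
T1-weighted short-axis images acquired at different inversion times (TI).
Conventional analysis needs manual contouring of the myocardium and
explicit motion correction before the per-pixel relaxation fit — slow, and
a source of observer variability.  This package automates the chain:

1. **Segment** each T1-weighted image `I_k(x,y)` with a U-Net-style fully
   convolutional network → binary myocardium mask `B_k(x,y)`.
2. **Quality-control** each mask: drop components under 5 cm², require an
   annular shape (Euler number 0, eccentricity ≤ 0.65); refine improper
   masks by affine alignment of the longest-TI mask, or exclude them.
3. **Resample** each segmented ring onto a 20 × 360 polar grid centred at
   its own centre of mass — translation of the heart moves the origin with
   it, so the images align implicitly, with no registration step.
4. **Fit** the magnitude inversion-recovery model
   `S(TI) = A·|1 − 2·e^(−TI/T1)|` per polar cell over all TIs (slices with
   fewer than 8 usable images are rejected), inverse-transform the T1 map
   onto the shortest-TI reference image.
5. **Summarize**: prune to a mid-wall band (skeleton dilated to ⅓ of the
   mean wall thickness), average T1 within the 850–1500 ms native window.

The TI schedule models a slice-interleaved free-breathing acquisition:
∞, 115, 115+RR, …, 115+4·RR, 350, …, 350+4·RR ms (11 images per slice).

Since no patient data ships with the package, a phantom module renders
annular-myocardium stacks with known T1 field, motion trace and masks, at
realistic tissue contrast, so every stage is testable against ground truth.

## Worked example

```python
import numpy as np
from cardiot1 import (PhantomConfig, render_stack, T1wStack,
                      TruthMaskSegmenter, RunConfig, process_slice,
                      summarize_t1)

cfg = PhantomConfig(grid_size=128, center=(63.5, 63.5), r_endo=12,
                    r_epi=20, noise_sd=0.02, motion_amplitude=5.0, seed=1)
stack, truth = render_stack(cfg)                  # 11 images + ground truth
st = T1wStack(images=stack, tis=truth.ti_schedule,
              pixel_spacing=cfg.pixel_spacing)

order = np.argsort(st.tis)
seg = TruthMaskSegmenter([truth.masks_per_ti[k] for k in order])
res = process_slice(st, seg, RunConfig(n_rays=180))
summary = summarize_t1([res.t1_map], [res.pruned_mask])
print(f"reconstructed: {res.reconstructed}")
print(f"global T1 = {summary.global_t1:.1f} ms "
      f"({summary.n_pixels_used} px used, "
      f"{summary.n_pixels_excluded} excluded)")
```

Output:

```
reconstructed: True
global T1 = 1099.7 ms (267 px used, 0 excluded)
```

The phantom's myocardial T1 is 1100 ms; despite ±5 px of per-image motion
the polar alignment recovers the global value to well under a millisecond
of bias at this noise level — the implicit-motion-correction property at
the heart of the design.

To train the segmenter instead of using ground-truth masks:

```python
from cardiot1 import UNetSegmenter
est = UNetSegmenter(input_size=64, depth=3, base_kernels=8, dropout_p=0.1,
                    iterations=300, batch_size=8, seed=0)
est.fit(X_train, y_train)       # (n, 64, 64) images and binary masks
masks = est.predict(X_test)
```

A command-line interface wraps the same functionality:
`cardiot1 phantom`, `cardiot1 train`, `cardiot1 segment`, `cardiot1 run`,
`cardiot1 eval` (see `cardiot1 --help`).

## Layout

```
src/cardiot1/
  phantom.py    synthetic stacks with ground truth
  segnet.py     U-Net-style segmenter (NumPy, sklearn-style estimator)
  _nn.py        conv/batch-norm/dropout layers with manual backprop
  shapeqc.py    area filter, Euler/eccentricity gate, affine refinement
  polar.py      forward/inverse polar transform
  t1fit.py      pixel-wise IR fitting, pruning, T1 summaries
  evalstats.py  Dice, Bland-Altman, zero-intercept slope, ICC
  pipeline.py   per-slice / per-patient orchestration
  io.py         NIfTI/DICOM/PNG readers and writers
  cli.py        command-line interface
docs/methods.md   the full methods note
```
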