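# Methods

`cardiot1` implements a fully automated analysis chain for myocardial
native T1 mapping from slice-interleaved inversion-recovery acquisitions:
segmentation of the left-ventricular myocardium in every T1-weighted image,
shape quality control with affine refinement, implicit motion alignment by
polar resampling, pixel-wise two-parameter curve fitting, mid-wall pruning,
and global/regional T1 statistics.  A synthetic phantom with exact ground
truth drives all validation; no patient data is required or included.

## Signal model

Each T1-weighted magnitude image is modelled as ideal magnitude inversion
recovery with perfect inversion,

    S(TI) = A · |1 − 2 · exp(−TI / T1)|,

with two free parameters per pixel: the equilibrium amplitude `A` (arbitrary
signal units) and the longitudinal relaxation time `T1` (ms).  One image of
the eleven-image schedule is acquired without inversion preparation; it is
treated as TI = ∞ and enters every computation analytically as `S = A`
(the sentinel is never pushed through the exponential).  The inversion-time
schedule for a cardiac cycle of length RR is

    ∞, 115, 115+RR, …, 115+4·RR, 350, 350+RR, …, 350+4·RR   (ms),

eleven values in total; RR defaults to 1000 ms.

Whether the acquisition's inversion efficiency differs from the ideal
factor 2 is not observable at this level; the factor is fixed at 2 and the
choice is isolated in `phantom.ir_signal` / the fitting model so a different
efficiency would be a one-line change.

## Phantom

The phantom is a concentric annulus (myocardium, T1 1100 ms) around a
blood pool (T1 1600 ms) on a background (T1 300 ms), on a 256 × 256 grid at
2.1 × 2.1 mm pixels.  Relative proton densities are 1.0 (myocardium),
1.6 (blood), 0.2 (background), so the blood pool is brighter than the
myocardium at every TI and, in particular, the non-inverted (TI = ∞) image
has the highest myocardium-to-blood contrast of the stack — with a uniform
amplitude this image would have *no* tissue contrast at all, since every
tissue recovers to the same equilibrium.  Respiratory motion is emulated as
a per-image rigid translation drawn uniformly within ± the configured
amplitude and rounded to whole pixels; noise is additive zero-mean Gaussian
on the magnitude signal (Rician optionally, for low-SNR work).  Elliptical
and broken-ring (C-shaped) variants exercise the shape-QC gate.

What the phantom does **not** emulate: real torso anatomy and coil shading,
through-plane motion, cardiac deformation, partial-volume mixtures beyond
the discrete pixel edge, k-space/SENSE artefacts, and the intensity
statistics of parallel-imaging reconstructions.  Passing phantom tests
therefore demonstrates correctness of the numerics and the pipeline logic,
not clinical segmentation performance.

## Segmentation network

The segmenter is an encoder–decoder fully convolutional network with skip
connections built from "bottleneck" units: batch normalization → ReLU →
3 × 3 convolution, with dropout inside each unit.  Kernel counts double at
each down-sampling (2 × 2 max pool) and halve at each up-sampling (nearest
neighbour); a final 1 × 1 convolution produces two channels and a softmax
gives per-pixel background/myocardium probabilities.  The predicted mask is
the strict `p > 0.5` myocardium set, so an exact tie resolves to background.
Inference is deterministic: dropout is inactive and batch norm uses frozen
running statistics.

The network is implemented directly in NumPy (`cardiot1._nn`): im2col/GEMM
convolutions with exact adjoint scatter-add backward passes, verified
against finite differences in the test suite.  Training minimizes mean
pixel-wise cross entropy with Adam (learning rate 0.001, β₁ 0.9, β₂ 0.999)
and L2 weight decay 0.001.  Augmentation applies random translation,
mirroring and elastic deformation with probabilities 0.95 / 0.95 / 0.5,
geometric only, identically to image and label, re-binarizing the label
after interpolation.  Elastic fields are Gaussian-smoothed uniform noise
(σ = 6 px, amplitude 8 px), chosen so deformed annuli remain annular.

Two presets are provided.  `PAPER_SCALE` (depth 5, 34 base kernels,
256 × 256 input) reproduces the published geometry at ≈ 8.9 million
parameters.  `TINY` (depth 3, 8 base kernels, 64 × 64 input, 300
iterations, batch 8) is the CPU benchmark configuration used throughout the
tests; its dropout is reduced to 0.1 because a 50 % rate starves a network
this narrow — with 8 kernels per layer, dropping half of them removes whole
feature directions rather than regularizing.  On 200 random-geometry
phantom pairs the tiny preset reaches a held-out Dice ≥ 0.90 in 300
iterations (≈ 2 min on one CPU).

## Shape quality control

After segmentation, connected components with physical area below 5 cm²
(pixel count × spacing², strict less-than) are removed and only the largest
survivor kept.  A mask is anatomically proper iff it is non-empty, its
Euler number (components − holes; 8-connected foreground, 4-connected
holes) is 0, and the eccentricity of its second-moment ellipse is ≤ 0.65.
Eccentricity is computed on the annulus as segmented, not on its filled
hull; the moment ellipse of a ring tracks the epicardial outline, which is
the quantity the elongation bound is meant to police.

An improper mask is refined by affinely aligning the longest-TI mask onto
it (that image segments most reliably).  The search maximizes Dice overlap
over translation ±10 px, rotation ±15°, scale 0.9–1.1: a coarse grid
(1 px / 3° / 0.05) in which each rotation–scale candidate's translations
are evaluated exhaustively by FFT cross-correlation (the correlation of two
binary images at a shift *is* their intersection area), followed by a local
5 × 5 rotation–scale polish between the best grid nodes.  The identity is
always a candidate, so refinement never returns less overlap than the
untransformed reference.  If the longest-TI mask is itself improper, or the
improper mask is empty, no refinement is possible and the image is excluded.
A segmentation counts as successful iff a proper mask results, with or
without refinement.

## Polar resampling and implicit motion alignment

Each successfully segmented image is resampled onto a C × 360 polar grid
(C = 20, chosen above the maximum plausible wall thickness of 15 px so the
transform is one-to-one in radius) centred at that image's **own** mask
centre of mass.  Because the origin travels with the mask, a global
translation of the heart leaves the polar image unchanged — this replaces
explicit registration.  360 rays at 1° spacing run from the origin outward;
on each ray the innermost contiguous myocardium run defines the
endocardial/epicardial boundaries (noise specks beyond the wall are
ignored; rays through the gap of a broken ring are flagged invalid and
excluded).  Boundaries are located as sub-pixel 0.5-level crossings of the
bilinearly interpolated mask, then pulled half a pixel inward (at most a
quarter wall each) before sampling, because samples on the discrete edge
itself would average blood-pool or background intensity into the wall.  The
C samples span the inset boundaries inclusively, bilinearly interpolated.
The angle convention is 0° along +x, counter-clockwise in array space.

The inverse transform maps each foreground pixel of the shortest-TI
reference mask to (angle, normalized radius) and bilinearly interpolates
the polar T1 map with angular wrap-around; pixels radially outside the
sampled band would extrapolate and are excluded from the map support.
Round-tripping a smooth radial field through both transforms reproduces it
to ≈ 1 % of its range (tested at 2 %).

## T1 map reconstruction

Per polar cell, (A, T1) are fitted by bounded nonlinear least squares
(T1 ∈ [100, 3000] ms, A > 0) over the TIs whose image passed QC and whose
ray is valid.  The magnitude model has local minima at its null points, so
initialization matters: the residual is first scanned over an 80-node
geometric T1 grid using the closed-form optimal A at each node (the model
is linear in A), and the refinement starts from the best node.  The grid is
dense enough that consecutive nodes bracket every null-point basin, which
makes the scan + single refine as robust as a multi-start while being about
five times faster; a 500-replicate comparison against an exhaustive
1 ms × 0.001 2-D grid search agrees to well under 1 ms mean absolute error.

A slice map is reconstructed only when at least 8 of the 11 images
segmented successfully; the same floor applies per cell to the number of
valid observations (a conservative per-cell extension of the slice rule).
Cells with non-converged fits or fits pinned at the T1 bounds are invalid.

The reconstructed map is inverse-transformed onto the shortest-TI reference
grid.  For the summary statistics, the mask is pruned to a mid-wall band:
the skeleton of the ring dilated with a disk of radius
`round(wall/3 / 2)` — a full band width of one third of the mean wall
thickness (mean over valid rays of epi − endo radius).  The band width is
interpreted as the *full* retained width, mimicking manual avoidance of
sub-endocardial/epicardial partial-volume pixels; the fraction is a
configuration field.  Global T1 is the mean over all pruned pixels of all
reconstructed slices whose value lies inside the native-T1 acceptance
window at 1.5 T, 850–1500 ms inclusive; regional (per-slice) means use the
same window, and exclusion counts are reported.

## Agreement statistics

Dice = 2|A∩B|/(|A|+|B|), with two empty masks defined as 1 (perfect
agreement about absence).  Bland–Altman reports the mean difference and
bias ± 2 SD limits of agreement — the conventional 1.96 is deliberately
rounded to 2.  Correlation reports the ordinary Pearson r together with the
zero-intercept least-squares slope Σxy/Σx².  The intraclass correlation
defaults to the two-way random-effects, absolute-agreement, single-measure
variant ICC(2,1) (computed via pingouin, F-based 95 % CI); the variant is a
parameter because conventions differ between studies.

## Numerical and benchmark choices

* All subpixel sampling in the polar transforms and refinement is bilinear;
  labels are re-binarized at 0.5 after any interpolation.
* Phantom benchmark scales: unit tests run slices at grid 128 with 90–180
  rays; the full 256-grid, 360-ray geometry is exercised where the test is
  about dimensions or alignment.  Segmenter benchmarks use 64 × 64 phantoms
  with the tiny preset.  These sizes are the package's reference benchmark
  conditions and are stated with each test.
* Determinism: every stochastic component (phantom noise and motion,
  weight initialization, batching, dropout, augmentation) draws from a
  seeded generator; identical seeds give bit-identical phantoms and
  training runs.
* Degenerate inputs: constant images cannot be intensity-normalized
  (error); empty masks cannot be assessed, centred, or polar-transformed
  (explicit errors); a slice whose pruned pixels are all outside the
  acceptance window yields NaN for that slice without affecting others.

## Known limitations

* The fitted model ignores inversion efficiency, saturation effects of the
  slice-interleaved readout, and Rician noise bias at low SNR; on real data
  these bias T1 at the few-ms level.
* The polar transform aligns translation exactly but non-rigid deformation
  only approximately (radial normalization absorbs uniform wall-thickness
  change, not shear).
* Eccentricity of strongly C-shaped but Euler-0 masks can pass the gate;
  the ray-validity fraction (slices with > 90 invalid rays are flagged
  unreliable) is the backstop.
* The NumPy network trains tiny configurations in minutes but is not
  suitable for full-scale 256 × 256 training; the architecture and recipe
  are identical at both scales, only throughput differs.
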