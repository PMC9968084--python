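# Methods

## Problem and approach

A volumetric macular OCT scan `I(x, y, z)` — `x` the fast-scan pixel within a
B-scan, `y` the B-scan index, `z` the axial (depth) index — can be collapsed
into a 2D *en-face* fundus image by averaging each A-scan over a depth window
bounded by retinal layer borders.  Superficial vessels are hyper-reflective
inside the ganglion-cell layer (GCL), while every voxel beneath a vessel is
attenuated, so the hyper-reflective outer bands (photoreceptor outer segments
and retinal pigment epithelium, OS+RPE) show vessels as dark shadows.  The
package implements:

1. layer-bounded axial projections `P_GCL` (NFL/GCL → GCL/IPL),
   `P_GCL+IPL` (NFL/GCL → IPL/INL) and `P_OS+RPE` (IS/OS → RPE/CHR);
2. three reconstruction variants: `P1 = P_OS+RPE`,
   `P2 = w1·P_OS+RPE + w2·f(P_GCL)` (defaults w1 = 1.7, w2 = 0.8) and
   `P3 = w1·P_OS+RPE + w2·f(P_GCL+IPL)` (defaults w1 = 2, w2 = 1.2);
3. a patch-based encoder–decoder vessel segmenter with the published
   per-network preprocessing/augmentation/training recipes as named presets;
4. dual-threshold iterative (DTI) refinement and a classical shadowgraph
   baseline;
5. confusion metrics, exact ROC/AUC, and k-fold cross-validation
   (24 scans → 6 folds of 20 train / 4 test for the study protocol).

## Coordinate and projection conventions

The axial orientation of clinical exports varies by device.  We declare `z`
increasing toward the choroid and compute every projection with an
**inclusive span and a voxel-count denominator**:

    P(x, y) = (1 / n) * Σ_{z=lo}^{hi} I(x, y, z),   n = hi − lo + 1

where `lo/hi` are the min/max of the two border indices.  This makes the
projection invariant to the z-orientation choice, reproduces constants
exactly, and handles zero-thickness spans (the foveal pit, where the inner
retina collapses) by returning the single border voxel instead of dividing
by zero.

## Weighted reconstructions: normalization and inner-term inversion

The outer projection renders vessels *dark* and the inner projection renders
them *bright*; summing the raw terms therefore partially cancels vessel
contrast.  By default each component projection is min–max normalized to
[0, 1] and the inner term is inverted (`f(p) = 1 − p`) before weighting, so
both terms agree in sign and the combination *enhances* the vessel network.
Normalizing first also makes the empirically tuned weights portable across
acquisition scalings.  The literal raw weighted sum (`f = identity`, no
normalization) remains available with `invert_inner=False`.

## Isotropic resampling

The study geometry (141 B-scans × 385 px over 7 × 7 mm) is anisotropic:
pitch 7/385 ≈ 0.0182 mm along the fast axis versus 7/141 ≈ 0.0496 mm across
B-scans.  `resample_isotropic` enlarges the coarser axis to the fast-axis
pitch (385 × 141 → 385 × 385) with bicubic interpolation by default; masks
use nearest-neighbour so they stay binary.  The finer axis is never
downsampled.

## Synthetic phantom

The generator emulates the features of a macular scan that the pipeline
actually exploits:

* **Layers** — nine ordered border surfaces built bottom-up from a gently
  undulating RPE/choroid interface; band thicknesses are fixed fractions of
  the axial extent, and a Gaussian pit profile thins the inner bands
  (NFL…OPL) to near zero at the center (`pit_depth_px` defaults to roughly
  the inner-stack height, so the pit genuinely exposes the outer retina).
* **Vessels** — correlated random walks entering from the image borders,
  steering around a foveal avascular disc, dilated to widths drawn from
  1–5 px (1-px vessels are kept: the thinnest real vessels are a single
  pixel at this resolution).  The en-face mask is the exact rasterized
  ground truth.
* **Contrast physics** — vessel voxels inside the GCL band are multiplied by
  a brightness gain (1.6); beyond a configured eccentricity the gain also
  applies in the IPL band, mirroring how vessels dive deeper away from the
  fovea; all voxels below the vessel-bearing band in vessel columns are
  multiplied by the shadow attenuation (0.45).
* **Speckle** — unit-mean multiplicative gamma noise, shape 4 (amplitude
  contrast ≈ 0.5, a standard single-parameter OCT speckle surrogate),
  drawn after the geometry so seed-paired noiseless/speckled renders share
  surfaces and vessels exactly.

Not modelled: axial vessel crossings, motion/blink artifacts, penumbral
shadow edges (columns are hard-edged), device-specific speckle statistics.
Passing phantom tests therefore demonstrates pipeline correctness and
recoverability under idealized contrast, not clinical-grade performance.

## Segmenter

A compact U-shaped convolutional network implemented directly on numpy
(im2col convolutions with hand-written backprop, verified against central
finite differences in the test suite): `depth` encoder levels of two 3×3
convolutions + ReLU + 2×2 max-pool, a bottleneck, nearest-neighbour
upsampling with skip concatenation, and a 1×1 head — sigmoid (1 channel)
or softmax (2 channels, vessel/non-vessel).  Optional weight-shared
refinement passes re-process the input together with the current
probability map (`refine_iters`), trained end-to-end through the unrolled
chain with the loss on the final output.  Optimizers: SGD (momentum
configurable) and Adam.  All training is single-threaded and bitwise
reproducible from the seeds.

Training presets mirror the published recipes: epochs 50/50/20/100/40,
batch 32/32/8/8/24, SGD lr 1e-2 (unet) or Adam lr 1e-3 / 1e-4 (frunet),
categorical vs binary cross-entropy, train/validation splits 90/10, 100/0,
80/20, 80/20, 90/10, and the matching augmentation menus (photometric +
affine for iternet; photometric + noise + rotation + crop for saunet;
right-angle rotations and flips — mask-exact — for frunet).  Validation
accuracy uses the vessel probability channel only.

## Preprocessing choices

The conditioning pipeline is grayscale → z-score → rescale to [0, 1] →
CLAHE → gamma, with no edge cropping.  CLAHE uses 8 × 8 contextual tiles
and a normalized clip limit of 0.02 (the skimage convention; equivalent in
effect to the common OpenCV clipLimit = 2.0 retina recipe), gamma = 1.2.
Patch sampling is uniform over valid positions without class balancing.
A zero-variance image skips the z-score stage with a warning rather than
failing, so degenerate inputs survive batch runs.

## Post-processing

DTI refinement is realized as two-threshold hysteresis region growth:
seed at `prob ≥ high` (default 0.6), repeatedly annex 8-connected
neighbours with `prob ≥ low` (default 0.3) until a fixpoint or `max_iter`
(100).  The output provably nests between the high- and low-threshold
masks and equals connected-component filtering of the low mask (components
containing a seed), which the tests verify independently.  The shadowgraph
baseline is Gaussian smoothing followed by a global threshold (Otsu or
fixed) with a dark/bright polarity switch.

## Evaluation

Metrics come from confusion counts with vessel as the positive class;
zero-denominator ratios return an explicit `None` so empty-vessel tiles do
not crash aggregation (undefined entries are excluded from fold means).
AUC is exact (threshold sweep over unique values / Mann–Whitney with ties
half).  Fold construction shuffles items by seed and deals them
round-robin; an optional pairing map keeps both eyes of a subject in the
same fold.  Cross-validated results are unweighted fold means.

## Desk-scale experiment sizes

The end-to-end experiment uses the small phantom preset (96 × 48 × 160
voxels), a cohort of 8 volumes with 2 held out, a depth-3 / 8-filter model
trained 10 epochs on 2,000 48×48 patches with right-angle augmentation,
and sliding-window prediction at half-patch stride.  These sizes keep a
full run in single-digit CPU minutes while leaving the recovery task
non-trivial (speckle on, 1-px vessels present).  The full-size study
geometry (385 × 141 × 640) is available behind `PhantomConfig.study()` and
the same code paths.

## Known limitations

* The segmenter is a compact stand-in honoring the published networks'
  I/O contracts; it does not reproduce their internal architectures, so
  absolute metric levels on real data are not comparable with published
  tables.
* Phantom vessels never cross axially and shadows are hard-edged.
* The raw-volume reader supports flat binaries and TIFF/PNG B-scan stacks
  only; proprietary device containers and DICOM are out of scope.
* Refinement passes require the 1-channel head.
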