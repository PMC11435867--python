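# Methods

`cottonhsi` implements a patch-based hyperspectral classification pipeline
for detecting foreign fibers (plastic film, paper scraps, ropes, foam
board, ...) in seed cotton: reflectance preprocessing, a center-labeled
patch dataset, a multi-branch hierarchical-residual CNN with
squeeze-and-excitation (SE) channel attention, a two-phase training
protocol, and AA/OA evaluation. Real acquisitions are not distributed
with the package; every pipeline stage is exercised on scenes produced by
the built-in simulator, which is first-class, tested code.

## The synthetic scene model

The simulator emulates a laboratory push-broom acquisition:

* Each of the (default nine) material classes carries a smooth
  reflectance curve in [0, 1] over a 400–1000 nm grid — sums of 2–3
  Gaussian bumps with deterministically staggered class-specific centers.
  This guarantees smoothness on the sensor's spectral resolution scale
  and pairwise separability without hand-drawing curves.
* Contaminants are painted as rotated elliptical blobs (default 24 blobs
  with 5–14 px semi-axes, cycling through the eight foreground classes so
  every material appears) over the background class, which fills the
  rest of the scene; every pixel therefore carries a class, and 0 is
  reserved for pixels excluded from training.
* Per pixel, the raw signal is
  `dark_level + a·signature + c + noise`, with `a ~ N(1, 0.10)` and
  `c ~ N(0, 0.02)` shared across bands (the multiplicative/additive
  scatter distortion that MSC exists to remove), band-wise sensor noise
  `N(0, 0.01)`, and a dark-current floor of 0.05 — modest,
  laboratory-plausible magnitudes in reflectance units with the white
  board at 1. Dark and white reference cubes carry the same sensor noise.

The generator is a pure function of its `SceneSpec`; identical seeds give
bit-identical scenes. What it does **not** emulate: mixed border pixels
(each pixel is a pure material), wavelength-correlated noise, spatial
texture within a material, specular highlights, or sensor smile/keystone.
Passing tests on these scenes therefore demonstrate the pipeline's
mechanics and trainability, not field performance on real cotton.

## Preprocessing chain

Stages run in the order: black/white correction → crop → standardization
→ MSC → spectral PCA; each is individually skippable, and fitted MSC/PCA
state is returned for reuse on held-out cubes.

* **Black/white correction** `R = (L − B)/(W − B)` per cell; cells with
  `|W − B| < 1e-8` map to 0 with a logged warning. No clipping: mild
  reflectance above 1 is allowed. The correction is invariant to a common
  positive gain on all three cubes.
* **Standardization** subtracts a mean and divides by a population
  standard deviation. Two scopes are offered. `"band"` (the transformer
  default) standardizes each band across pixels. The full chain instead
  uses `"global"` — one scalar mean/sd for the whole cube — because
  band-wise standardization forces the cube's mean spectrum to be
  identically zero, which degenerates a subsequent MSC fit against that
  mean reference (the regression target would have zero variance). The
  global scalar scope also matches reading the standardization formula
  with a single mean and deviation of "the input spectral data".
* **MSC** regresses each pixel spectrum `Z_i` on a reference spectrum
  (ordinary least squares over bands; the reference defaults to the
  cube's mean spectrum) to get slope `m_i` and intercept `b_i`, then
  corrects `(Z_i − b_i)/m_i`. This inverts a noiseless per-pixel affine
  distortion exactly; pixels with `|m_i| < 1e-8` pass through with a
  warning. The sample unit is one pixel spectrum.
* **Spectral PCA** eigendecomposes the *population* band covariance of
  the pooled pixels (so the reconstruction error of a rank-p projection
  equals the trailing eigenvalue sum times the pixel count). Exactly one
  of a fixed dimension `p` or a cumulative-explained-variance threshold
  `b` selects the retained components; eigenvector signs are fixed by
  making each loading's largest-magnitude entry positive. The package
  default is the fixed `p = 16` working dimension.

An absorbance view `A = −log10(I/I0)` is provided for inspecting spectra;
non-positive intensities are clipped to `1e-8` with a warning.

All divide guards use `eps = 1e-8`.

## Patch dataset

Every labeled pixel yields exactly one `s × s × d` patch centered on it
(`s` odd, default 9). Borders are mirror-padded by `s//2` — reflection
avoids injecting the unlabeled value and is the standard choice for
patch-CNN pixel labeling. The patch label is the center-pixel class. The
train/test split is stratified per class with train count
`round(f·n)` (minimum 1) at the default `f = 0.08`, a deterministic
function of the split seed, pooled over whatever scenes were stacked into
the dataset.

## Architecture

For a 9×9×16 patch with 3×3 kernels and 64 channels:

* **Conv0**: one valid (unpadded) k×k convolution, d → 64 channels
  (output 7×7×64).
* **First hierarchical residual block**: four convolutional branches
  C1..C4, each a chain of 6 pre-activation BN–ReLU–Conv units (channel-
  and size-preserving, pad k//2). Branch inputs chain —
  `y1 = C1(xn)`, `y_i = C_i(xn + y_{i−1})` — and the block output is the
  elementwise sum `xp = xn + y1 + y2 + y3 + y4` (five summands, i.e. five
  branches counting the identity).
* **Second block** on `xp`: `y6 = C6(xp)` with k×k units and
  `y7 = C7(xp + y6)` with 1×1 units (pad 0 — padding a 1×1 kernel would
  grow the map); output `Y = xp + y6 + y7`.
* The two block outputs are **concatenated** along channels (128): the
  only composition consistent with keeping every branch at 64 channels
  inside the blocks while presenting a 128-channel map to the attention
  stage. Within a block the branch fusion is elementwise addition, for
  the same channel-accounting reason.
* **SE gate** on the 128 channels: global average pool, bottleneck
  128 → 128/r → 128 with ReLU then sigmoid, channels rescaled by their
  gates (all in (0, 1)). Default reduction r = 16, the customary value;
  it is exposed because it is one of the two free knobs in parameter
  accounting.
* Global average pooling (7×7 → 1×1) and a fully connected 128 → 9 head.

With all convolution weights zero every branch maps to zero and both
blocks collapse to the identity — the property that keeps the 30-plus
convolution stack trainable, and an invariant the tests assert directly.

Biases are disabled on convolutions feeding batch norm and on the SE
bottleneck, enabled on the head — standard practice, and the second free
accounting knob. Initialization is Kaiming fan-in for convolutions and
linear layers, ones/zeros for BN scale/shift, from a single config seed.

Ablation variants reuse the same machinery: `dhr_only` removes the SE
gate (forcing the gates to 1 reproduces its forward exactly);
`first_block_only` keeps one hierarchical block (SE then acts on 64
channels); `single_multibranch` replaces the two chained blocks with a
single block holding the same branch inventory (five k×k chains plus one
1×1 chain).

**Parameter accounting.** The default configuration counts 1,147,529
trainable scalars (1.15 M), including BN affine terms: 9,216 (Conv0) +
5 × 221,952 (six-unit 3×3 branches) + 25,344 (six-unit 1×1 branch) +
2,048 (SE, r = 16) + 1,161 (head). `cottonhsi model-summary` prints this
per-layer breakdown plus the totals under alternative SE ratios and bias
conventions; across those conventions the total stays within
1.146–1.154 M. FLOP counting is out of scope: there is no single
convention for multi-branch residual blocks that we would be matching
against.

## Training protocol

Cross-entropy loss, Adadelta (canonical formulation: decay ρ = 0.9,
ε = 1e-6, accumulators of squared gradients and squared unscaled updates;
the learning rate multiplies the adaptive step at application). Two-phase
schedule: `lr_a = 1.0` for the first 70 epochs, `lr_b = 0.1` for the last
30, batch size 1024 at full scale. Shuffling is per epoch from the run
seed; the last incomplete batch is kept; no early stopping, weight decay
or augmentation. Per-epoch held-out accuracy is measured on a fixed
seeded subsample of the test split (at most `eval_max` patches, default
2048) with batch norm in inference mode, keeping epoch bookkeeping cheap
on large test sets; final evaluation always uses the full test split.
Under single-threaded execution a run is a bit-reproducible function of
the seed.

The sweep harness trains one model per grid cell (kernel × patch size, or
learning-rate pairs), derives each cell's seed reproducibly from the base
seed and cell index, records per-cell failures without aborting the grid,
and returns the table sorted by AA with the best cell flagged.

## Evaluation

Confusion matrix with rows = truth, columns = prediction; per-class
recall = diagonal / row sum and precision = diagonal / column sum — the
universal definitions. (In the source table this package reproduces, the
recall/precision formulas are printed transposed; the standard reading is
the one that makes the published AA column equal the mean of the
published recall rows, which is how the implementation and its fixtures
are reconciled.) AA is the mean of the defined per-class recalls, OA the
trace over the total, both in percent to 4 decimal places. Classes absent
from the truth have undefined recall and are excluded from AA with a
logged warning. Full-scene maps classify every pixel from its
mirror-padded patch and render with a fixed per-class palette.

## Problem sizes used in the checks

The package's own end-to-end check runs a 96×96×32 nine-class scene:
full chain with p = 16, 9×9 patches, an 8% stratified train split
(~740 training patches), and a shortened 10 + 5 epoch schedule at batch
256 — the same protocol shape as the full-scale setting with the scene
and epoch budget scaled to a desktop CPU. Under the package defaults
(seed 0) this reaches ≥ 95% OA on the held-out 92% of patches; a
nearest-class-mean baseline on the same scene attains ~99.6% pixel
accuracy, so the residual gap is optimizer convergence within 45 updates,
not class confusability. Unit and oracle tests use smaller configurations
(4–16 channels, 1–2 units per branch) whose contracts are
size-independent.

## Known limitations

* The NumPy network trains on CPU only and at desk scale; there is no
  GPU path or data parallelism.
* Bit-reproducibility is guaranteed under single-threaded BLAS; with
  threaded BLAS, reductions may reorder across library versions.
* MSC against the pooled mean spectrum mixes materials on heterogeneous
  scenes; variance reduction is guaranteed only per material (the tests
  check exactly that), though the full chain remains beneficial upstream
  of PCA.
* The simulator's pure-pixel assumption makes border pixels easier than
  in real acquisitions, where mixed pixels dominate the error budget.
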