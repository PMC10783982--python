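# Methods

This note documents the models, conventions and design choices behind
`osteotex`, and what its tests do and do not demonstrate.

## Synthetic trabecular textures

The generator models a trabecular texture as a thresholded Gaussian
random field: seeded white noise is smoothed with a Gaussian kernel of
scale `correlation_length` (periodic boundary, so the field is
stationary), thresholded at the empirical quantile that yields
`fill_fraction` "bone" pixels, mapped to two intensity levels
(`bone_level` = 200, `marrow_level` = 60 by default on an 8-bit scale),
and degraded with additive Gaussian noise (`noise_sigma` = 12 by
default). This is the simplest stationary model in which strut density
(fill fraction) and coarseness (correlation length) — the two texture
axes that change as bone mineral density falls — are independently
controllable.

Shipped class parameters decrease in fill fraction and increase in
correlation length with disease severity:

| class | fill_fraction | correlation_length (px) |
|---|---|---|
| normal | 0.55 | 1.2 |
| osteopenia | 0.40 | 2.0 |
| osteoporotic | 0.25 | 3.0 |

Defaults: 64×64 images, 8-bit scale — large enough for stable zone
statistics, small enough that the classifier trains in CPU seconds.
Per-image random streams are derived from
`SeedSequence(master_seed, class_key, index)`, so a dataset is a pure
function of its seed and parameters and images are reproducible
independent of generation order.

What the phantom does **not** model: X-ray projection physics, scanner
noise spectra, anatomy, partial-volume effects, or any quantitative link
between fill fraction and real BMD values. Passing tests demonstrate that
the pipeline's machinery is correct and that it separates textures that
differ in density and coarseness; they say nothing about clinical
accuracy on real scans.

## Bilateral filter

Both the domain (spatial) and range (intensity) kernels are Gaussians
`exp(−d²/2σ²)`; this is the canonical choice and the only smoothing form
the surrounding method refers to. The continuous defining integrals are
discretised as finite sums over a `(2r+1)²` window with
`r = ceil(3·σ_domain)` by default, which captures > 99.7 % of the domain
kernel's mass. Border handling is mirror reflection by default
(configurable to constant or edge replication); reflection keeps constant
images exactly invariant at the borders, preserving the DC-component
property that the normalisers exist to guarantee. Defaults
`σ_domain = 2 px` and `σ_range = 0.1 · max_intensity` smooth additive
noise while leaving the two-phase step of the synthetic textures intact.

All arithmetic is float64; outputs are re-quantised to integer bit depth
only when written to file, so feature extraction never sees double
rounding. The output is a convex combination of in-window intensities; a
final clip removes only last-ulp floating-point overshoot.

Correctness is established against a literal per-pixel double-loop
implementation of the defining formula (kept in `tests/oracles.py`,
sharing no code with the package): pixelwise agreement to 1e−10 on seeded
random images, plus the two analytic limits (constant-image invariance;
σ_range → ∞ collapsing onto the pure domain filter).

## Zone-matrix features

Quantisation is uniform-width binning of the observed [min, max] range
into N levels (default N = 32), with an optional fixed `value_range` for
cross-image comparability; a constant image maps to level 1 by
convention. Grey levels are 1-based so the low-grey emphasis weights
1/i² are finite.

Zones are maximal connected components of equal level; connectivity is
8 by default (4 configurable), the convention of the wider GLSZM
literature. Construction uses `scipy.ndimage.label` per level; the test
oracle is an independent breadth-first flood fill.

**A deliberate correction:** the source formulation prints the short-zone
and long-zone emphasis with an identical divide-by-j² form. As printed,
the two statistics would be equal, and "long-zone emphasis" would
emphasise short zones. LZE is therefore implemented as multiply-by-j²,
the only reading under which the name is meaningful and the form agrees
with the standard GLSZM definitions. The invariants SZE ≤ 1 ≤ LZE and
the Cauchy–Schwarz bounds SZE·LZE ≥ 1, LGZE·HGZE ≥ 1 hold under this
reading and are property-tested.

The sliding-window feature map (default 16-px window, stride 8, N = 8,
HGZE) quantises each window over the *global* image range so windows are
comparable, evaluates the feature per window, bilinearly resizes the
coarse grid back to the image shape, and min–max rescales to the
intensity range. All processing is strictly 2-D.

## Channel boosting

The boosted input is the concatenation `I_B = [natural, A_1 … A_M]`.
The shipped auxiliary learners reuse the pipeline's own primitives —
bilateral smoothing, the detail residual (original − smoothed, shifted
nonnegative), and the HGZE feature map — so every artificial channel is a
deterministic, documented computation rather than a learned generator;
generative auxiliary learners are deliberately out of scope. M defaults
to 3 and is configurable by name list. Channels carry heterogeneous
units, so each is independently min–max rescaled to [0, 1] before
stacking; the natural channel is divided by the intensity bound instead,
keeping it an exact affine copy of the input. Learner order is the
configuration order and is recorded as provenance in stacks and reports.

## Classifier and transfer protocol

No layer counts or hyperparameters are prescribed by the method being
implemented, so a fixed small architecture ("CBTCNNOD-small") is used:
three blocks of 3×3 same-padded convolution + ReLU + 2×2 max-pool
(widths 8, 16, 32), global average pooling, and a dense softmax head —
about 6 000 parameters for a 4-channel input, deliberately far under the
10⁵ budget so training is a CPU-seconds affair. Loss is softmax
cross-entropy; the optimiser is plain minibatch SGD (defaults: learning
rate 0.05, batch 16). Initialisation is He-scaled Gaussian from a seeded
generator; shuffling comes from the same config seed, so training is
bit-reproducible in single-threaded numpy.

Transfer learning is exercised structurally: the model is pretrained on a
*source* synthetic task with the same class structure but 1.6× longer
correlation lengths, then fine-tuned on the target task with
`freeze_upto = k` parameterised blocks frozen (default k = 2 of 4).
Frozen blocks are never touched by the update loop, and the tests assert
byte-identity of their parameters across fine-tuning. `freeze_upto = 0`
reduces to ordinary training and `freeze_upto = n_blocks` to a no-op,
both verified.

The end-to-end experiment defaults mirror the evaluation protocol of the
method: 200 training images (100 per class, two classes), 100 held-out
test images, 4-channel boosted input, batches of 20 at evaluation. The
channel-boosting ablation is asserted only as non-degradation at this
desk scale, not as the large improvements reported on clinical data.

## Metrics, batching, BMD rule

Accuracy, precision, sensitivity and specificity are computed from
binarised confusion counts; in the three-class setting the binarisation
is one-vs-rest for a stated positive class. Zero-denominator ratios are
reported as NaN with a warning — never silently 0 or 1 — and batch
averages skip them. Batches are consecutive slices (default 20 images); a
trailing partial batch is kept and identifiable by its `n_images`
column. Tables render percentages to two decimals; the average row equals
the arithmetic mean of the batch rows to 1e−12.

BMD categorisation: > 833 mg/cm² normal, < 648 osteoporotic, and both
boundary values assigned to osteopenia — the interval wording of the
clinical rule is closed ("between 648 and 833") while its neighbours are
strict inequalities. The mapping is monotone by construction and tested
over a 100–1500 mg/cm² grid. Wall-clock processing time is available only
as an optional log line; it is hardware-dependent and excluded from all
assertions.

## Known limitations

- The synthetic phantom is a two-phase stationary field; results on it do
  not transfer to claims about clinical images.
- The bilateral filter is evaluated directly (no grid or permutohedral
  acceleration); fine for 64×64–512×512 desk scale.
- Only 2-D zone matrices are implemented; volumetric (voxel) zones and
  other radiomics families (GLCM, run-length) are out of scope.
- The CNN is intentionally small and CPU-bound; it is not a platform for
  large pretrained backbones.
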