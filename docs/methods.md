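# Methods

`ctforensics` detects small-region generative forgeries in CT slices with a
two-stage cascade: a local patch detector that scores every sliding-window
position inside the slice's inscribed circle, and a global classifier that
decides from the texture of the resulting tamper-probability heatmap whether
the slice — and, aggregated, the scan — has been manipulated.

## Threat model and problem geometry

The attack emulated here in-paints a small square region (at most 32 × 32
pixels of a 512 × 512 slice, i.e. 1/1024 to 1/256 of the image) so that a
lesion appears or disappears, consistently across roughly ten consecutive
slices of the 3-D scan. Whole-image classifiers fail in this regime because
more than 99% of each image is authentic "cover". The cascade counters this
by classifying 32 × 32 sub-images, small enough that a forgery fills most of
the window.

## Stage 1 — local patch detector

**Window grid.** Rows of window centers lie at `y = img/2 + i·s`
(`i = 0 … ⌊(CT−img)/s⌋`); within the row at height offset `h = |y − CT/2|`
the admissible chord half-width is `w = ⌊√((CT/2)² − h²)⌋` and centers lie at
`x = CT/2 ± j·s` for `j·s ≤ w − img/2`. Defaults: `CT = 512`, `img = 32`,
`s = 4` → 121 rows, first/last center ordinate 16/496. Only the abscissas on
the positive side are generated by the formula as printed; we mirror them
across the vertical midline (deduplicating `j = 0`), since both lung fields
must be covered. Windows are half-open `[c − img/2, c + img/2)` in 0-based
(row, col) coordinates.

**Network.** A lightweight CNN maps a single-channel patch to a two-class
softmax. Reference architecture (widths configurable): two standard 3 × 3
convolutions (32, 64 channels), a spatial attention gate, three residual
depthwise-separable stages (128, 256, 256 channels; the first block of each
stage max-pools 2 × 2 and widens, identity skips elsewhere; the final stage
keeps 256 so channel attention sits after the widest stage), a channel
attention gate, global average pooling and a dense head
(128, SELU) → (2, softmax). Every convolution is followed by batch
normalization. 768,325 parameters at the defaults.

- *Spatial attention* `σ(Conv7×7([max_c F ; mean_c F]))` multiplies the
  feature map before the first pooling stage, where spatial resolution is
  largest.
- *Channel attention* `σ(MLP(maxpool F) + MLP(avgpool F))` with a shared
  C → C/4 → C bottleneck, placed after the widest stage.
- *SELU* uses the canonical self-normalizing constants
  λ = 1.0507009873554805, α = 1.6732632423543772.

The engine is a self-contained NumPy implementation with hand-written
backward passes (verified against central finite differences in float64) and
an Adam optimizer. Activations are float32 by default. Batch-norm running
moments are zero-debiased exponential moving averages with keep-rate 0.95,
so short trainings are not biased toward the (0, 1) initialization.

**Training.** Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e−8) on softmax
cross-entropy, initial learning rate 5e−4 with staircase decay ×0.85 every
600 steps, batch 56, L2 weight decay 1e−4 on convolution/dense weights, at
most 30 epochs with early stopping after 3 epochs without validation-accuracy
improvement; the best-validation parameters are retained.

**Augmentation.** Positives: all 25 integer shifts within Chebyshev radius 2
of the tamper center, cropped from the tampered slice. Negatives per
tampered slice: the 10 near offsets in the rectangle (−2,−2)…(−1,2) plus 20
distinct random grid centers, cropped from the pre-tamper slice; additional
negatives come from `neg_per_pos` standalone clean slices (25 random-grid
crops each, default pairing 10). Shifted centers whose window would exit the
image are dropped with a warning.

## Stage 2 — global classification

The per-window probabilities are assembled on the stride lattice (one cell
per window position; cells outside the circle default to probability 0),
quantized to `g` gray levels by `min(round_half_up(g·p), g−1)` (default
g = 100; the top value clips into level 99 rather than opening a 101st
level), and summarized by four gray-level co-occurrence matrices at distance
1 and angles 0°, 45°, 90°, 135°. Offsets are `(Δx, Δy)` with y downward:
(1,0), (1,−1), (0,1), (−1,−1); counts are raw — unnormalized, asymmetric.
The stacked 100 × 100 × 4 counts flatten to a 40000-vector, are
mean-centered and PCA-reduced to 256 dimensions (no whitening; the dimension
is lowered with a warning when fewer samples are available), and classified
by an SVM chosen by seeded 5-fold stratified grid search (RBF and linear
kernels; C ∈ {0.1, 1, 10, 100}; RBF widths {1/(d·var), 1/d, 0.01, 0.001};
accuracy objective). Scores are Platt-calibrated probabilities; a slice is
positive above 0.5 (configurable).

**Scan rule.** A scan is declared tampered when any `m` consecutive slices
contain at least `n` positive decisions (defaults m = 10, n = 9). Sequences
shorter than `m` are evaluated whole, with a warning.

## Evaluation protocols

Slice-level (2-D): per-slice confusion counts with
ACC = (TP+TN)/total, P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R); a
metric whose denominator vanishes is reported as undefined (`None`), never
silently 0.

Region-level (3-D): a tampered region is a true positive when at least `n`
of the `m` consecutive slices containing its central slice are predicted
positive — the window is searched over all alignments containing the central
slice and the best is used — otherwise a missed report (false negative).
Each maximal run of ≥ `n` consecutive positive predictions disjoint from
every annotated span counts one false positive; this mirrors the
true-positive run criterion, since the protocol's false-positive unit is not
otherwise pinned down. TP + FN always equals the number of annotated
regions.

## Synthetic phantom benchmark

Real training data (lung CT plus a trained in-painting attack) is not
redistributable, so the package generates phantoms: a mid-intensity body
ellipse over dark background, two low-intensity lung ellipses, correlated
Gaussian noise (σ = 60 stored units, 1.5 px correlation) and bright
vessel-like blobs, intensities in the stored-value range [0, 4095]
(normalized over that full range; phantoms are not HU-calibrated). The
forgery operator replaces the texture inside a square box planted wholly
inside a lung field with its Gaussian-smoothed version (σ = 1.5 px) plus
re-sampled noise that is smoother than the native texture (2.0 px
correlation, gain 0.5 of the removed residual) — reproducing the two
artifacts generative in-painting leaves: over-smoothness and a
high-frequency spectral deficit. Outside the box the image is bit-identical
to its input. The deficit is measurable: over 100 seeds, the mean energy in
the upper half of the radial spectrum inside the box drops in ≥ 95% of
cases. The operator is deliberately *not* a generative model; it has the
statistical shape of the attack without any capability.

Scans stack phantom slices whose vessel-like blobs persist through the
stack (lung fields taper smoothly towards the ends); per-slice noise is
fresh. A tampered scan carries the forgery at a fixed (y, x) through a
physical span of consecutive slices; the re-sampled box noise interpolates
smoothly (variance-preserving) between two draws across the span — the
emulated attack is a 3-D in-painter whose generated texture is z-coherent,
varying gradually along the stack, blended with each slice's local
context. The
*annotated* region is the 10 consecutive slices centered in that span: 3-D
in-painting involves more slices than the window a region-level evaluation
marks around the central slice, so the annotated slices are a subset of the
physically tampered ones (benchmark: 16 tampered, 10 annotated, on
24-slice scans).

**What the phantoms do not model:** real anatomy (airways, vasculature,
mediastinum), HU calibration, scanner-specific noise spectra, slice-to-slice
anatomical continuity beyond a smooth lung taper, and a learned adversary
that adapts to the detector. Passing the synthetic benchmark therefore
demonstrates that the cascade recovers the designed statistical signature at
small scale — not clinical performance.

### Reduced-scale study conditions

The benchmark runs every stage at sizes a single CPU handles in minutes; all
scale choices move together and are fixed in `BenchmarkConfig`:

| quantity | full scale | benchmark | rationale |
|---|---|---|---|
| slice side | 512 | 128 | compute |
| tamper box | ≤ 32 | 16 | keeps tamper/image area regime (1/64) |
| window side | 32 | 16 | tamper must fill the window, the method's core geometric premise |
| stride | 4 | 4 | unchanged |
| heatmap lattice | 121² | 29² | follows from the above |
| GLCM gray levels | 100 | 25 | keeps pairs-per-coordinate density (~14.5k/10⁴ vs ~0.8k/625) |
| detector widths | 32/64; 128/256/256 | 8/16; 16/32/64 | compute |
| forgery pairs (train / val) | — | 50 / 12 | distinct instances dominate patch-detector generalization; a val set with many distinct forgeries keeps the early-stopping signal informative |
| clean slices per pair | 10 | 2 | ~1:3 patch class ratio within budget |
| early-stop patience | 3 epochs (~37k steps) | 12 epochs (~1.1k steps) | patience is a step budget in disguise; a benchmark epoch is ~100× fewer optimizer steps |
| global training slices | — | 150/class | GLCM coordinate coverage |
| PCA dimension | 256 (of thousands of samples) | 16 (of 300) | keeps the reduction ratio; near-full-rank PCA at small n leaves the SVM riding sample noise |
| held-out slices | — | 20/class | fixed evaluation set |
| scans (region eval) | — | 3 × 24 slices, span 10 | 3-D protocol check |

The pairs-per-coordinate argument for the gray levels: co-occurrence counts
are informative only where training and test heatmaps populate the same
matrix coordinates; 100 levels on a 29 × 29 lattice leaves each coordinate
observed at most once across a small training set, and the classifier cannot
generalize. 25 levels restores the density of the full-scale configuration.

## Numerical choices and degenerate inputs

- Quantization rounds half-up (`floor(g·p + 0.5)`), platform-independent.
- Heatmap assembly requires `(CT − img)/2` to be a multiple of the stride so
  the row- and column-anchored lattices coincide (all standard configs
  satisfy this); a clear error is raised otherwise.
- Max-pool and attention max gradients split evenly across ties.
- `fit_global` refuses single-class labels and empty grids; CV folds are
  lowered to the minority-class count when needed.
- DICOM reading refuses empty directories, mixed series and duplicate or
  non-monotonic z positions; rescale slope/intercept map stored values to HU
  on read.
- All randomness flows from explicit integer seeds (`numpy` Generators); a
  master seed fans out to per-stage seeds via `SeedSequence` with fixed
  stage tags.

## Known limitations

- Region-level recovery on the scan benchmark is sensitive to rare
  placement contexts: a forgery planted over a dim vessel-like blob can be
  missed on every slice of its span, costing the whole region, because such
  contexts are underrepresented among the ~75 training forgeries the
  single-CPU budget allows. Slice-level metrics are much less affected
  (misses cost single slices, not regions). More distinct training
  forgeries is the lever; the patch count per forgery matters far less.

- The detector engine is CPU NumPy: ~0.2 s per 56-patch training step at
  benchmark widths; the full-width 512-scale configuration trains, but
  slowly. The architecture behind `DetectorConfig` is an interpretation of a
  figure-level description; exact layer counts of the original are not
  recoverable from text.
- GLCM counts are asymmetric and unnormalized by design; heatmaps of
  different lattice sizes are not directly comparable feature spaces.
- The 3-D protocol's false-positive unit follows the run-based reading
  documented above; other unitizations are defensible.
- Scan-level anatomy varies only smoothly with z; no registration issues,
  breathing artifacts or inter-scan protocol variation are modeled.
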