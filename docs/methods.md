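# Methods

## Problem and pipeline

`retscreen` detects *referable* diabetic retinopathy (DR grade ≥ 2 on the
0–4 International Clinical DR scale) from color fundus photographs. Rather
than feeding photographs to a classifier directly, the pipeline converts
each image into two **entropy images** — per-pixel maps of local texture
complexity — and classifies the pair with a two-stack ("bichannel")
convolutional network:

1. **Resize** to the working resolution (default 100 × 100, anti-aliased
   bilinear).
2. **Channel extraction.** Two planes per image: the luminance
   `0.299 R + 0.587 G + 0.114 B` (rounded half-up to integers, so the
   entropy step sees discrete intensities) and the raw green component,
   which carries the strongest vessel/lesion contrast because retinal
   pigmentation reflects green light preferentially.
3. **Unsharp masking (UM).**
   `out = clip(round(x + amount · (x − G_σ x)), 0, 255)` with a Gaussian
   blur `G_σ`. Defaults `σ = 2 px`, `amount = 1` at 100 × 100; the blur uses
   reflect-about-edge-pixel boundaries (scipy `mode="mirror"`), matching the
   reflective padding used everywhere else.
4. **Local entropy.** For every pixel, the Shannon entropy (bits) of the
   intensity histogram in the centered `n × n` window,
   `E = −Σᵢ P(i) log₂ P(i)`, with `0·log₂0 ≡ 0` and reflective padding at
   the borders. Default `n = 9` (the window size that maximized screening
   accuracy) and 256 intensity bins. Homogeneous regions score 0; windows
   whose 81 pixels are all distinct score `log₂ 81 ≈ 6.34` bits.
5. **Unit rescale.** Entropy divided by the *fixed* theoretical maximum
   `log₂(min(n², bins))`, never per-image min–max, which would destroy
   comparability across images.
6. **Bichannel CNN.** One convolutional stack per entropy image, each four
   blocks of `conv 5×5 (same) → ReLU → max-pool 2×2 → dropout`; stacks are
   flattened, concatenated and passed through dense layers to a single
   sigmoid unit. Training minimizes binary cross-entropy with Adam.

### Implementation notes

* `local_entropy` computes exact window histograms with one summed-area
  table per intensity level and evaluates
  `E = log₂ n² − (Σ c log₂ c)/n²` from the integer counts via a lookup
  table. It agrees with a naive per-pixel histogram to ≈ 1e-15 and runs in
  ~30 ms for a 100 × 100 plane.
* The network is a small self-contained NumPy engine (im2col convolution,
  max-pool with stored argmax, inverted dropout, dense layers, Adam,
  numerically stable BCE-with-logits). All randomness (initialization,
  dropout, shuffling) derives from the config seed, so runs are bit-stable
  at a fixed BLAS thread count. Gradients are verified against central
  differences in the test suite.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `UMParams.sigma` | 2.0 px | Gaussian blur scale of the unsharp mask |
| `UMParams.amount` | 1.0 | high-frequency boost factor (0 = identity) |
| `EntropyParams.block_size` | 9 | odd window side `n` |
| `EntropyParams.bins` | 256 | intensity levels of the window histogram |
| `ModelConfig.conv_filters` | (32, 64, 64, 128) | filters per conv block |
| `ModelConfig.kernel_side` | 5 | conv kernel side |
| `ModelConfig.dropout` | 0.3 | rate after each pool stage and hidden dense |
| `ModelConfig.learning_rate` | 1e-4 | Adam step size |
| `ModelConfig.input_side` | 100 | square single-plane input side |

The operating threshold for sensitivity/specificity is 0.5 and exposed as a
flag; a probability equal to the threshold counts positive. AUC uses
trapezoidal integration over all thresholds (equivalently the Mann–Whitney
pairwise concordance, ties at 0.5).

## Dataset handling

Grades are heavily imbalanced in screening corpora, so under-represented
grades are expanded by lossless flips and 90°-multiple rotations to
per-grade targets (round-robin over shuffled sources and transforms: no
(source, transform) pair repeats until the 5-transform vocabulary is
exhausted; beyond that the cycle restarts with fresh ids, which the
grade-3/4 targets of the original corpus require). Arbitrary-angle rotation
is deliberately excluded by default because it needs interpolation.

Augmenting *before* splitting places near-duplicates of one photograph in
both train and test. The default split therefore assigns whole source
groups to one split (greedy packing with a single-swap repair; it raises an
error if the exact per-stratum counts are unattainable with whole groups).
`paper_mode=True` splits at the record level instead — exact counts,
augment-then-split order — and is what the corpus-arithmetic checks use.

## Synthetic fundus phantoms

Real screening photographs cannot ship with the package, so every stage is
exercised on generated phantoms that reproduce the *statistical* structure
the pipeline exploits, not photorealism:

* bright retina disc (fundus-colored, mild radial falloff) on a near-black
  background; a brighter optic-disc blob at 0.55 R from center;
* 8–10 dark quadratic-Bézier vessels radiating from the optic disc,
  width 1–2 px;
* two DR-lesion populations — bright exudate-like blobs (radius
  4.5–6.5 px) and dark hemorrhage-like blobs (3–4.5 px) — with **speckled
  interiors**: real lesions are granular, and the speckle is what gives
  them their high local-entropy signature. Lesion radius grows mildly with
  grade (+8 %/grade): severer DR produces larger lesions, not just more;
* lesion counts are Poisson with mean total 0 / 2 / 6 / 12 / 20 for grades
  0–4 (split evenly between the two populations; grade 0 draws none), so
  expected heterogeneity rises strictly with grade;
* contrast is green-dominant — vessels (8, 35, 6), bright lesions
  (12, 48, 7), surface dark lesions (8, 42, 5) in (R, G, B) — reflecting
  fundus physiology: retinal pigmentation reflects green light, and blood
  reflects red, so vasculature and most lesions nearly vanish in the red
  plane while green shows them best;
* **deep intraretinal hemorrhages**: 40 % of dark lesions lie below the
  vessel layer and are visible in red light but barely in green
  (contrast (34, 10, 4)) — the complementary signal that the luminance
  channel carries and the green component misses, i.e. the information
  the two-channel fusion exists to recover;
* **grade-independent artifact populations**, one per channel: drusen-like
  deposits visible almost only in red (mean 6/image, contrast (32, 4, 2)),
  and flash/nerve-fiber-layer reflection spots visible mostly in green
  (mean 5/image, contrast (4, 26, 2)). The luminance channel inherits both
  (diluted), which is why the clean green component is the preferred single
  channel;
* diffuse low-frequency **choroidal mottling** in the red plane
  (amplitude 10), the texture of the vascular layer beneath the retina;
* pixel noise (σ = 0.8) is mostly common-mode across the color planes (a
  shared field plus a 0.3 σ per-channel part), as sensor and illumination
  noise is; with independent per-channel noise the weighted luminance
  average would cancel noise and make the gray channel *better* than
  green, inverting the contrast ordering the generator must emulate.

What the phantoms do **not** model: camera vignetting and illumination
gradients, anatomical macula/fovea structure, eye-side (left/right)
pairing, acquisition-quality variation, or subpixel microaneurysms. A model
that separates phantoms well says nothing quantitative about Kaggle-scale
photographs; the benchmark checks the pipeline's machinery and the
qualitative channel ordering, not clinical performance.

## The synthetic benchmark

`benchmark.run_benchmark` is the package's end-to-end study, also invoked
by `scripts/acceptance.py`:

* **Corpus**: 2,000 phantoms at side 100 — 1,000 referable, 1,000 not —
  with the grade mix inside each binary class following the screening-
  population proportions (grade 0:1 ≈ 92.5:7.5 within non-referable;
  2:3:4 ≈ 60.8:19.6:19.6 within referable).
* **Split**: grade-stratified, leakage-free, 60 % train / 40 % test.
* **Inputs**: the two unit-scaled entropy images, 2×2-mean-pooled to
  50 × 50 and centered by −0.5. Pooling quarters single-core training cost
  and slightly denoises; centering lets first-layer units see signed
  inputs.
* **Augmentation**: the training split is tripled with horizontal and
  vertical flips. Flips commute exactly with every preprocessing step
  (symmetric kernels, square windows), so flipping entropy maps equals
  preprocessing flipped photographs.
* **Models**: the bichannel network and its two single-channel ablations
  under `benchmark_config` — the same four-block architecture with filters
  (4, 8, 8, 16), one hidden dense layer of 32 units per input stack (so
  the fused model's head is not bottlenecked relative to the ablations),
  dropout 0, Adam 2e-3, batch 32. Dropout is off here because at this
  capacity and data scale it only slows convergence; the full-scale
  default (32/64/64/128, dropout 0.3, lr 1e-4) is kept for fidelity but
  would need hours of CPU time and is not what the tests run.
* **Schedule**: singles train 15 epochs and the (twice-as-large) fused
  model 20, with the Adam step halved after epoch 10. The reported
  probability is the mean over the last four epochs' models (snapshot
  averaging) and over the identity/h-flip/v-flip views of each test image
  (test-time augmentation); both damp run-to-run jitter considerably
  without touching test labels.

Problem sizes (2,000 phantoms, ≤20 epochs, 3 training seeds for medians)
are chosen so the whole study runs in minutes on one CPU core.

## Numerical choices and edge cases

* Rounding is half-up everywhere an intensity is quantized (luminance, UM,
  resize); the half-up convention is asserted by the closed-form tests
  (e.g. pure red → 76).
* `rescale_unit` divides by the theoretical maximum rather than
  re-quantizing the entropy map to 8 bits first; an intermediate 8-bit
  step would be lossy and changes nothing downstream.
* Ties: a probability equal to the threshold is positive; AUC ties count
  0.5 (midrank).
* Degenerate inputs raise typed errors rather than NaN: empty classes in
  `metrics`/`roc_auc`, planes smaller than the entropy window, single-class
  ROC, train counts exceeding a stratum.
* Max-pool drops a trailing odd row/column (100 → 50 → 25 → 12 → 6).
* The two CNN stacks never share weights; the first conv layer skips the
  (unused) gradient with respect to the network input.

## Known limitations

* The NumPy backend is single-threaded-friendly but slow at the full-scale
  configuration; it is meant for the benchmark scale, not 30,000-image
  training runs.
* Group-level splitting can fail to hit exact per-stratum counts when all
  source groups are large; `paper_mode` is the escape hatch.
* Phantom realism is deliberately limited (see above); absolute metric
  values on phantoms do not transfer to clinical data.
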