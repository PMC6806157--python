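# Methods

## Problem and pipeline

A PAMONO surface-plasmon-resonance sensor renders nanoparticle bindings as
localized intensity excitations in grayscale image sequences. Upstream
detection produces 48×48 candidate patches; this package implements the
classification stage that decides, per patch, whether a binding is present.
The pipeline is: center-crop to 32×32 → frequency-domain feature
extraction (spectral and/or wavelet) → depth-limited decision tree or
random forest → binary decision. Cropping is a pure crop, never a resample,
and patches smaller than 32×32 are rejected rather than zero-padded:
padding introduces interpolation values into the spectrum that measurably
degrade spectral classification, so it is forbidden throughout.

Intensities are normalized to [0, 1] by the integer dtype maximum (255 or
65535). All features are scale-dependent, so a model is only valid for
features extracted with the same normalization, on the same platform —
floating-point differences between platforms can flip tree comparisons,
which is also why thresholds are serialized and exported at full
float64 round-trip precision (17 significant digits).

## Spectral features

The unnormalized forward 2D DFT (no 1/N² factor) is computed, the
zero-frequency bin shifted to (16, 16), and the elementwise magnitude
taken, with no logarithmic scaling. Two profiles reduce the 32×32
magnitude grid:

* **Radial profile (16 entries).** Pixel p belongs to radius r if
  round(‖p − center‖) = r. Only the upper half-plane (rows ≤ 16) is
  summed — a real image's spectrum is conjugate-symmetric, so one half
  carries all information; the full center row is included, the DC bin is
  excluded, and rounded radii above 16 (the grid corners) are discarded.
* **Angular profile (180 entries).** For each angle θ_k = k·π/180,
  k = 0..179, the profile sums 16 samples at integer radii r = 1..16,
  each taken at the nearest pixel (16 − round(r sin θ), 16 + round(r cos θ)).
  Indices wrap modulo 32: the DFT grid is periodic, and the radius-16
  sample of near-horizontal lines otherwise falls one pixel off-grid (its
  wrapped pixel is the identical Nyquist bin). Samples are not
  deduplicated across angles — each (angle, radius) pair contributes
  exactly once, so the profile of a constant magnitude grid is exactly
  16 per line.

Each profile yields mean, maximum, argmax (0-based, first index on ties),
population variance, and max − min: 10 spectral features. Discretization
choices (180 lines, nearest-pixel rounding, upper half-plane) are frozen
conventions of this package; nothing downstream depends on them beyond
train/inference consistency.

## Wavelet features

A 3-level separable 2D Haar transform uses the orthonormal filter pair
approx = (a+b)/√2, detail = (a−b)/√2, applied to all rows and then all
columns within a level before the approximation channel is recursed
(interleaving levels differently yields a different transform). Orthonormal
scaling — rather than plain pairwise averaging — is chosen so that the sum
of squared coefficients over the 10 channels equals the input's squared
sum exactly, an invariant the tests check at 1e-9 relative on 1000 random
patches. Any fixed rescaling would only multiply each feature by a
constant, which axis-aligned tree splits absorb. Since 32 is a power of
two and Haar filters have length 2, no boundary handling exists.

The per-channel feature is the mean absolute coefficient over the
channel's own N×M grid. The canonical order is frozen as
[A3, H3, V3, D3, H2, V2, D2, H1, V1, D1] (approximation first, coarse to
fine). A constant patch of value c gives E(A3) = 8c and zero elsewhere
(the approximation gains ×2 per 2D level).

## Classifier

Split search is delegated to scikit-learn's CART (Gini impurity by
default, depth cap 12); the fitted tree is immediately flattened into an
explicit node list that owns prediction (feature ≤ threshold goes left),
JSON round-tripping, and if-else C export. The exported source is verified
by parsing it back into an interpreter and checking 100% prediction parity
on random vectors for every depth 0–12. The default cap of 12 keeps the
unrolled code small and its execution time negligible relative to feature
extraction (asserted only as an ordering, never as an absolute time).

Forests are built from seeded bootstrap resamples, one depth-capped tree
each, predicting by majority vote with ties resolved to class 0
("no virus"): in a screening setting an undecided patch is reported
negative rather than raising a false alarm. Both trainers are pure
functions of (table, config) — repeated runs are bit-identical.

## Feature analysis

Features are ranked by PCA "variance accounted for" on standardized
training features: score(f) = Σ_j EVR_j · loading(f, j)², i.e. each
principal component's explained-variance share distributed over features by
squared loading. Constant columns standardize to zero and score 0; ties
break toward the smaller canonical index. Incremental curves retrain a
tree on the top-k features for k = 1..d against a single fixed train/test
split (no cross-validation), mirroring how the saturation of per-family
curves is assessed. The extraction planner closes a selected feature
subset over stage dependencies (radial/angular profiles need
DFT → shift → magnitude; energies need the Haar transform) so reduced
models skip unneeded stages entirely — dropping the angular profile
removes the 2880-sample summation that dominates spectral extraction cost.

## Synthetic data

The generator emulates the described appearance of sensor patches, not
their true distribution. Positives are
background + A·exp(−d²/2σ²) + 0.4A·exp(−d/8)·sin(2πd/λ + φ) + noise,
with A ∈ [0.05, 0.25], σ ∈ [2, 5] px, λ ∈ [4, 10] px, center jitter ±3 px,
background 0.5, Gaussian noise σ = 0.02, clamped to [0, 1]. Negatives mix
pure noise (50%), low-amplitude plane sinusoids imitating mechanical
vibration (30%, amplitude 0.02–0.08), and oriented Gaussian-ridge streaks
(20%, amplitude 0.05–0.2, width 1–3 px). The vibration and streak
amplitude ranges are this package's own choices, set so confounders are
visible above the noise floor yet weaker than typical bindings — roughly
what makes the real task hard. Patches are written as 8-bit PNG to
exercise the quantization/normalization path.

What passing tests show — and do not show: the synthetic task verifies
that the features separate blob-plus-ring textures from noise, vibration
and streak textures and that the pipeline is deterministic end to end; it
says nothing about accuracy on real sensor data, which contains background
drift, overlapping events and particle-size-dependent SNR that the
generator does not model. Real deployments should retrain from a manifest
of real annotated patches using the identical commands.

## Problem sizes and numerical choices

The end-to-end evaluation and acceptance runs use n = 4000 patches with a
70/30 split and balanced classes, large enough for stable accuracy
estimates on the synthetic task while keeping a full run in seconds on one
CPU. Transform correctness is checked against direct O(N⁴) double-sum
evaluation on 8×8 inputs (100 seeded patches, <1e-9 relative), Parseval's
identity and conjugate symmetry at 32×32, and profile construction against
brute-force pixel/sample enumeration. Degenerate inputs are handled
explicitly: empty profiles, empty channels, non-square or odd-sized
patches, and single-class training sets (a depth-0 leaf) raise or
short-circuit as documented, and undefined metric ratios (zero
denominators) raise rather than returning 0 so degenerate evaluations
cannot silently inflate summaries.

## Known limitations

* The angular profile's nearest-pixel sampling double-counts pixels shared
  by adjacent lines near the center; this is intentional (each line is an
  independent 16-sample sum) but means the profile is not a partition of
  the spectrum.
* The benchmark's timing decomposition attributes Python/numpy dispatch
  overhead to the stage being timed; relative stage costs are meaningful,
  absolute nanosecond values characterize this implementation, not the
  embedded C deployment.
* Exported C code is verified structurally (parse-back interpreter
  parity), not by compiling it.
* The forest stores full per-tree structure; no pruning or feature
  importance beyond the PCA ranking is implemented.
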