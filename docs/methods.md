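# Methods

This note records the scientific and numerical choices behind wavetap: what
each stage computes, which parameters matter, what the synthetic cohorts do
and do not emulate, and where the design was genuinely open.

## Keystroke model and file format

A keystroke event carries a keyboard region (L = left half, R = right half,
S = space bar), the transition from the previous event's region (nine
ordered pairs, `LL` … `SS`), and three non-negative millisecond timings:
hold (down-to-up of one key), latency (press-to-press of consecutive keys)
and flight (release-to-press). Logs are whitespace-delimited text, eight
columns per line, one file per subject. Any run of tabs/spaces delimits;
dates are ISO `YYYY-MM-DD` with a `YYMMDD` fallback; zero-padded numerals
parse as decimals. Real Tappy files contain noise lines, so the parser
skips and counts malformed lines by default (`strict=True` aborts instead).
Event streams must be chronologically non-decreasing, and each event's
transition must end in its own region — both are enforced at construction,
so no downstream code ever sees an inconsistent record.

## Feature schema

Each subject is reduced to a fixed-width vector by 11 descriptive
statistics — mean, sample standard deviation (ddof = 1), Fisher excess
kurtosis, standardized skewness (both population-moment, i.e. biased,
estimators), and linear-interpolation percentiles 10/20/40/60/70/80/90 —
applied to each timing series over event groups: hold over {ALL, L, R, S},
latency and flight over {ALL, LL, LR, RL, RR}. With the total event count
and three asymmetry contrasts (mean L − R hold; mean LR − RL latency; mean
LL − RR latency) this yields 158 features. The grouping is configuration:
other expansions (e.g. including space-bar transitions) change the width,
and everything downstream is width-agnostic. Degenerate groups get defined
conventions rather than NaNs: empty group → 0; n < 2 → std 0; n < 4 or zero
variance → kurtosis and skew 0. Statistics are order-free by construction,
so permuting events within a group never changes a value.

The asymmetry contrasts are the clinically motivated entries: early
Parkinson's disease is typically unilateral, so a left-minus-right
difference in hold or latency means captures exactly the signal the
simulator injects via its `asymmetry` parameter.

## Class balancing and scaling

SMOTE runs on raw features, before scaling. For each synthetic row a
minority sample x and one of its k = 5 nearest minority neighbours x_k
(Euclidean distance, exhaustively verifiable) are drawn, and
x' = x + u·(x_k − x), u ~ U(0,1). Synthetic points therefore lie on
segments between real minority points — a convex-combination property the
tests check against a brute-force neighbour search. The default target
grows the minority to the majority count: 162/55 → 324 rows. An
alternative published form of the update, x + u·|x − x_k|, makes every
coordinate offset non-negative and pushes synthetic points off the
interpolation segment; it is implemented as
`resampling.paper_formula_oversample` for comparison but is not the
default, which follows the canonical interpolation. Neighbour choice is
uniform among the k nearest. Min-max scaling then maps every column
affinely onto [0, 1]; constant columns map to 0, and the per-column
(min, max) pair is returned so the identical transform can be applied to
held-out data.

## Wavelet scalograms

The feature vector's index plays the role of time with unit spacing. Its
CWT against the real Morlet mother wavelet ψ(t) = exp(−t²/2)·cos(5t) is the
Riemann-sum discretization

W(λ, t) = Σ_τ x(τ) · ψ((τ − t)/λ) / √λ,

evaluated per scale as a correlation with a truncated kernel: |ψ| < 1e-14
for |arg| > 8, so the kernel is cut there and the signal is implicitly
zero-extended (no padding). The scale grid is the integers 1..20 — a
nominal [0, 20] interval would include the degenerate scale 0, which
divides by zero in ψ((τ−t)/λ). The constant 5 is the Morlet centre
frequency: a pure cosine of angular frequency ω peaks near scale 5/ω,
which a test verifies, including a cross-check against pywavelets' `morl`
(the same mother wavelet under a different discretization; the two agree
on peak location, not coefficient values, so the comparison is
qualitative). The implementation is oracle-tested against a naive
double-loop summation to 1e-9.

Rendering maps |W| linearly onto [0, 1] over the whole matrix (the sign of
a real wavelet coefficient carries no display information), applies a
perceptually uniform colormap (viridis by default, configurable) and
resamples bilinearly to 240×240×3. A zero-range matrix renders as a
uniform image rather than dividing by zero. Rendering is bit-deterministic.

## Augmentation

One variant = one composed affine transform about the image centre —
rotation (≤ 40°), shear (≤ 0.2), isotropic zoom (factor in [0.8, 1.2]),
vertical shift (≤ 0.2·H) — with bilinear interpolation and reflect padding,
plus a probability-1/2 horizontal flip. Parameters are drawn uniformly on
symmetric intervals, the keras "range" convention. Intensity rescaling is
not an augmentation here; images are scaled 1/255 at load time. Default
`copies_per_image=2` triples the dataset. Composition order (rotate∘shear,
then zoom, then shift) and the reflect fill are package choices; only the
transform families and ranges were fixed a priori. Augmentation applies to
the training split only — augmenting before splitting would place
near-duplicates of training images in the test set; the leakage-prone
augment-then-split order remains available behind an explicit flag so its
optimistic bias can be demonstrated.

## Architecture

The classifier is a SqueezeNet-style network built from fire modules: a
1×1 "squeeze" convolution to s channels, ReLU, then parallel 1×1 and 3×3
"expand" convolutions concatenated to e channels (even split; odd e rounds
the 1×1 branch up; the 3×3 branch is padded so spatial size is preserved).
Per-module parameter count is s(c+1) + e₁(s+1) + e₃(9s+1), which the tests
verify layer by layer.

Modified network (240×240×3 input): batch normalization on the input,
seven fires with palindromic sizes (24/48, 48/96, 64/128, 64/256, 64/128,
48/96, 24/48), a 2×2 max pool after each of the first six (240 → 3 after
six floor-halvings), global average pooling, dense 2-way head; ≈264 k
parameters. No pool follows the seventh fire — with six pools the
global-pool head makes a seventh redundant at this input size. ReLU
activations and He initialization are the SqueezeNet-family standard.
The reference baseline is canonical SqueezeNet v1.0 (7×7/2 stem, eight
fires, pools after the stem, fire4 and fire8, 1×1 convolutional 2-class
head), ≈736 k parameters.

Both are built on a compact numpy layer stack with hand-derived backward
passes (im2col convolutions, float32 throughout), verified by
finite-difference gradient checks and by the requirement that one Adam
step reduces the batch loss. Construction is pure: a configuration and
seed determine the architecture summary exactly.

## Training and evaluation protocol

Adam (lr 1e-3, β = 0.9/0.999), batch size 8, a fixed number of uniformly
sampled (without replacement per step) batches per epoch, up to 35 epochs.
The loss is softmax cross-entropy; validation loss is J = (1/N) Σ L(ŷᵢ, yᵢ)
over the whole validation set using running batch-norm statistics. The
stopping rule is *early stop by valid loss*: training halts the first
epoch J < 0.4. This halts on success, not stagnation — an unusual rule
implemented as stated; a conventional patience-based stop is available via
`TrainConfig.patience`. Splits are stratified by class, disjoint, and
seeded; default fractions 0.70/0.15/0.15 (train/test/valid).

Evaluation takes argmax decisions with Parkinson as the positive class:
TP/FN/FP/TN, accuracy, precision (PPV), recall = sensitivity, specificity,
and F1 (harmonic mean of precision and recall, checked numerically to
1e-12). Zero-denominator metrics report 0 and are listed in
`undefined_metrics` rather than raising.

## Synthetic cohorts

The simulator draws regions i.i.d. (default P(L)=P(R)=0.47, P(S)=0.06),
derives transitions from consecutive regions, and draws timings from
truncated-at-zero normals (log-normal optional) with class-specific
(mean, sd); Parkinson subjects get an additive offset on left-region hold
times. Timestamps advance by the latency draws. Three named scenarios:

- **default_scenario** — 162 Parkinson / 55 healthy, 300 events/subject;
  PD hold 110 ± 40 ms vs healthy 85 ± 25 ms, latency 260 ± 90 vs 200 ± 60,
  flight 160 ± 70 vs 120 ± 50, +15 ms left-hold asymmetry. Magnitudes are
  in the range reported for keystroke studies of PD; the imbalance ratio is
  the study condition this package targets.
- **separated_scenario** — balanced, 40/class, class means 3 pooled sd
  apart on all three series: the learnability condition.
- **null_scenario** — identical distributions, zero asymmetry: a negative
  control in which any above-chance accuracy indicates leakage.

What the simulator does *not* emulate: within-session drift and fatigue,
key-identity effects, autocorrelated typing bursts, medication cycles, and
between-subject heterogeneity of real cohorts. Passing tests therefore
demonstrate that the pipeline recovers class structure present in the
timing distributions — not clinical-grade performance on real patients.

## Problem sizes and determinism

The learnability experiment uses 40 subjects/class, 64×64 images, 10
steps/epoch (a full pass over the 80-image training split), ≤ 10 epochs,
five fixed seeds; the negative control uses 160/class with a 0.25/0.65/0.10
split so ≥ 200 images are tested, assessed by a two-sided binomial test at
α = 0.01. These sizes make the full suite run in minutes on one CPU while
leaving the conclusions unchanged at larger scale. Every random draw —
simulation, SMOTE, splits, initialization, batch order, augmentation —
flows through an explicit integer seed, so runs are bit-reproducible on a
given platform.

## Known limitations

- The direct-sum CWT is O(n·Σλ) per vector; an FFT formulation would be
  faster but the direct sum is the oracle-verified reference.
- Batch-norm running statistics converge over a few epochs; very short
  trainings can show eval-mode accuracy lagging train-mode loss.
- The numpy engine targets clarity and testability, not throughput; large
  image sizes (240×240) train slowly on one CPU.
- Region-level features discard key identity entirely; per-key features
  and disease-stage (UPDRS) covariates are out of scope.
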