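# Methods

## Problem and pipeline

Screening phonocardiogram (PCG) recordings for signs of cardiovascular
disease is a binary classification problem: a short chest-wall recording
(10–60 s, resampled to 2000 Hz) is labeled *healthy* or *unhealthy*.
`heartpcg` implements a five-stage pipeline:

1. **Ingestion** — WAV + manifest reading, channel averaging, polyphase
   resampling to 2000 Hz.
2. **Spectrogram** — short-time Fourier transform, dB scaling, min–max
   normalization, bilinear resize to a square image.
3. **Deep feature extraction** — a hybrid residual / attention / MLP-Mixer
   network trained with SGD + momentum and cross-entropy; features are read
   from the wide ReLU layer before the softmax head.
4. **Feature selection** — per-feature importances from NCA and ReliefF;
   the selected set is the intersection of the two top-*x* index sets.
5. **Classification** — polynomial-kernel SVM under repeated stratified
   10-fold cross-validation with full per-class confusion metrics.

## Spectrograms

Hamming window of 400 samples (0.2 s at 2000 Hz) with overlap 50 (hop 350);
no padding, so a record shorter than one window is rejected and the frame
count is `floor((L − 400)/350) + 1`. The transform length defaults to the
window length (201 frequency bins). A `matlab_truncate` compatibility mode
instead truncates each windowed frame to 50 samples before the FFT; this is
an escape hatch for tooling that pairs a 400-sample window with a 50-point
transform, which is otherwise ill-defined for a standard STFT. Magnitudes
are peak-normalized, dB-transformed with a floor of 1e−10 (a −200 dB
dynamic-range cap relative to the peak — this makes the image exactly
invariant to a constant signal gain), min–max rescaled to [0, 1] and
bilinearly resized to 200×200. The image is single-channel; colormaps are
applied only in the PNG export for human inspection, since they add no
information for the network. Frequency normalization (radians/sample) is
axis metadata only and never alters pixel values.

## The network

Both branches see the same one-channel image. Per stage the **residual
branch** applies a stride-2 3×3 conv (widths 32 then 64) followed by a
two-conv residual block with identity shortcut; the **attention branch**
uses the same stride-2 trunk and ends in a squeeze-and-excitation block
(global average squeeze, bottleneck ratio 4, sigmoid gates in (0, 1)
multiplied per channel). The branch outputs (50×50×64 each for a 200×200
input) are concatenated, reduced to 24 channels by a 1×1 conv, cut into
5×5 patches (20×20 in input pixels; 100 tokens), embedded to width 128 and
passed through 2 Mixer blocks (token-MLP hidden 64, channel-MLP hidden 412,
layer norm and residual connections, ReLU activations). Token-mean pooling
feeds a dense → ReLU layer of width 1000 — the deep-feature layer — and a
dense softmax head.

The default build has **582,114 learnable parameters**. The two-branch
topology, the 1000-unit feature layer, the concat merge and the overall
size are fixed design targets; block counts and widths within the branches
were open choices, set once so the default lands at that size, and all of
them are overridable in `RAMMConfig`.

Training: SGD with momentum 0.9, learning rate 0.001, batch size 16,
cross-entropy loss, He-style fan-in initialization seeded from the run
seed. The layers (conv via im2col, layer norm, SE, Mixer) and their
backward passes are implemented directly in numpy; a finite-difference
check in the test suite pins the analytic gradients to < 1e−3 relative
error on a small build.

## Feature selection

**NCA** is used in its diagonal feature-weighting form: weights `w` define
the metric `d_w(x_i, x_j) = Σ_r w_r² (x_ir − x_jr)²` and the objective is
the expected leave-one-out soft-nearest-neighbor accuracy
`f(w) = Σ_i Σ_{j ∈ class(i)} p_ij`,
`p_ij = exp(−d_w(x_i,x_j)) / Σ_{k≠i} exp(−d_w(x_i,x_k))`, minus an L2
penalty λ‖w‖² (default λ = 1/N). Only the diagonal form yields one
importance weight per feature, which is what the selector consumes; the
full-matrix variant learns a rotation and has no per-feature reading.
Features are standardized internally (zero-variance columns guarded with an
epsilon and a warning). Optimization is gradient ascent from `w = 1` (a
symmetric start, so duplicated features stay exactly tied) with a
backtracking line search, making the objective provably non-decreasing
across iterations; the reported weight is `w_r²`, the feature's
contribution scale in the learned metric, hence non-negative.

**ReliefF** starts from zero weights; for each instance (all N in
deterministic sequential order by default) it subtracts the range-scaled
feature differences to the k nearest same-class hits and adds the
prior-weighted differences to the k nearest misses per opposing class
(factor `P(C)/(1 − P(class(R_i)))`), each divided by `m·k`. `diff` is
`|a_i − a_j| / (max_a − min_a)`; constant features therefore score exactly
0 and all weights lie in [−1, 1]. Neighbors are ranked by Manhattan
distance on the range-scaled features, self excluded from hits, ties broken
toward the lowest index. Default k = 10.

**Matched-index selection** sorts both weight vectors descending, takes the
first top-*x* indices from each (ties at the boundary resolved toward the
lowest feature index) and returns their intersection, ordered by descending
NCA weight. The intersection may be empty (warning, not an error); its size
is data-dependent. Default top-*x* = 300 at full scale, 60 in the
reduced-scale configuration.

## Classification and metrics

SVM with polynomial kernel, degree 3, C = 1, coef0 = 1, features
standardized within each training fold — the common polynomial-kernel
defaults, overridable in `SVMConfig`. Folds are stratified (protecting the
~23% minority class) and reshuffled per repeat from the run seed; within a
repeat every sample is predicted exactly once and predictions pool into one
confusion matrix. Metrics are reported per class — sensitivity, specificity,
precision, F1 — as percentages rounded half-up to two decimals; zero
denominators yield *undefined* rather than 0. In the binary case
sensitivity of one class equals specificity of the other by construction.
Ablation comparisons (no selection vs single-method vs matched-index) share
identical fold assignments so arms differ only in the feature subset.
Before splitting, samples are put into a canonical order (label, then
feature values), so fold membership — and hence the whole report — depends
only on the data multiset and the seed, not on the order records arrive in.

## Synthetic data generator

Each record is a train of cardiac cycles at 70 ± 5 bpm: an S1 burst
(Gaussian-enveloped tone drawn from 30–80 Hz, amplitude 1.0) and an S2
burst (50–120 Hz, amplitude 0.7) separated by a 0.3 s systolic interval.
Unhealthy records add stationary band-passed noise (150–400 Hz, relative
amplitude 0.35) gated over systole — the rows of the spectrogram where real
murmurs live. White noise (σ = 0.02) is added to every record, records are
10 s at 2000 Hz, and the default class mix is 124/36 ≈ 77/23, mirroring the
imbalance of real screening corpora. Output WAVs are 16-bit PCM and
byte-identical for a fixed seed.

What the generator does **not** emulate: murmur sub-types (AS/MR/VSD),
diastolic murmurs, respiratory and handling noise, device responses,
sensor placement variability, or recording-length heterogeneity. Passing
the end-to-end tests on this data shows the pipeline's stages compose
correctly and that the selection/classification machinery exploits a real
spectral class difference; it does not certify performance on clinical
recordings.

## Problem sizes and numerical choices

The end-to-end evaluation runs at a reduced scale chosen as this package's
desk-scale study condition: 160 synthetic records, a narrow network
(widths 8/16, hidden 64, ~142k parameters), 6 training epochs, top-*x* 60,
one 10-fold CV — about 1–2 minutes on a single CPU. All arithmetic is
float64. Degenerate inputs are handled explicitly: constant spectrogram
grids map to a uniform 0.5 image with a warning; zero-variance features are
epsilon-guarded in NCA and score 0 in ReliefF; empty matched sets fall back
to evaluating all features in the pipeline.

## Known limitations

- The network trains on CPU in numpy; full-corpus training (thousands of
  200×200 images, 50 epochs) is out of reach here and the full-scale
  headline accuracy is correspondingly not reproduced — the pipeline's
  contracts are verified at reduced scale instead.
- NCA's objective is non-convex; the line-searched ascent finds a local
  optimum. With separable data and λ = 0 weights can grow until capped by
  `max_iters`.
- The reduced-scale matched-feature count (and the 128-of-300 figure at
  full scale) is data-dependent, not a contract.
- Reference-count metrics: the counts imply an unhealthy F1 of 97.33; a
  published table rounds it as 97.28. The counts are treated as primary.
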