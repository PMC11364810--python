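# Methods

## Problem and model

Motor-imagery EEG decoding assigns one of N imagined-movement classes to a
trial `X ∈ R^{C×T}` of C electrode channels and T samples. The decoder here
combines a convolutional front end, which captures local spectral-spatial
structure (band-passed temporal filters, per-filter spatial patterns), with
a Transformer encoder, which models dependencies across the whole token
sequence that the convolutional stage produces. The only preprocessing is a
per-trial scalar Z-score; no band-pass filtering, re-referencing or artifact
removal is applied.

Pipeline per trial:

1. **Temporal convolution** — `F1` kernels of shape `(1, K_C1)` with
   same-length zero padding on the time axis, no bias, batch norm. `K_C1`
   defaults to one quarter of the 250 Hz sampling rate (64), so the filters
   resolve rhythms above ≈4 Hz.
2. **Depth-wise convolution** — per temporal map, `D` spatial filters of
   shape `(C, 1)` (no padding, no bias), batch norm, ELU, average pooling
   `(1, P1)`, dropout `p1`.
3. **Spatial convolution** — `F2 = F1·D` kernels `(1, K_C2)`, same padding,
   no bias, batch norm, ELU, average pooling `(1, P2)`, dropout `p1`.
   The output is transposed to a sequence of `T_C = ⌊⌊T/P1⌋/P2⌋` tokens of
   width `d = F2`.
4. **Transformer encoder**, `L` post-norm layers. Attention uses `h` heads
   of width `d_k = d/h`; queries/keys/values are linear maps with biases;
   scores are scaled by `1/√d_k` and softmax-normalized over keys; head
   outputs are concatenated and projected (`W^O`, bias). Residual + layer
   norm follows the attention and the feed-forward sublayer
   (`d → 4d → d`, exact-erf GELU, dropout between the linears). No
   positional encoding: the token order information the classifier needs
   survives in the flattened readout, and adding a learned embedding would
   change the parameter budget.
5. **Classifier** — element-wise sum `S + E` of convolutional and encoded
   tokens (a residual fusion that also defines the encoder-ablated wiring),
   flatten, dropout `p2`, one fully-connected layer to `N` logits.

### Parameter accounting

Counts include batch-norm and layer-norm affine terms. At the 22-channel,
1000-sample, 4-class geometry: convolutional module 5,040 (temporal 512 +
BN 16 + depth-wise 352 + BN 32 + spatial 4,096 + BN 32), each encoder layer
3,280 (Q/K/V/O projections 4×272, two layer norms 64, feed-forward 2,128),
classifier 964; total 25,684 for L=6. The 3-channel, 2-class build gives
24,898. The test suite checks these integers and a closed-form formula over
randomized configurations. Three structural choices are pinned down *by*
this accounting: bias-free convolutions, feed-forward expansion 4 (expansion
2 would give ≈19.3 k), and the absence of a positional embedding.

### Why these defaults

`F1=8, D=2, K_C2=16, P1=P2=8, h=2, L=6` are the published global settings
for this architecture family on the BCI Competition IV benchmarks; two
heads match the two sensorimotor rhythms of interest (mu 8–13 Hz, beta
13–30 Hz). Dropout `p1` is 0.5 for subject-specific training and 0.25 for
cross-subject training (larger pooled training sets need less
regularization); `p2 = 0.5`; the feed-forward dropout defaults to 0.5.
Batch-norm momentum 0.1 and epsilon 1e-5 are framework-conventional and
recorded in the config for reproducibility.

## Numerical core

No deep-learning framework is used. `ctnet.autograd` implements a ~20-op
reverse-mode tensor autodiff (convolution via im2col + BLAS matmul, exact
softmax/erf/ELU vector-Jacobian products, broadcast-aware reductions);
`ctnet.nn` implements the layers and Adam. Correctness is established by
(a) central finite-difference gradient checks through the entire model,
(b) a scipy `correlate2d` oracle for the convolutions, and (c) an
independent step-by-step numpy transcription of the attention /
residual-norm / feed-forward chain that the encoder must match to 1e-5.
Forward inference in evaluation mode is bit-deterministic; all randomness
(init, dropout, shuffling, splits, augmentation) flows from explicit seeds
through separate `numpy` generator streams.

## Training protocols

* **Stratified validation split.** 30% of the initial training set, by
  largest-remainder apportionment across classes (overall fraction exact,
  each class within one trial), random within class with a fixed seed. The
  split is random rather than session-contiguous; session order is not
  modeled.
* **S&R augmentation.** Training trials of a class are cut into K equal
  contiguous segments; artificial trials concatenate, in original temporal
  order, segment k of a uniformly chosen same-class trial. Defaults K=8
  (125-sample segments at the benchmark geometry) and multiplier 1
  (training set doubled); both are explicit assumptions, configurable.
  Augmentation runs once per training run (static), after standardization
  and after the validation split, so validation and test data are never
  synthetic and never influence selection.
* **Optimization.** Adam, lr 0.001, β₁ 0.5, β₂ 0.999, epsilon 1e-8, no
  weight decay, categorical cross-entropy. All epochs run (no early
  stopping); the snapshot with minimum validation loss is returned. When
  the configured batch size (288 subject-specific / 512 LOSO in the
  benchmark protocol) exceeds the training-set size, a single full batch is
  used.
* **LOSO.** For each held-out subject the other subjects' trials are pooled
  as training data, the 30% validation split and the cross-subject dropout
  profile (p1 = 0.25) are applied, and the selected model is evaluated on
  the held-out subject. Leakage is audited in tests by SHA-1 fingerprints
  of trial bytes.

## Statistics

Accuracy is trace/total of the confusion matrix. Cohen's κ uses the
balanced-chance convention `P_e = 1/N` by default (the benchmark test
sessions are class-balanced; this convention reproduces the published mean
κ of 0.7670 from the printed IV-2a accuracies); a marginal-chance variant
is available. Aggregation reports mean ± sample standard deviation (n−1) of
per-subject accuracy percentages. Hedges' g applies the small-sample
correction `1 − 3/(4(n1+n2) − 9)` to pooled-SD Cohen's d — the correction
form conventionally used with nine-subject groups, not the exact
gamma-function factor.

The paired Wilcoxon signed-rank test is exact: zero differences dropped,
midranks for tied absolute differences, and the null distribution of the
positive-rank sum enumerated over all 2^n sign assignments via integer
convolution on doubled ranks (n ≤ 25). No normal approximation is ever
used, so printed benchmark p-values such as 1/512 = 0.0020 (nine positive
differences) and 3/512 = 0.0059 (one midrank-tied negative difference) are
reproduced bit-exactly. The default alternative is one-sided ("greater",
proposed minus baseline); published tables are not consistent about
sidedness, so both one-sided and two-sided variants are exposed and no
intent is guessed.

Published per-subject benchmark accuracy rows (IV-2a/IV-2b, both protocols)
are embedded in `ctnet.benchmarks` as worked-example inputs for this chain;
the package does not re-derive them from raw recordings.

## Synthetic data

`ctnet.synthetic` emulates the decodable signature of motor imagery:
band-limited oscillatory power differing between classes on designated
channels. Background is per-channel independent 1/f^a noise (a = 1.0,
EEG-like). Every channel mapped by any class carries a baseline unit-variance
narrow-band Gaussian oscillation (default mu band 8–13 Hz, hard FFT mask);
trials of class c get `(1+effect)`× that baseline band power on their mapped
channels. `effect = 0` makes classes exchangeable in distribution, which the
tests verify with an independent Welch periodogram estimate. The default
geometry (C=3, T=1000, fs=250, N=2, one mapped channel per class) mirrors
the 3-channel benchmark so fixtures are fast.

What the generator does *not* emulate: volume conduction / leadfields,
artifacts, non-stationarity, session effects, or realistic inter-subject
variability (synthetic "subjects" are i.i.d. draws). Passing end-to-end
tests therefore demonstrates that the implementation decodes band-power
contrasts of known size under controlled noise — not that it attains any
particular accuracy on real recordings.

## Desk-scale problem sizes

The test suite trains at reduced sizes chosen as sensible smoke-test
conditions: the subject-specific end-to-end check uses 100 trials/class for
training, an independent 100/class test session, batch 64 and 30 epochs at
effects {0, 1, 3}; the LOSO check uses three subjects at 30 trials/class and
10 epochs; unit tests use a T=256 geometry that preserves every
architectural stage. The benchmark protocol values (batch 288/512, 1000/600
epochs) remain the config defaults for full-scale runs on the real GDF data,
which are supported via the loader but not part of the test suite.

## Degenerate inputs and edge conventions

Constant trials (zero variance) raise a degenerate-input error from the
Z-score; Z-score uses the population (C·T-denominator) standard deviation.
Pooling floors partial windows. A trial window must contain an integer
number of samples. Cross-entropy on explicit probabilities clamps logs at
1e-12; the training loss uses a log-sum-exp formulation instead. The exact
Wilcoxon test refuses all-zero difference vectors; Hedges' g refuses zero
pooled variance (ablation reports map the identical-groups case to g = 0).
Rejected-trial markers in GDF recordings are honored by default with a
switch to keep them, since the benchmark's own convention is unstated.
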