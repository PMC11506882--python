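# Methods

## Problem and model

CSTGAT is a window classifier for multichannel intracranial EEG (iEEG):
given a short segment of an N-channel recording, decide whether it comes
from a pre-seizure or a seizure period.  The model couples three ideas:

1. **Causal graph construction.**  For each window, pairwise transfer
   entropy (TE) between channels yields a directed N x N matrix.  For
   discretized series x (target) and y (source), with target history
   length k, source history length l and lag 1,

       TE(Y→X) = Σ p(x_{i+1}, x_i^{(k)}, y_i^{(l)})
                 · log₂ [ p(x_{i+1} | x_i^{(k)}, y_i^{(l)}) / p(x_{i+1} | x_i^{(k)}) ]

   TE is asymmetric: it measures how much the source's recent past reduces
   uncertainty about the target's next sample beyond the target's own past.
   The matrix is sparsified into a binary graph (see below).

2. **Spatial encoding by multi-head graph attention.**  Node features are
   the raw window samples per channel, split into S consecutive
   sub-windows.  For each sub-window, every node i attends over its
   in-neighbourhood G_i (information flows into a node along causal
   edges): e_ij = LeakyReLU(aᵀ[Wv_i ∥ Wv_j]), α_ij = softmax_{j∈G_i}(e_ij),
   and the K heads are fused by **averaging**

       v_i′ = σ( (1/K) Σ_k Σ_{j∈G_i} α_ij^k W^k v_j ),   σ = ELU.

   Averaging (rather than the also-common concatenation) is the fusion
   this implementation commits to.

3. **Temporal encoding by BiLSTM + softmax.**  The per-sub-window graph
   embeddings form an S-step sequence that a bidirectional LSTM (standard
   forget/input/output gating, hidden size H) consumes in both directions;
   the two final hidden states are concatenated and classified by an
   affine layer + softmax over {pre-seizure, seizure}.

### Estimator choices

The TE estimator is the plug-in (histogram) rule: equal-width binning
(default 8 bins), k = l = 1, lag = 1, log base 2, empirical counts
substituted for every probability, and negative rounding artifacts clamped
at zero.  The plug-in rule is the direct transcription of the definition,
which makes it exactly checkable against an independent tuple-counting
oracle — the test suite asserts agreement to 1e-12.  Bin count, binning
strategy, k, l and lag are all configurable.  Kernel/KSG continuous
estimators, surrogate significance testing and conditional/multivariate TE
are out of scope.

Comparison graph builders for ablations: Granger causality
(ln(RSS_restricted/RSS_full) from OLS autoregressions, directed), absolute
Pearson correlation ("FC", symmetric), and plug-in mutual information
(symmetric).

### Graph construction

The matrix→graph step keeps, for every target node, its `k_in` = 3
strongest incoming edges (`top_k_in`), then adds self-loops.  Per-target
top-k guarantees that no node is isolated, which the attention softmax
requires; threshold and global-density rules are available as
alternatives.  Attention uses only the binary mask — the attention-logit
formula consumes node features, not edge weights — but weights are
retained on kept edges for inspection and export.  One graph is computed
per window from that window's own samples.

### Network interfaces and initialization

* GAT→BiLSTM interface: per-sub-window embeddings are mean-pooled over
  nodes by default (`pooling="mean"`), giving a D = F′ sequence element.
  `pooling="node_flatten"` concatenates node embeddings instead
  (D = N·F′), preserving node identity.  Mean-pooling is permutation
  invariant, which is the safe default for heterogeneous electrode
  layouts; node-flattening is the right choice when the *location* of
  information matters — the ablation study uses it for exactly that
  reason (below).
* LeakyReLU negative slope 0.2; ELU fusion activation; Glorot-uniform
  seeded initialization; dropout 0.2 applied to attention coefficients and
  to the sequence-encoder output, only during training.
* Ablation variants: `gat_only` replaces the BiLSTM with mean-pooling over
  the sequence; `bilstm_only` feeds flattened raw node features per
  sub-window to the BiLSTM.

### Training defaults

Adam (classic L2-style weight decay added to the gradient), cross-entropy
loss, learning rate 5e-4, weight decay 1e-5, dropout 0.2, 8 attention
heads, BiLSTM hidden size 192, 500 epochs, batch size 32 (batch size is
this package's choice; it is not fixed by the reference recipe).  Every
run is seeded: data shuffling, dropout masks and initialization all derive
from the config seed, and evaluation-mode forward passes are bit
reproducible.

The network and its gradients are implemented in numpy float64 on a small
reverse-mode autodiff tape (`cstgat.autodiff`) with a hand-written Adam.
This keeps every forward computation explicit and lets the test suite
gradient-check the full model against central finite differences (the
norm-relative error on a tiny instance is required to stay below 1e-4).

## Preprocessing

Fourth-order Butterworth bandpass 0.5–150 Hz, applied zero-phase
(forward–backward, `sosfiltfilt`) so seizure-onset timing is not shifted;
the squared magnitude response is the analytic oracle the filter tests use.
If the upper edge reaches Nyquist the band degrades to a high-pass with a
logged warning.

Around each annotated onset t0, the class-0 (pre-seizure) interval is
[t0 − 5 min, t0) and the class-1 (seizure) interval is [t0, t0 + min(30
min, annotated duration)); intervals are clipped at recording boundaries
and at the previous seizure's end, and never overlap across seizures.
Both durations are configurable.  All intervals are half-open, in
seconds; window offsets are 0-based sample indices.

Windows are cut by overlapping sliding windows per class period
(count = ⌊(L − window)/stride⌋ + 1).  Window length and strides are not
fixed by the problem statement; defaults are 2 s windows, 2 s class-1
stride, and a class-0 stride chosen automatically (logged) so the
pre-seizure minority class is oversampled to within 10% of the seizure
count.

Train/test splitting for subject experiments is **event-wise**: whole
seizure events (pre-seizure + seizure period) are held out.  Overlapping
windows from a single event would otherwise share samples across the
split; the harness exposes a `shuffled` protocol only to demonstrate that
this leakage inflates accuracy.

## Synthetic data

Real annotated iEEG is large and access-restricted, so the package
generates vector-autoregressive (VAR) surrogates with a known directed
coupling graph:

    x_c[t] = ar_self[c]·x_c[t−1] + Σ_{(s→c)} strength·x_s[t−lag] + ε,
    ε ~ N(0, noise_sd²)

Stability is enforced at construction (companion spectral radius < 1).
Recordings switch coefficient sets inside annotated "ictal" intervals
(state carries over at boundaries) and optionally add a sinusoid, so the
two classes can differ in coupling topology, spectral content, or both —
independently controllable, which lets the ablation isolate the purely
directional signal.

What the surrogates deliberately do **not** model: realistic neural-mass
dynamics, clinical artifacts, non-stationary noise, volume conduction, or
channel dropout.  Passing tests therefore demonstrate the correctness of
the estimators, the network, and the harness — not clinical performance.

### Reference studies (desk-scale conditions)

Two fixed studies are used by the tests and by `scripts/acceptance.py`;
their conditions are part of the package:

* **Separable study**: 8 channels, 400 windows of 512 samples (2 s at a
  nominal 256 Hz), two VAR regimes with reversed pair coupling (0.6), the
  seizure-like class adding a 7 Hz amplitude-2 oscillation.  Full model,
  fixture-scaled network (H = 32, F′ = 16, 4 heads, S = 8), 100 epochs,
  stratified 80/20 window split (valid here because windows are i.i.d. by
  construction).  Expected outcome: held-out accuracy ≥ 0.90, and ~0.50 on
  a label-permuted control.
* **Direction-only ablation**: same geometry but the classes differ
  *solely* in coupling direction (edges reversed; identical noise and
  per-channel AR coefficients).  Channels get distinct AR coefficients
  (0.2–0.8): with identical channel dynamics, reversing each pair would be
  a channel permutation, and any permutation-invariant readout would be
  provably blind — hence also the `node_flatten` interface for this study,
  since the quantity compared is whether the *location-resolved* graph
  structure carries class information.  Six variants ({TE,GC,FC,MI} + full
  model, TE+GAT-only, TE+BiLSTM-only) share the split and seed within each
  of 5 replicates, 400 windows and 50 epochs per replicate.  Symmetric
  builders (FC, MI) see identical graphs for both classes by construction;
  directed builders (TE, GC) should therefore rank above them in mean
  accuracy.  All variants sit well below the separable study's accuracy —
  the direction-only signal is intentionally subtle (it is second-order in
  the features), and near-chance accuracies for FC/MI are the designed
  outcome, not a failure.

Problem sizes for these studies were chosen so the full suite runs on a
single CPU at desk scale; the reference hyperparameters (H = 192, 8 heads,
500 epochs) remain the package defaults for real use.

## Numerical choices and edge cases

* Equal-width bins span [min, max]; values on an interior edge go to the
  lower bin.  Equal-frequency binning is rank-based with a stable sort;
  constant series degenerate to a single symbol (logged).
* TE/MI are clamped at 0 (nonnegative in population; −0.0 artifacts from
  finite counts).  Granger causality drops constant lag columns and falls
  back to a tiny ridge (1e-10) on rank-deficient designs, logged.
* Attention masking restricts the softmax support; excluded coefficients
  are exactly 0 and supported rows sum to 1.  An isolated node is an
  error that names the node.
* Sparsification tie-breaks: smaller source index, then smaller target
  index.
* Metric formulas are evaluated in exact rational arithmetic and rounded
  once; Pre := 0 when TP+FP = 0 and F1 := 0 when Sen+Pre = 0.  Positive
  class is seizure; prediction ties resolve to the positive class
  (logged).
* Checkpoints are HDF5 (float64) with a JSON hyperparameter sidecar;
  round-trips are bit exact.

## Known limitations

* The plug-in TE estimator is biased upward for short windows and many
  bins; per-window graphs at 2 s windows are noisy (systematically, not
  fatally — direction recovery at T = 4096 exceeds 95/100).
* One GAT layer (configurable head count only); no GCN baseline, no
  Transformer refinement, no cross-patient generalization experiments.
* EDF files can be read (via `mne` when installed) but not written;
  the canonical container is HDF5 + CSV annotations.
* The training loop is plain-python numpy; it is sized for desk-scale
  experiments, not for multi-gigabyte clinical recordings.
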