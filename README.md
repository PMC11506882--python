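# cstgat

Causal-spatio-temporal graph attention network for seizure detection in
multichannel intracranial EEG (iEEG).

Seizures propagate: during an event, information flows between electrode
channels along directed pathways.  `cstgat` detects seizure windows by
making that flow explicit — it estimates a **directed causal graph**
between channels with **transfer entropy (TE)**, encodes spatial structure
with a **multi-head graph attention network (GAT)**, encodes temporal
dynamics with a **bidirectional LSTM**, and classifies each window with a
softmax head.  The package is aimed at researchers studying
information-flow networks in neural time series who want a fully
inspectable, deterministic reference implementation with an ablation
harness (alternative graph builders: Granger causality, correlation,
mutual information; GAT-only and BiLSTM-only variants; attention-head
sweeps) and a synthetic-data generator with known ground-truth coupling.

## The model

For channels y (source) and x (target), discretized, with history lengths
k = l = 1:

    TE(Y→X) = Σ p(x_{i+1}, x_i^{(k)}, y_i^{(l)})
              · log₂ [ p(x_{i+1} | x_i^{(k)}, y_i^{(l)}) / p(x_{i+1} | x_i^{(k)}) ]

The N×N TE matrix is sparsified (top-3 incoming edges per node +
self-loops) into the binary graph G.  Each window's samples are split into
S sub-windows; per sub-window, node i attends over its in-neighbours G_i:

    e_ij = LeakyReLU(aᵀ[Wv_i ∥ Wv_j]),   α_ij = softmax_{j∈G_i}(e_ij)
    v_i′ = ELU( (1/K) Σ_k Σ_{j∈G_i} α_ij^k W^k v_j )        (K heads, averaged)

Pooled embeddings form an S-step sequence for the BiLSTM
(f/i/o gates with logistic sigmoid, candidate tanh,
c_t = f⊙c_{t−1} + i⊙c̃, h_t = o⊙tanh c_t); the concatenated final forward
and backward states feed an affine + softmax classifier.  Windows are
scored by the usual confusion metrics with seizure as positive class:
Acc, Sen = TP/(TP+FN), Spe = TN/(TN+FP), Pre = TP/(TP+FP),
F1 = 2·Sen·Pre/(Sen+Pre).

The network (including gradients and Adam) is implemented in numpy
float64 on a small built-in autodiff tape, so every computation is
explicit and the whole model is finite-difference checkable.  See
`docs/methods.md` for estimator details, design decisions and limitations.

## Worked example

```python
import numpy as np
from cstgat import (CouplingSpec, TEParams, simulate_var, te_matrix,
                    build_graph, transfer_entropy, discretize)

# two channels, ground-truth edge 0 -> 1 with strength 0.6
spec = CouplingSpec(n_channels=2, edges=((0, 1, 0.6),), ar_self=0.5, noise_sd=1.0)
x = simulate_var(spec, n_samples=4096, seed=0)

m = te_matrix(x)                       # directed TE matrix (bits)
print(np.round(m.values, 4))
graph = build_graph(m, sparsify="top_k_in", parameter=1)
print(graph.adjacency)
```

Output:

```
[[0.     0.2504]
 [0.0365 0.    ]]
[[1 1]
 [1 1]]
```

TE(0→1) = 0.250 bits exceeds TE(1→0) = 0.037 bits — the estimator ranks
the true coupling direction first (the reverse entry is not zero because
plug-in TE is upward-biased at finite sample size).  With two nodes,
keeping each node's strongest incoming edge plus self-loops yields the
full adjacency; the direction signal lives in the weights and, at larger
N, in which edges survive sparsification.

End-to-end, on the built-in separable synthetic study (400 windows, 8
channels, two VAR regimes):

```python
from cstgat import separable_study
r = separable_study(seed=1, epochs=100)
print(round(r["holdout_accuracy"], 3), round(r["permuted_accuracy"], 3))
```

```
1.0 0.512
```

The full pipeline separates the classes perfectly on held-out windows,
while a label-permuted control sits at chance — the pipeline does not leak.

A command-line interface wraps the same library:

```bash
cstgat simulate --out-dir runs/sim --n-channels 8 --n-seizures 2 --seed 1
cstgat connectivity --recording runs/sim/recording.h5 --method TE --out-dir runs/conn
cstgat train --recording runs/sim/recording.h5 --annotations runs/sim/annotations.csv \
             --epochs 20 --out-dir runs/model
cstgat ablate --recording runs/sim/recording.h5 --annotations runs/sim/annotations.csv \
              --epochs 20 --out-dir runs/ablation
```

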