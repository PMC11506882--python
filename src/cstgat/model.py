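"""The causal-spatio-temporal graph attention network (CSTGAT).

One labelled training sample is a :class:`GraphWindow`: an N x F node-feature
matrix (N electrode channels, F samples per channel) plus the binary causal
adjacency estimated from that same window.  The forward pass:

1. split each node's F samples into S consecutive sub-windows;
2. encode each sub-window spatially with a multi-head graph-attention layer —
   node i attends over its in-neighbourhood G_i (information flows *into*
   the node along causal edges), attention logits
   e_ij = LeakyReLU(a^T [W v_i || W v_j]) are softmax-normalized over G_i,
   and the K heads are fused by *averaging*:
   v_i' = sigma(1/K sum_k sum_{j in G_i} alpha_ij^k W^k v_j);
3. mean-pool node embeddings, giving one vector per sub-window;
4. run the S-step sequence through a bidirectional LSTM (standard
   forget/input/output gating) and concatenate the two final hidden states;
5. affine classifier + softmax over {pre-seizure, seizure}.

Two ablation variants replace a stage: ``gat_only`` mean-pools over the
sub-window sequence instead of the BiLSTM; ``bilstm_only`` feeds flattened
raw node features to the BiLSTM with no graph layer.

All parameters are float64 tensors on the local autodiff tape, so the whole
network is exactly differentiable and finite-difference checkable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .autodiff import Tensor, concatenate, softmax_cross_entropy

__all__ = [
    "GraphWindow",
    "GATHeadParams",
    "GATLayerParams",
    "LSTMParams",
    "ModelParams",
    "init_model_params",
    "attention_coefficients",
    "gat_forward",
    "lstm_step",
    "bilstm_forward",
    "cstgat_forward",
    "forward_batch",
    "save_checkpoint",
    "load_checkpoint",
    "gradient_check",
]

VARIANTS = ("full", "gat_only", "bilstm_only")


@dataclass(frozen=True)
class GraphWindow:
    """One labelled sample: node features, causal adjacency, class label."""

    node_features: np.ndarray  # N x F
    adjacency: np.ndarray  # N x N binary, (s, t) = edge s -> t
    label: int

    def __post_init__(self) -> None:
        feats = np.asarray(self.node_features, dtype=float)
        adj = np.asarray(self.adjacency, dtype=int)
        if feats.ndim != 2 or adj.shape != (feats.shape[0], feats.shape[0]):
            raise ValueError("node_features must be N x F with N x N adjacency")
        in_deg = adj.sum(axis=0)  # incoming edges per target node
        if (in_deg == 0).any():
            node = int(np.argmin(in_deg))
            raise ValueError(f"node {node} has no in-neighbours (add self-loops)")
        object.__setattr__(self, "node_features", feats)
        object.__setattr__(self, "adjacency", adj)


@dataclass
class GATHeadParams:
    W: Tensor  # F' x F shared linear transform
    a: Tensor  # 2F' attention vector
    leaky_slope: float = 0.2


@dataclass
class GATLayerParams:
    heads: list[GATHeadParams]
    activation: str = "elu"  # or "relu"


@dataclass
class LSTMParams:
    """Gate weights of one LSTM direction, named after the standard equations.

    ``W_*_m`` (H x D) act on the input m_t, ``W_*_h`` (H x H) on the previous
    hidden state, ``b_*`` are biases; gates f/i/o use the logistic sigmoid and
    the candidate cell c~ uses tanh.
    """

    W_f_m: Tensor
    W_i_m: Tensor
    W_c_m: Tensor
    W_o_m: Tensor
    W_f_h: Tensor
    W_i_h: Tensor
    W_c_h: Tensor
    W_o_h: Tensor
    b_f: Tensor
    b_i: Tensor
    b_c: Tensor
    b_o: Tensor

    @property
    def hidden_size(self) -> int:
        return self.W_f_h.shape[0]


@dataclass
class ModelParams:
    gat: GATLayerParams | None
    lstm_forward: LSTMParams | None
    lstm_backward: LSTMParams | None
    classifier_W: Tensor  # 2 x (classifier input)
    classifier_b: Tensor  # 2
    dropout_rate: float = 0.2
    variant: str = "full"
    pooling: str = "mean"
    hyper: dict = field(default_factory=dict)

    def tensors(self) -> list[Tensor]:
        out: list[Tensor] = []
        if self.gat is not None:
            for h in self.gat.heads:
                out += [h.W, h.a]
        for lstm in (self.lstm_forward, self.lstm_backward):
            if lstm is not None:
                out += [getattr(lstm, f.name) for f in lstm.__dataclass_fields__.values()]
        out += [self.classifier_W, self.classifier_b]
        return out


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> Tensor:
    fan_in = shape[-1] if len(shape) > 1 else shape[0]
    fan_out = shape[0]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


def _init_lstm(rng: np.random.Generator, hidden: int, input_size: int) -> LSTMParams:
    kw = {}
    for gate in "fico":
        kw[f"W_{gate}_m"] = _glorot(rng, (hidden, input_size))
        kw[f"W_{gate}_h"] = _glorot(rng, (hidden, hidden))
        kw[f"b_{gate}"] = Tensor(np.zeros(hidden), requires_grad=True)
    return LSTMParams(**kw)


def init_model_params(
    n_channels: int,
    feat_per_sub: int,
    gat_out: int = 16,
    heads: int = 8,
    hidden: int = 192,
    dropout_rate: float = 0.2,
    variant: str = "full",
    activation: str = "elu",
    leaky_slope: float = 0.2,
    pooling: str = "mean",
    seed: int = 0,
) -> ModelParams:
    """Seeded Glorot-uniform initialization of all learnable weights.

    ``pooling`` selects the graph-to-sequence interface: ``mean`` pools node
    embeddings per sub-window (permutation invariant); ``node_flatten``
    concatenates them, preserving node identity.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    if pooling not in ("mean", "node_flatten"):
        raise ValueError("pooling must be 'mean' or 'node_flatten'")
    rng = np.random.default_rng(seed)
    gat = None
    lstm_f = lstm_b = None
    if variant != "bilstm_only":
        gat = GATLayerParams(
            heads=[
                GATHeadParams(W=_glorot(rng, (gat_out, feat_per_sub)), a=_glorot(rng, (2 * gat_out,)), leaky_slope=leaky_slope)
                for _ in range(heads)
            ],
            activation=activation,
        )
    emb = gat_out * (n_channels if pooling == "node_flatten" else 1)
    if variant == "full":
        lstm_input, clf_input = emb, 2 * hidden
    elif variant == "gat_only":
        lstm_input, clf_input = 0, emb
    else:  # bilstm_only
        lstm_input, clf_input = n_channels * feat_per_sub, 2 * hidden
    if variant != "gat_only":
        lstm_f = _init_lstm(rng, hidden, lstm_input)
        lstm_b = _init_lstm(rng, hidden, lstm_input)
    clf_W = _glorot(rng, (2, clf_input))
    clf_b = Tensor(np.zeros(2), requires_grad=True)
    hyper = dict(
        n_channels=n_channels,
        feat_per_sub=feat_per_sub,
        gat_out=gat_out,
        heads=heads,
        hidden=hidden,
        dropout_rate=dropout_rate,
        variant=variant,
        activation=activation,
        leaky_slope=leaky_slope,
        pooling=pooling,
        seed=seed,
    )
    return ModelParams(
        gat=gat,
        lstm_forward=lstm_f,
        lstm_backward=lstm_b,
        classifier_W=clf_W,
        classifier_b=clf_b,
        dropout_rate=dropout_rate,
        variant=variant,
        pooling=pooling,
        hyper=hyper,
    )


# ---------------------------------------------------------------------------
# graph attention

def _neighbour_mask(adjacency: np.ndarray) -> np.ndarray:
    """mask[..., i, j] = 1 iff j is an in-neighbour of i (edge j -> i)."""
    mask = np.swapaxes(np.asarray(adjacency, dtype=float), -1, -2)
    rows = mask.sum(axis=-1)
    if (rows == 0).any():
        node = int(np.argwhere(rows == 0)[0][-1])
        raise ValueError(f"node {node} is isolated (no in-neighbours); attention undefined")
    return mask


def _attention_alpha(feats: Tensor, mask: np.ndarray, head: GATHeadParams, drop_mask: np.ndarray | None = None) -> tuple[Tensor, Tensor]:
    """Masked attention coefficients and transformed features for one head.

    ``feats``: (..., N, F).  Returns (alpha (..., N, N), Wv (..., N, F')).
    alpha rows are supported exactly on the in-neighbourhood: excluded
    entries are identically zero, included rows sum to one.
    """
    Wv = feats @ head.W.swapaxes(0, 1)  # (..., N, F')
    fp = head.W.shape[0]
    a_src = head.a[:fp].reshape(fp, 1)  # multiplies Wv_i (the attending node)
    a_dst = head.a[fp:].reshape(fp, 1)  # multiplies Wv_j (the neighbour)
    s_i = (Wv @ a_src).reshape(*Wv.shape[:-2], Wv.shape[-2], 1)  # (..., N, 1)
    s_j = (Wv @ a_dst).reshape(*Wv.shape[:-2], 1, Wv.shape[-2])  # (..., 1, N)
    e = (s_i + s_j).leaky_relu(head.leaky_slope)  # e[..., i, j]
    # softmax restricted to the supported entries of each row
    neg = np.where(mask > 0, e.data, -np.inf)
    row_max = neg.max(axis=-1, keepdims=True)  # constant shift, no gradient needed
    z = (e - Tensor(row_max)).exp() * Tensor(mask)
    alpha = z / z.sum(axis=-1, keepdims=True)
    if drop_mask is not None:
        alpha = alpha * Tensor(drop_mask)
    return alpha, Wv


def attention_coefficients(node_features: np.ndarray, adjacency: np.ndarray, head: GATHeadParams) -> np.ndarray:
    """N x N attention matrix alpha_ij of a single head (numpy output)."""
    mask = _neighbour_mask(adjacency)
    alpha, _ = _attention_alpha(Tensor(np.asarray(node_features, dtype=float)), mask, head)
    return alpha.data


def _gat_layer(feats: Tensor, mask: np.ndarray, params: GATLayerParams, drop_masks: list[np.ndarray] | None = None) -> Tensor:
    head_outs = []
    for idx, head in enumerate(params.heads):
        dm = drop_masks[idx] if drop_masks is not None else None
        alpha, Wv = _attention_alpha(feats, mask, head, dm)
        head_outs.append(alpha @ Wv)
    acc = head_outs[0]
    for h in head_outs[1:]:
        acc = acc + h
    fused = acc * (1.0 / len(head_outs))
    return fused.elu() if params.activation == "elu" else fused.relu()


def gat_forward(window: GraphWindow, params: GATLayerParams) -> np.ndarray:
    """Spatially encode one window's node features: returns N x F' (numpy)."""
    mask = _neighbour_mask(window.adjacency)
    out = _gat_layer(Tensor(window.node_features), mask, params)
    return out.data


# ---------------------------------------------------------------------------
# LSTM

def lstm_step(m_t: Tensor | np.ndarray, h_prev: Tensor | np.ndarray, c_prev: Tensor | np.ndarray, params: LSTMParams) -> tuple[Tensor, Tensor]:
    """One gated recurrence step.  Accepts (..., D) inputs, returns (h_t, c_t)."""
    m = Tensor._lift(m_t)
    h = Tensor._lift(h_prev)
    c = Tensor._lift(c_prev)
    f = (m @ params.W_f_m.swapaxes(0, 1) + h @ params.W_f_h.swapaxes(0, 1) + params.b_f).sigmoid()
    i = (m @ params.W_i_m.swapaxes(0, 1) + h @ params.W_i_h.swapaxes(0, 1) + params.b_i).sigmoid()
    c_tilde = (m @ params.W_c_m.swapaxes(0, 1) + h @ params.W_c_h.swapaxes(0, 1) + params.b_c).tanh()
    o = (m @ params.W_o_m.swapaxes(0, 1) + h @ params.W_o_h.swapaxes(0, 1) + params.b_o).sigmoid()
    c_t = f * c + i * c_tilde
    h_t = o * c_t.tanh()
    return h_t, c_t


def _run_lstm(seq: Tensor, params: LSTMParams, reverse: bool) -> Tensor:
    """Consume a (B, S, D) sequence in one direction; return final h (B, H)."""
    b, s, _ = seq.shape
    h = Tensor(np.zeros((b, params.hidden_size)))
    c = Tensor(np.zeros((b, params.hidden_size)))
    order = range(s - 1, -1, -1) if reverse else range(s)
    for t in order:
        h, c = lstm_step(seq[:, t], h, c, params)
    return h


def bilstm_forward(sequence: np.ndarray | Tensor, fwd: LSTMParams, bwd: LSTMParams) -> np.ndarray:
    """Bidirectional encoding of an S x D sequence -> concatenated 2H vector."""
    seq = Tensor._lift(sequence)
    if seq.ndim == 2:
        seq = seq.reshape(1, *seq.shape)
    if seq.shape[1] < 1:
        raise ValueError("sequence must have at least one step")
    h_f = _run_lstm(seq, fwd, reverse=False)
    h_b = _run_lstm(seq, bwd, reverse=True)
    out = concatenate([h_f, h_b], axis=-1)
    return out.data[0] if np.asarray(sequence).ndim == 2 else out.data


# ---------------------------------------------------------------------------
# full network

def _split_subwindows(feats: Tensor, s: int) -> list[Tensor]:
    """Split (..., N, F) features into S consecutive (..., N, F/S) blocks."""
    f_total = feats.shape[-1]
    if f_total % s != 0:
        valid = [d for d in range(1, f_total + 1) if f_total % d == 0]
        raise ValueError(f"window length {f_total} not divisible by S={s}; valid S include {valid[:8]}")
    f = f_total // s
    return [feats[..., i * f : (i + 1) * f] for i in range(s)]


def forward_batch(
    features: np.ndarray,
    adjacency: np.ndarray,
    params: ModelParams,
    sub_windows: int,
    train_mode: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[Tensor, np.ndarray]:
    """Batched forward pass.

    ``features``: (B, N, F_total); ``adjacency``: (B, N, N).  Returns the
    logits tensor (B, 2) — differentiable — and detached softmax
    probabilities.  Dropout (on attention coefficients and on the sequence
    encoder output) is applied only in ``train_mode`` and needs ``rng``.
    """
    feats = Tensor(np.asarray(features, dtype=float))
    p_drop = params.dropout_rate if train_mode else 0.0
    if p_drop > 0 and rng is None:
        raise ValueError("train_mode dropout requires an rng")

    def drop(shape):
        return (rng.random(shape) >= p_drop) / (1.0 - p_drop)

    blocks = _split_subwindows(feats, sub_windows)

    if params.variant == "bilstm_only":
        b, n, _ = feats.shape
        steps = [blk.reshape(b, 1, n * blk.shape[-1]) for blk in blocks]
    else:
        mask = _neighbour_mask(adjacency)
        steps = []
        for blk in blocks:
            dms = [drop(mask.shape) for _ in params.gat.heads] if p_drop > 0 else None
            emb = _gat_layer(blk, mask, params.gat, dms)  # (B, N, F')
            if params.pooling == "node_flatten":
                pooled = emb.reshape(emb.shape[0], emb.shape[1] * emb.shape[2])
            else:
                pooled = emb.mean(axis=-2)  # (B, F')
            steps.append(pooled.reshape(pooled.shape[0], 1, pooled.shape[-1]))

    if params.variant == "gat_only":
        seq = concatenate(steps, axis=1)  # (B, S, F')
        encoded = seq.mean(axis=1)  # (B, F')
    else:
        seq = concatenate(steps, axis=1)  # (B, S, D)
        h_f = _run_lstm(seq, params.lstm_forward, reverse=False)
        h_b = _run_lstm(seq, params.lstm_backward, reverse=True)
        encoded = concatenate([h_f, h_b], axis=-1)  # (B, 2H)

    if p_drop > 0:
        encoded = encoded * Tensor(drop(encoded.shape))
    logits = encoded @ params.classifier_W.swapaxes(0, 1) + params.classifier_b
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    return logits, probs


def cstgat_forward(
    window: GraphWindow,
    sub_windows: int,
    params: ModelParams,
    train_mode: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Class-probability 2-vector for a single window."""
    _, probs = forward_batch(
        window.node_features[None], window.adjacency[None], params, sub_windows, train_mode, rng
    )
    return probs[0]


# ---------------------------------------------------------------------------
# checkpointing

def save_checkpoint(params: ModelParams, path: str | Path) -> None:
    """HDF5 checkpoint mirroring the parameter structure + JSON hyperparameter sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        if params.gat is not None:
            g = f.create_group("gat")
            g.attrs["activation"] = params.gat.activation
            for i, head in enumerate(params.gat.heads):
                hg = g.create_group(f"head{i}")
                hg.create_dataset("W", data=head.W.data)
                hg.create_dataset("a", data=head.a.data)
                hg.attrs["leaky_slope"] = head.leaky_slope
        for name, lstm in (("lstm_forward", params.lstm_forward), ("lstm_backward", params.lstm_backward)):
            if lstm is not None:
                lg = f.create_group(name)
                for fld in lstm.__dataclass_fields__:
                    lg.create_dataset(fld, data=getattr(lstm, fld).data)
        cg = f.create_group("classifier")
        cg.create_dataset("W", data=params.classifier_W.data)
        cg.create_dataset("b", data=params.classifier_b.data)
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(params.hyper | {"dropout_rate": params.dropout_rate, "variant": params.variant}, fh, indent=2)


def load_checkpoint(path: str | Path) -> ModelParams:
    path = Path(path)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        hyper = json.load(fh)
    with h5py.File(path, "r") as f:
        gat = None
        if "gat" in f:
            heads = []
            g = f["gat"]
            for i in range(len(g)):
                hg = g[f"head{i}"]
                heads.append(
                    GATHeadParams(
                        W=Tensor(hg["W"][()], requires_grad=True),
                        a=Tensor(hg["a"][()], requires_grad=True),
                        leaky_slope=float(hg.attrs["leaky_slope"]),
                    )
                )
            gat = GATLayerParams(heads=heads, activation=str(g.attrs["activation"]))
        lstms = {}
        for name in ("lstm_forward", "lstm_backward"):
            if name in f:
                lg = f[name]
                lstms[name] = LSTMParams(**{fld: Tensor(lg[fld][()], requires_grad=True) for fld in lg})
            else:
                lstms[name] = None
        clf_W = Tensor(f["classifier/W"][()], requires_grad=True)
        clf_b = Tensor(f["classifier/b"][()], requires_grad=True)
    return ModelParams(
        gat=gat,
        lstm_forward=lstms["lstm_forward"],
        lstm_backward=lstms["lstm_backward"],
        classifier_W=clf_W,
        classifier_b=clf_b,
        dropout_rate=float(hyper.get("dropout_rate", 0.2)),
        variant=str(hyper.get("variant", "full")),
        pooling=str(hyper.get("pooling", "mean")),
        hyper=hyper,
    )


# ---------------------------------------------------------------------------
# verification utility

def gradient_check(
    params: ModelParams,
    features: np.ndarray,
    adjacency: np.ndarray,
    labels: np.ndarray,
    sub_windows: int,
    eps: float = 1e-6,
) -> float:
    """Max relative error between backprop and central finite differences.

    Runs the full network (no dropout) with cross-entropy loss and perturbs
    every parameter entry.  The error is reported per parameter tensor as
    ``max|analytic - numeric| / max(|analytic|_inf, |numeric|_inf, 1e-8)``
    — a norm-relative measure, so finite-difference roundoff on individual
    near-zero entries does not mask agreement.  Intended for tiny instances.
    """
    logits, _ = forward_batch(features, adjacency, params, sub_windows, train_mode=False)
    loss, _ = softmax_cross_entropy(logits, labels)
    loss.backward()
    worst = 0.0
    for p in params.tensors():
        analytic = p.grad.reshape(-1).copy()
        flat = p.data.reshape(-1)
        num = np.zeros_like(flat)
        for idx in range(flat.size):
            orig = flat[idx]
            flat[idx] = orig + eps
            lp, _ = softmax_cross_entropy(forward_batch(features, adjacency, params, sub_windows)[0], labels)
            flat[idx] = orig - eps
            lm, _ = softmax_cross_entropy(forward_batch(features, adjacency, params, sub_windows)[0], labels)
            flat[idx] = orig
            num[idx] = (lp.data - lm.data) / (2 * eps)
        denom = max(np.abs(analytic).max(), np.abs(num).max(), 1e-8)
        worst = max(worst, float(np.abs(analytic - num).max() / denom))
    return worst
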