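"""Directed channel-channel dependence and causal-graph construction.

The central quantity is transfer entropy (TE): how much the recent history
of a source channel reduces uncertainty about a target channel's next
sample, beyond the target's own history.  For discretized series with
target history length ``k`` and source history length ``l``,

    TE(Y -> X) = sum p(x_{i+1}, x_i^{(k)}, y^{(l)})
                 * log2 [ p(x_{i+1} | x_i^{(k)}, y^{(l)}) / p(x_{i+1} | x_i^{(k)}) ]

estimated by the plug-in rule: empirical counts substituted for every
probability.  TE is asymmetric, so the N x N matrix of pairwise estimates is
a *directed* connectivity matrix; entry (s, t) is the flow s -> t.

Three comparison builders are provided for ablations: Granger causality
(directed, linear), absolute Pearson correlation ("functional
connectivity", symmetric), and plug-in mutual information (symmetric).
A sparsification step turns any matrix into the binary graph the attention
network consumes; the default keeps each node's strongest incoming edges so
no node is isolated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DiscretizationParams",
    "TEParams",
    "CausalMatrix",
    "GraphSpec",
    "discretize",
    "shannon_entropy",
    "transfer_entropy",
    "te_matrix",
    "granger_causality",
    "mutual_information",
    "functional_connectivity",
    "causal_matrix",
    "build_graph",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_edge_list_tsv",
]

METHODS = ("TE", "GC", "FC", "MI")
SYMMETRIC_METHODS = frozenset({"FC", "MI"})


@dataclass(frozen=True)
class DiscretizationParams:
    """Binning scheme used before the information-theoretic estimators."""

    n_bins: int = 8
    strategy: str = "equal-width"

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.strategy not in ("equal-width", "equal-frequency"):
            raise ValueError(f"unknown strategy {self.strategy!r}")


@dataclass(frozen=True)
class TEParams:
    """Histories and binning for the plug-in TE estimator.

    ``k``: target-history length; ``l``: source-history length; ``lag``:
    samples between the end of the source history and the predicted target
    sample (lag=1 means the source history ends one step before the target
    future, the conventional choice).
    """

    k: int = 1
    l: int = 1
    lag: int = 1
    discretization: DiscretizationParams = field(default_factory=DiscretizationParams)

    def __post_init__(self) -> None:
        if min(self.k, self.l, self.lag) < 1:
            raise ValueError("k, l, lag must all be >= 1")


@dataclass(frozen=True)
class CausalMatrix:
    """N x N dependence matrix; entry (s, t) = dependence of flow s -> t."""

    values: np.ndarray
    method: str
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("values must be square")
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        if self.method != "GC" and np.any(v < -1e-12):
            raise ValueError(f"{self.method} entries must be nonnegative")
        object.__setattr__(self, "values", v)
        if not self.channel_names:
            object.__setattr__(self, "channel_names", tuple(f"ch{i:02d}" for i in range(v.shape[0])))

    @property
    def symmetric(self) -> bool:
        return self.method in SYMMETRIC_METHODS

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class GraphSpec:
    """Sparsified graph: binary adjacency (s, t) = edge s -> t, plus retained weights."""

    adjacency: np.ndarray
    edge_weights: np.ndarray
    sparsify: str
    parameter: float

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=int)
        w = np.asarray(self.edge_weights, dtype=float)
        if adj.shape != w.shape or adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency and edge_weights must be square and congruent")
        if np.any(w[adj == 0] != 0):
            raise ValueError("weights must be zero where adjacency is zero")
        object.__setattr__(self, "adjacency", adj)
        object.__setattr__(self, "edge_weights", w)


# ---------------------------------------------------------------------------
# discretization and entropies

def discretize(series: np.ndarray, params: DiscretizationParams) -> np.ndarray:
    """Map a real series to integer symbols in ``[0, n_bins)``.

    Equal-width bins span [min, max]; a value landing exactly on an interior
    edge goes to the lower bin.  Equal-frequency bins are rank-based (stable
    sort), so bin counts are as equal as the tie structure allows; a
    constant series degenerates to a single symbol.
    """
    x = np.asarray(series, dtype=float).ravel()
    lo, hi = x.min(), x.max()
    if lo == hi:
        if params.strategy == "equal-frequency":
            logger.warning("constant series under equal-frequency binning; single symbol")
        return np.zeros(len(x), dtype=np.int64)
    if params.strategy == "equal-width":
        edges = np.linspace(lo, hi, params.n_bins + 1)[1:-1]
        return np.digitize(x, edges, right=True).astype(np.int64)
    if len(x) < params.n_bins:
        raise ValueError("series shorter than n_bins under equal-frequency binning")
    ranks = np.empty(len(x), dtype=np.int64)
    ranks[np.argsort(x, kind="stable")] = np.arange(len(x))
    return (ranks * params.n_bins) // len(x)


def shannon_entropy(symbols: np.ndarray) -> float:
    """Plug-in Shannon entropy in bits of an integer symbol vector."""
    s = np.asarray(symbols)
    if s.size == 0:
        raise ValueError("empty symbol vector")
    counts = np.bincount(s.ravel().astype(np.int64))
    p = counts[counts > 0] / s.size
    return float(-(p * np.log2(p)).sum())


def _history_codes(sym: np.ndarray, ends: np.ndarray, length: int, alphabet: int) -> np.ndarray:
    """Encode the tuples (sym[e], sym[e-1], ..., sym[e-length+1]) as integers."""
    code = np.zeros(len(ends), dtype=np.int64)
    for j in range(length):
        code = code * alphabet + sym[ends - j]
    return code


def transfer_entropy(source: np.ndarray, target: np.ndarray, params: TEParams) -> float:
    """Plug-in transfer entropy, in bits, from ``source`` to ``target``.

    Inputs are integer symbol vectors (discretize first for real data).
    The estimate is clamped at zero: TE is nonnegative in population but
    -0.0 rounding can occur for degenerate inputs.
    """
    x = np.asarray(target, dtype=np.int64).ravel()
    y = np.asarray(source, dtype=np.int64).ravel()
    if len(x) != len(y):
        raise ValueError("source and target must have equal length")
    k, l, lag = params.k, params.l, params.lag
    n = len(x)
    if n <= k + l + lag:
        raise ValueError(f"series length {n} too short for k={k}, l={l}, lag={lag}")
    alphabet = int(max(x.max(), y.max())) + 1
    # present indices i: target future is x[i+1]; target history x[i..i-k+1];
    # source history y[i+1-lag .. i+2-lag-l]
    start = max(k - 1, lag + l - 2)
    i = np.arange(start, n - 1)
    xf = x[i + 1]
    xk = _history_codes(x, i, k, alphabet)
    yl = _history_codes(y, i + 1 - lag, l, alphabet)

    n_xk = alphabet**k
    n_yl = alphabet**l
    code_xky = xk * n_yl + yl
    code_fxk = xf * n_xk + xk
    code_full = code_fxk * n_yl + yl

    c_xk = np.bincount(xk, minlength=n_xk)
    c_xky = np.bincount(code_xky, minlength=n_xk * n_yl)
    c_fxk = np.bincount(code_fxk, minlength=alphabet * n_xk)
    c_full = np.bincount(code_full, minlength=alphabet * n_xk * n_yl)

    ratio = (c_full[code_full] * c_xk[xk]) / (c_xky[code_xky] * c_fxk[code_fxk])
    te = float(np.log2(ratio).mean())
    return max(te, 0.0)


# ---------------------------------------------------------------------------
# comparison builders

def granger_causality(source: np.ndarray, target: np.ndarray, order: int = 2) -> float:
    """Bivariate Granger causality ln(RSS_restricted / RSS_full).

    The restricted model regresses the target on its own ``order`` lags (plus
    intercept); the full model adds the source's ``order`` lags, both fit by
    ordinary least squares.  Degenerate (constant) lag columns are dropped;
    a rank-deficient design falls back to a tiny ridge penalty.
    """
    x = np.asarray(source, dtype=float).ravel()
    y = np.asarray(target, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("source and target must have equal length")
    n = len(y)
    if n <= 10 * order:
        raise ValueError(f"need length > {10 * order} for order={order}")

    t = np.arange(order, n)
    own = np.column_stack([y[t - p] for p in range(1, order + 1)])
    cross = np.column_stack([x[t - p] for p in range(1, order + 1)])
    resp = y[t]

    def rss(design: np.ndarray) -> float:
        cols = [np.ones(len(design))]
        for col in design.T:
            if np.ptp(col) > 0:
                cols.append(col)
        d = np.column_stack(cols)
        beta, _, rank, _ = np.linalg.lstsq(d, resp, rcond=None)
        if rank < d.shape[1]:
            logger.warning("rank-deficient Granger design; ridge fallback")
            g = d.T @ d + 1e-10 * np.eye(d.shape[1])
            beta = np.linalg.solve(g, d.T @ resp)
        r = resp - d @ beta
        return float(r @ r)

    rss_r = rss(own)
    rss_f = rss(np.column_stack([own, cross]))
    if rss_f <= 0 or rss_r <= 0:
        return 0.0
    return float(np.log(rss_r / rss_f))


def mutual_information(x: np.ndarray, y: np.ndarray, params: DiscretizationParams) -> float:
    """Plug-in mutual information in bits: H(X) + H(Y) - H(X, Y)."""
    xs = discretize(x, params)
    ys = discretize(y, params)
    if len(xs) != len(ys):
        raise ValueError("series must have equal length")
    joint = xs * (int(ys.max()) + 1) + ys
    mi = shannon_entropy(xs) + shannon_entropy(ys) - shannon_entropy(joint)
    return max(float(mi), 0.0)


def functional_connectivity(x: np.ndarray, y: np.ndarray) -> float:
    """Absolute Pearson correlation in [0, 1]."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("zero-variance series in functional connectivity; returning 0")
        return 0.0
    return float(abs(np.corrcoef(x, y)[0, 1]))


# ---------------------------------------------------------------------------
# matrices

def te_matrix(window: np.ndarray, params: TEParams | None = None) -> CausalMatrix:
    """Pairwise TE matrix of a channels x samples window; entry (s, t) = TE(s -> t)."""
    params = params or TEParams()
    w = np.asarray(window, dtype=float)
    if w.ndim != 2 or w.shape[0] < 2:
        raise ValueError("window must be channels x samples with >= 2 channels")
    n = w.shape[0]
    symbols = [discretize(w[c], params.discretization) for c in range(n)]
    values = np.zeros((n, n))
    for s in range(n):
        for t in range(n):
            if s != t:
                values[s, t] = transfer_entropy(symbols[s], symbols[t], params)
    return CausalMatrix(values=values, method="TE")


def causal_matrix(
    window: np.ndarray,
    method: str = "TE",
    te_params: TEParams | None = None,
    gc_order: int = 2,
    discretization: DiscretizationParams | None = None,
) -> CausalMatrix:
    """Channel-pair dependence matrix for any of the four builders."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if method == "TE":
        return te_matrix(window, te_params)
    w = np.asarray(window, dtype=float)
    n = w.shape[0]
    disc = discretization or (te_params.discretization if te_params else DiscretizationParams())
    values = np.zeros((n, n))
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            if method == "GC":
                values[s, t] = max(granger_causality(w[s], w[t], gc_order), 0.0)
            elif t > s:  # symmetric methods: compute once, mirror
                v = (
                    functional_connectivity(w[s], w[t])
                    if method == "FC"
                    else mutual_information(w[s], w[t], disc)
                )
                values[s, t] = values[t, s] = v
    return CausalMatrix(values=values, method=method)


# ---------------------------------------------------------------------------
# graph construction

def build_graph(
    matrix: CausalMatrix,
    sparsify: str = "top_k_in",
    parameter: float = 3,
    self_loops: bool = True,
) -> GraphSpec:
    """Sparsify a dependence matrix into the binary graph fed to the GAT.

    ``top_k_in`` keeps the ``parameter`` largest incoming weights per target
    node (guaranteeing no isolated nodes once self-loops are added);
    ``threshold`` keeps entries strictly above ``parameter``; ``density``
    keeps the ``ceil(parameter * N * (N-1))`` globally largest off-diagonal
    entries.  Ties break toward the smaller source index, then smaller
    target index.  Self-loops (weight 0) are added afterwards if requested.
    """
    v = matrix.values
    n = v.shape[0]
    adj = np.zeros((n, n), dtype=int)
    if sparsify == "top_k_in":
        k = int(parameter)
        if k < 1 or k >= n:
            raise ValueError(f"top_k_in needs 1 <= k < N, got k={k}, N={n}")
        for t in range(n):
            sources = [s for s in range(n) if s != t]
            sources.sort(key=lambda s: (-v[s, t], s))
            for s in sources[:k]:
                adj[s, t] = 1
    elif sparsify == "threshold":
        adj[(v > parameter)] = 1
        np.fill_diagonal(adj, 0)
    elif sparsify == "density":
        if not (0 < parameter <= 1):
            raise ValueError("density parameter must lie in (0, 1]")
        m = int(np.ceil(parameter * n * (n - 1)))
        offdiag = [(s, t) for s in range(n) for t in range(n) if s != t]
        offdiag.sort(key=lambda st: (-v[st], st[0], st[1]))
        for s, t in offdiag[:m]:
            adj[s, t] = 1
    else:
        raise ValueError(f"unknown sparsify rule {sparsify!r}")
    weights = np.where(adj == 1, v, 0.0)
    if self_loops:
        np.fill_diagonal(adj, 1)
    return GraphSpec(adjacency=adj, edge_weights=weights, sparsify=sparsify, parameter=float(parameter))


# ---------------------------------------------------------------------------
# TSV I/O

def write_matrix_tsv(matrix: CausalMatrix, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        f.write("\t".join(matrix.channel_names) + "\n")
        for row in matrix.values:
            f.write("\t".join(repr(float(x)) for x in row) + "\n")


def read_matrix_tsv(path: str | Path, method: str = "TE") -> CausalMatrix:
    with open(path) as f:
        names = tuple(f.readline().rstrip("\n").split("\t"))
        values = np.array([[float(x) for x in line.split("\t")] for line in f])
    return CausalMatrix(values=values, method=method, channel_names=names)


def write_edge_list_tsv(graph: GraphSpec, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        f.write("source\ttarget\tweight\n")
        src, tgt = np.nonzero(graph.adjacency)
        for s, t in zip(src, tgt):
            f.write(f"{s}\t{t}\t{float(graph.edge_weights[s, t])!r}\n")
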