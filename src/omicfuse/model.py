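"""Multi-reconstruction graph-convolutional autoencoder.

The network embeds V omics layers into one consensus space and is trained by
jointly reconstructing, per omics, both the expression matrix (node
attributes) and the kNN similarity graph (structure):

* per-omics GCN encoder:   Z_m = tanh(T Z_{m-1} W_m),  T = D^{-1/2}(A+I)D^{-1/2}
* consensus fusion:        h_j = mean of the available per-omics embeddings
                           of intact sample j (indicator-matrix weighted)
* attribute decoder:       first layer tanh((G H) W'), then propagated tanh
                           layers back to the omics' feature dimension
* bilinear graph decoder:  A_hat = tanh((G H) W~ (G H)^T)
* DEC-style refinement:    Student-t soft assignment Q of H to centers mu,
                           sharpened target P, loss KL(P || Q)

Total loss  L = L_nar + alpha * L_gsr + beta * L_ss  with squared-Frobenius
reconstruction terms.  Everything is dense numpy; gradients for training are
derived analytically in :func:`loss_and_grads` (finite-difference checked in
the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .graphs import IndicatorMatrix, NormalizedOperator

_EPS = 1e-12  # floor inside soft-assignment denominators


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass
class EncoderStack:
    """Per-omics lists of encoder weight matrices; tanh activation throughout."""

    layers: list[list[np.ndarray]]

    @property
    def depth(self) -> int:
        return len(self.layers[0])


@dataclass
class DecoderStack:
    """Per-omics decoder weights, applied first-to-last starting from H."""

    layers: list[list[np.ndarray]]


@dataclass
class GraphDecoderWeights:
    """Per-omics d x d bilinear matrices for graph reconstruction."""

    mats: list[np.ndarray]


@dataclass
class ConsensusEmbedding:
    """Shared N x d embedding; row j averages omics embeddings of sample j."""

    H: np.ndarray

    @property
    def d(self) -> int:
        return self.H.shape[1]


@dataclass
class ClusterCenters:
    mu: np.ndarray


@dataclass
class SoftAssignment:
    """Row-stochastic soft labels Q and sharpened target P (both N x C)."""

    Q: np.ndarray
    P: np.ndarray


@dataclass
class LossBreakdown:
    l_nar: float
    l_gsr: float
    l_ss: float
    alpha: float
    beta: float
    total: float = field(init=False)

    def __post_init__(self) -> None:
        self.total = self.l_nar + self.alpha * self.l_gsr + self.beta * self.l_ss


def total_loss(
    l_nar: float, l_gsr: float, l_ss: float, alpha: float, beta: float
) -> LossBreakdown:
    """Combine the three loss components with trade-off weights alpha, beta."""
    if alpha < 0 or beta < 0:
        raise ValueError(f"trade-off weights must be >= 0, got alpha={alpha}, beta={beta}")
    return LossBreakdown(l_nar=l_nar, l_gsr=l_gsr, l_ss=l_ss, alpha=alpha, beta=beta)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _as_h(h) -> np.ndarray:
    return h.H if isinstance(h, ConsensusEmbedding) else np.asarray(h, dtype=float)


def _as_op(op) -> np.ndarray:
    return op.op if isinstance(op, NormalizedOperator) else np.asarray(op, dtype=float)


def _indices(g) -> np.ndarray | None:
    """Row->column index representation of an indicator; None means identity."""
    if g is None:
        return None
    if isinstance(g, IndicatorMatrix):
        return g.indices
    g = np.asarray(g)
    return np.argmax(g, axis=1)


def _select(h: np.ndarray, idx: np.ndarray | None) -> np.ndarray:
    """G . H without materializing G (exact row selection)."""
    return h if idx is None else h[idx]


def glorot_uniform(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape)


def init_params(
    dims: Sequence[int],
    hidden: Sequence[int],
    d: int,
    rng: np.random.Generator,
    depth: int = 2,
) -> dict:
    """Glorot-initialized encoder/decoder/graph-decoder weights for all omics.

    Encoder widths per omics: D_v -> hidden_v (depth-1 times) -> d; the
    attribute decoder mirrors it in reverse.  ``mu`` starts unset (None) and
    is attached when fine-tuning begins.
    """
    enc, dec, graph = [], [], []
    for d_v, h_v in zip(dims, hidden):
        widths = [int(d_v)] + [int(h_v)] * (depth - 1) + [int(d)]
        enc.append([glorot_uniform((widths[m], widths[m + 1]), rng) for m in range(depth)])
        rev = widths[::-1]
        dec.append([glorot_uniform((rev[m], rev[m + 1]), rng) for m in range(depth)])
        graph.append(glorot_uniform((int(d), int(d)), rng))
    return {"enc": enc, "dec": dec, "graph": graph, "mu": None}


# ---------------------------------------------------------------------------
# forward operations
# ---------------------------------------------------------------------------


def encode_omics(x: np.ndarray, op, enc: EncoderStack, v: int) -> np.ndarray:
    """Run omics v through its GCN encoder: Z_m = tanh(T Z_{m-1} W_m)."""
    t = _as_op(op)
    z = np.asarray(x, dtype=float)
    for m, w in enumerate(enc.layers[v], start=1):
        if z.shape[1] != w.shape[0]:
            raise ValueError(
                f"encoder layer {m} of omics {v}: input has {z.shape[1]} columns "
                f"but weight expects {w.shape[0]}"
            )
        z = np.tanh(t @ z @ w)
    return z


def fuse_consensus(z_list: Sequence[np.ndarray], g_list: Sequence) -> ConsensusEmbedding:
    """Average each intact sample's embeddings over the omics that measured it.

    h_j = (sum_v sum_i G_ij^(v) z_i^(v)) / (sum_v sum_i G_ij^(v)); raises if
    some intact sample appears in no omics (zero denominator).
    """
    n = len(g_list[0].col_ids) if isinstance(g_list[0], IndicatorMatrix) else np.asarray(
        g_list[0]
    ).shape[1]
    d = z_list[0].shape[1]
    num = np.zeros((n, d))
    counts = np.zeros(n)
    for z, g in zip(z_list, g_list):
        idx = _indices(g)
        if idx is None:
            idx = np.arange(z.shape[0])
        np.add.at(num, idx, z)
        np.add.at(counts, idx, 1.0)
    if np.any(counts == 0):
        missing = int(np.flatnonzero(counts == 0)[0])
        raise ValueError(f"intact sample at position {missing} is absent from every omics")
    return ConsensusEmbedding(H=num / counts[:, None])


def decode_attributes(h, op, dec: DecoderStack, g, v: int) -> np.ndarray:
    """Reconstruct omics v's expression from the consensus embedding.

    The first decoder layer applies tanh((G H) W') with no propagation; each
    subsequent layer propagates through the omics' operator, ending at the
    original feature dimension.
    """
    t = _as_op(op)
    y = _select(_as_h(h), _indices(g))
    for j, w in enumerate(dec.layers[v]):
        if y.shape[1] != w.shape[0]:
            raise ValueError(
                f"decoder layer {j} of omics {v}: input has {y.shape[1]} columns "
                f"but weight expects {w.shape[0]}"
            )
        pre = y @ w if j == 0 else t @ y @ w
        y = np.tanh(pre)
    return y


def decode_graph(h, wt: GraphDecoderWeights, g, v: int) -> np.ndarray:
    """Bilinear graph reconstruction A_hat = tanh((G H) W~ (G H)^T)."""
    hv = _select(_as_h(h), _indices(g))
    w = wt.mats[v]
    if w.shape != (hv.shape[1], hv.shape[1]):
        raise ValueError(
            f"graph decoder of omics {v}: expected {hv.shape[1]}x{hv.shape[1]} "
            f"bilinear matrix, got {w.shape}"
        )
    return np.tanh(hv @ w @ hv.T)


def attribute_reconstruction_loss(
    x_list: Sequence[np.ndarray], xhat_list: Sequence[np.ndarray]
) -> float:
    """Sum over omics of the squared Frobenius reconstruction error."""
    tot = 0.0
    for v, (x, xh) in enumerate(zip(x_list, xhat_list)):
        if x.shape != xh.shape:
            raise ValueError(f"omics {v}: shape mismatch {x.shape} vs {xh.shape}")
        tot += float(np.sum((x - xh) ** 2))
    return tot


def graph_reconstruction_loss(
    a_list: Sequence[np.ndarray], ahat_list: Sequence[np.ndarray]
) -> float:
    """Sum over omics of the squared Frobenius graph reconstruction error."""
    tot = 0.0
    for v, (a, ah) in enumerate(zip(a_list, ahat_list)):
        if a.shape != ah.shape:
            raise ValueError(f"omics {v}: shape mismatch {a.shape} vs {ah.shape}")
        tot += float(np.sum((a - ah) ** 2))
    return tot


def soft_assignment(h, mu) -> np.ndarray:
    """Student-t (one degree of freedom) soft cluster assignment Q.

    Q_ij is proportional to (1 + ||h_i - mu_j||^2)^-1 and each row sums to 1.
    """
    hm = _as_h(h)
    m = mu.mu if isinstance(mu, ClusterCenters) else np.asarray(mu, dtype=float)
    sq = np.sum((hm[:, None, :] - m[None, :, :]) ** 2, axis=2)
    q_un = 1.0 / (1.0 + sq)
    return q_un / np.maximum(q_un.sum(axis=1, keepdims=True), _EPS)


def target_distribution(q: np.ndarray) -> np.ndarray:
    """Sharpened target P_ij ∝ Q_ij^2 / f_j with f_j the soft cluster frequency."""
    f = q.sum(axis=0)
    if np.any(f <= 0):
        empty = int(np.flatnonzero(f <= 0)[0])
        raise ValueError(f"soft cluster {empty} has zero total assignment")
    num = q**2 / f[None, :]
    return num / np.maximum(num.sum(axis=1, keepdims=True), _EPS)


def self_supervised_loss(p: np.ndarray, q: np.ndarray) -> float:
    """KL(P || Q) with the convention 0 log 0 = 0 (natural logarithm)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    mask = p > 0
    if np.any(q[mask] == 0):
        raise ValueError("Q has a zero where P is positive: KL divergence is infinite")
    out = np.zeros_like(p)
    out[mask] = p[mask] * np.log(p[mask] / q[mask])
    return float(out.sum())


# ---------------------------------------------------------------------------
# joint forward + analytic backward
# ---------------------------------------------------------------------------


def model_forward(
    params: dict,
    x_list: Sequence[np.ndarray],
    t_list: Sequence[np.ndarray],
    idx_list: Sequence[np.ndarray | None],
    n: int,
) -> dict:
    """Full forward pass; returns H plus per-omics activation caches."""
    enc_acts: list[list[np.ndarray]] = []
    d = params["enc"][0][-1].shape[1]
    num = np.zeros((n, d))
    counts = np.zeros(n)
    for x, t, idx, ws in zip(x_list, t_list, idx_list, params["enc"]):
        acts = [np.asarray(x, dtype=float)]
        for w in ws:
            acts.append(np.tanh(t @ acts[-1] @ w))
        enc_acts.append(acts)
        z = acts[-1]
        if idx is None:
            num += z
            counts += 1.0
        else:
            np.add.at(num, idx, z)
            np.add.at(counts, idx, 1.0)
    if np.any(counts == 0):
        missing = int(np.flatnonzero(counts == 0)[0])
        raise ValueError(f"intact sample at position {missing} is absent from every omics")
    h = num / counts[:, None]

    dec_acts: list[list[np.ndarray]] = []
    ahat_list: list[np.ndarray] = []
    hv_list: list[np.ndarray] = []
    for t, idx, ws, wg in zip(t_list, idx_list, params["dec"], params["graph"]):
        hv = _select(h, idx)
        hv_list.append(hv)
        acts = []
        y = hv
        for j, w in enumerate(ws):
            pre = y @ w if j == 0 else t @ y @ w
            y = np.tanh(pre)
            acts.append(y)
        dec_acts.append(acts)
        ahat_list.append(np.tanh(hv @ wg @ hv.T))
    return {
        "H": h,
        "counts": counts,
        "enc_acts": enc_acts,
        "dec_acts": dec_acts,
        "ahat": ahat_list,
        "hv": hv_list,
    }


def loss_and_grads(
    params: dict,
    x_list: Sequence[np.ndarray],
    t_list: Sequence[np.ndarray],
    idx_list: Sequence[np.ndarray | None],
    a_list: Sequence[np.ndarray],
    n: int,
    alpha: float,
    beta: float,
    p_target: np.ndarray | None = None,
) -> tuple[LossBreakdown, dict, dict]:
    """Evaluate the total loss and its analytic gradients.

    When ``p_target`` is None (pre-training) the self-supervision term and
    the gradient w.r.t. mu are skipped and l_ss is reported as 0.  P is
    treated as a constant (refreshed periodically by the trainer), matching
    the usual deep-embedded-clustering alternation.
    """
    fwd = model_forward(params, x_list, t_list, idx_list, n)
    h = fwd["H"]
    counts = fwd["counts"]

    grads = {
        "enc": [[np.zeros_like(w) for w in ws] for ws in params["enc"]],
        "dec": [[np.zeros_like(w) for w in ws] for ws in params["dec"]],
        "graph": [np.zeros_like(w) for w in params["graph"]],
        "mu": None,
    }
    dh = np.zeros_like(h)

    l_nar = 0.0
    l_gsr = 0.0
    for v, (x, t, idx, a) in enumerate(zip(x_list, t_list, idx_list, a_list)):
        hv = fwd["hv"][v]
        acts = fwd["dec_acts"][v]
        xhat = acts[-1]
        l_nar += float(np.sum((x - xhat) ** 2))

        # attribute decoder chain
        dy = 2.0 * (xhat - x)
        dhv = np.zeros_like(hv)
        for j in range(len(acts) - 1, -1, -1):
            dpre = dy * (1.0 - acts[j] ** 2)
            inp = hv if j == 0 else acts[j - 1]
            if j == 0:
                grads["dec"][v][j] += inp.T @ dpre
                dhv += dpre @ params["dec"][v][j].T
            else:
                grads["dec"][v][j] += (t @ inp).T @ dpre
                dy = t @ dpre @ params["dec"][v][j].T  # T is symmetric

        # bilinear graph decoder
        ahat = fwd["ahat"][v]
        l_gsr += float(np.sum((a - ahat) ** 2))
        wg = params["graph"][v]
        de = alpha * 2.0 * (ahat - a) * (1.0 - ahat**2)
        grads["graph"][v] += hv.T @ de @ hv
        dhv += de @ hv @ wg.T + de.T @ hv @ wg

        if idx is None:
            dh += dhv
        else:
            np.add.at(dh, idx, dhv)

    l_ss = 0.0
    q = None
    if p_target is not None:
        mu = params["mu"]
        sq = np.sum((h[:, None, :] - mu[None, :, :]) ** 2, axis=2)
        q_un = 1.0 / (1.0 + sq)
        s = np.maximum(q_un.sum(axis=1, keepdims=True), _EPS)
        q = q_un / s
        l_ss = self_supervised_loss(p_target, q)
        w = q_un * (p_target - q)
        dh += beta * 2.0 * (w.sum(axis=1, keepdims=True) * h - w @ mu)
        grads["mu"] = beta * (-2.0) * (w.T @ h - w.sum(axis=0)[:, None] * mu)

    # fusion backward, then encoder chains
    dh_scaled = dh / counts[:, None]
    for v, (t, idx) in enumerate(zip(t_list, idx_list)):
        acts = fwd["enc_acts"][v]
        dz = dh_scaled if idx is None else dh_scaled[idx]
        for m in range(len(acts) - 1, 0, -1):
            dpre = dz * (1.0 - acts[m] ** 2)
            grads["enc"][v][m - 1] += (t @ acts[m - 1]).T @ dpre
            if m > 1:
                dz = t @ dpre @ params["enc"][v][m - 1].T

    breakdown = total_loss(l_nar, l_gsr, l_ss, alpha, beta)
    aux = {"H": h, "Q": q, "Xhat": [a[-1] for a in fwd["dec_acts"]], "Ahat": fwd["ahat"]}
    return breakdown, grads, aux
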