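"""Training orchestration: pretrain, spectral initialization, fine-tune.

The schedule is the usual two-phase one for self-supervised graph
autoencoders:

1. **Pre-train** the encoders/decoders full-batch on the reconstruction
   objective L_nar + alpha * L_gsr.
2. **Initialize clustering**: spectral-cluster the pre-trained consensus
   embedding H, choosing the cluster count C by the eigengap rule; the
   cluster centroids of H seed the centers mu.
3. **Fine-tune** on the full objective L_nar + alpha*L_gsr + beta*KL(P||Q)
   with mu trained by gradient, refreshing the target distribution P every
   few epochs and stopping once the fraction of samples that change their
   (argmax-Q) cluster between refreshes falls below a tolerance.
4. Final labels come from spectral clustering of the final H with the
   frozen C.

Data are small (hundreds of patients), so training is full-batch with a
numpy Adam optimizer (plain SGD available) at the default learning rate
0.001 and trade-off weights alpha = beta = 1.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import graphs, model, spectral
from .model import LossBreakdown
from .synthetic import SyntheticDataset

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Hyperparameters of the full pipeline.

    ``d`` (embedding dimension) and ``hidden`` default to the data-driven
    rules of :func:`default_embedding_dim` and min(256, D_v); ``k_neighbors``
    defaults to the slowly growing rule in :mod:`omicfuse.graphs`.
    """

    learning_rate: float = 1e-3
    alpha: float = 1.0
    beta: float = 1.0
    d: int | None = None
    hidden: int | None = None
    depth: int = 2
    pretrain_epochs: int = 200
    finetune_epochs: int = 100
    p_refresh_interval: int = 5
    convergence_tol: float = 1e-3
    k_neighbors: int | None = None
    c_min: int = 2
    c_max: int = 15
    n_clusters: int | None = None  # override eigengap estimate if set
    index_weighted_eigengap: bool = False
    similarity_t: float | str = "auto"
    kmeans_restarts: int = 20
    optimizer: str = "adam"
    record_assignments: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError(f"learning_rate must be > 0, got {self.learning_rate}")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        for name in ("depth", "p_refresh_interval"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("pretrain_epochs", "finetune_epochs"):
            # zero epochs is a legal baseline: the untrained forward pass
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0 < self.convergence_tol < 1:
            raise ValueError(
                f"convergence_tol must be in (0, 1), got {self.convergence_tol}"
            )
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"optimizer must be 'adam' or 'sgd', got {self.optimizer!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "TrainConfig":
        path = Path(path)
        with open(path) as fh:
            raw = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
        return cls(**(raw or {}))


@dataclass
class FitResult:
    """Output of a fitted run: embedding, labels, and the loss trajectory."""

    H: np.ndarray
    labels: np.ndarray
    n_clusters: int
    loss_history: list[LossBreakdown]
    n_pretrain_epochs: int
    config: TrainConfig
    sample_ids: list[str] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)


def default_embedding_dim(dims: Sequence[int]) -> int:
    """Consensus dimension rule: 0.8x the lowest omics dimension if that is
    below 2000, otherwise 1600."""
    if len(dims) == 0:
        raise ValueError("dims must be nonempty")
    lo = min(dims)
    return int(round(0.8 * lo)) if lo < 2000 else 1600


def zscore(x: np.ndarray) -> np.ndarray:
    """Per-feature z-scoring; zero-variance features are dropped (warned)."""
    x = np.asarray(x, dtype=float)
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance feature(s) before z-scoring",
            stacklevel=2,
        )
        x, mean, sd = x[:, keep], mean[keep], sd[keep]
        if x.shape[1] == 0:
            raise ValueError("all features have zero variance")
    return (x - mean) / sd


class _Optimizer:
    """Adam (default) or plain SGD over a flat list of parameter arrays."""

    def __init__(self, lr: float, kind: str = "adam"):
        self.lr = lr
        self.kind = kind
        self.t = 0
        self._m: list[np.ndarray] | None = None
        self._v: list[np.ndarray] | None = None

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if self.kind == "sgd":
            for p, g in zip(params, grads):
                p -= self.lr * g
            return
        if self._m is None:
            self._m = [np.zeros_like(p) for p in params]
            self._v = [np.zeros_like(p) for p in params]
        b1, b2, eps = 0.9, 0.999, 1e-8
        self.t += 1
        for p, g, m, v in zip(params, grads, self._m, self._v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


def _flat_params(params: dict) -> list[np.ndarray]:
    out: list[np.ndarray] = []
    for ws in params["enc"]:
        out.extend(ws)
    for ws in params["dec"]:
        out.extend(ws)
    out.extend(params["graph"])
    if params["mu"] is not None:
        out.append(params["mu"])
    return out


def _flat_grads(grads: dict, with_mu: bool) -> list[np.ndarray]:
    out: list[np.ndarray] = []
    for ws in grads["enc"]:
        out.extend(ws)
    for ws in grads["dec"]:
        out.extend(ws)
    out.extend(grads["graph"])
    if with_mu:
        out.append(grads["mu"])
    return out


@dataclass
class _Prepared:
    """Normalized matrices, graphs, operators and indicator indices."""

    x_list: list[np.ndarray]
    a_list: list[np.ndarray]
    t_list: list[np.ndarray]
    idx_list: list[np.ndarray | None]
    n: int
    dims: list[int]


def prepare(dataset, config: TrainConfig, use_indicators: bool = True) -> _Prepared:
    """Z-score each omics, build its kNN graph/operator, and map its rows
    into the intact sample universe."""
    n = len(dataset.intact_ids)
    x_list, a_list, t_list, idx_list, dims = [], [], [], [], []
    for v in range(len(dataset.omics)):
        x = zscore(dataset.omics[v])
        k = config.k_neighbors or graphs.default_k(x.shape[0])
        k = max(1, min(k, x.shape[0] - 1))
        g = graphs.build_knn_graph(x, k)
        x_list.append(x)
        a_list.append(g.adj.astype(float))
        t_list.append(graphs.normalize_adjacency(g).op)
        dims.append(x.shape[1])
        if use_indicators:
            ind = graphs.build_indicator_matrix(dataset.sample_ids[v], dataset.intact_ids)
            idx_list.append(ind.indices)
        else:
            if list(dataset.sample_ids[v]) != list(dataset.intact_ids):
                raise ValueError(
                    "use_indicators=False requires every omics to cover the "
                    "intact cohort in order"
                )
            idx_list.append(None)
    return _Prepared(
        x_list=x_list, a_list=a_list, t_list=t_list, idx_list=idx_list, n=n, dims=dims
    )


def pretrain(
    dataset, config: TrainConfig, prepared: _Prepared | None = None
) -> tuple[dict, np.ndarray, list[LossBreakdown]]:
    """Phase 1: train on L_nar + alpha * L_gsr (no self-supervision).

    Returns the trained parameters, the consensus embedding H, and the
    per-epoch loss history.
    """
    prep = prepared if prepared is not None else prepare(dataset, config)
    d = config.d or default_embedding_dim(prep.dims)
    hidden = [config.hidden or min(256, d_v) for d_v in prep.dims]
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    params = model.init_params(prep.dims, hidden, d, rng, depth=config.depth)

    opt = _Optimizer(config.learning_rate, config.optimizer)
    history: list[LossBreakdown] = []
    for epoch in range(config.pretrain_epochs):
        loss, grads, aux = model.loss_and_grads(
            params, prep.x_list, prep.t_list, prep.idx_list, prep.a_list,
            prep.n, config.alpha, config.beta, p_target=None,
        )
        if not np.isfinite(loss.total):
            raise FloatingPointError(f"non-finite loss at pretrain epoch {epoch}")
        history.append(loss)
        opt.step(_flat_params(params), _flat_grads(grads, with_mu=False))
        logger.debug("pretrain epoch %d: %s", epoch, loss)
    h = model.model_forward(params, prep.x_list, prep.t_list, prep.idx_list, prep.n)["H"]
    return params, h, history


def _init_centers(
    h: np.ndarray, config: TrainConfig, seed: int
) -> tuple[np.ndarray, np.ndarray, int]:
    """Eigengap C, spectral labels of H, and per-cluster centroid centers.

    Empty clusters at initialization trigger bounded re-seeded retries of
    the k-means discretization before failing.
    """
    k = config.k_neighbors or graphs.default_k(h.shape[0])
    k = max(1, min(k, h.shape[0] - 1))
    sim = spectral.build_similarity(h, k, config.similarity_t)
    lap = spectral.normalized_laplacian(sim)
    lam = np.linalg.eigvalsh(lap)
    if config.n_clusters is not None:
        c = config.n_clusters
    else:
        c_max = min(config.c_max, h.shape[0] - 1)
        c = spectral.estimate_num_clusters(
            lam, config.c_min, c_max, config.index_weighted_eigengap
        )
    for attempt in range(5):
        sol = spectral.spectral_cluster(lap, c, seed + attempt)
        sizes = np.bincount(sol.labels, minlength=c)
        if np.all(sizes > 0):
            mu = np.stack([h[sol.labels == j].mean(axis=0) for j in range(c)])
            return mu, sol.labels, c
    raise RuntimeError(f"could not initialize {c} nonempty clusters after 5 retries")


def finetune(
    params: dict, dataset, config: TrainConfig, prepared: _Prepared | None = None
) -> FitResult:
    """Phase 2: self-supervised refinement on the full objective."""
    prep = prepared if prepared is not None else prepare(dataset, config)
    h = model.model_forward(params, prep.x_list, prep.t_list, prep.idx_list, prep.n)["H"]
    mu, _, c = _init_centers(h, config, config.seed)
    params = dict(params, mu=mu.copy())

    opt = _Optimizer(config.learning_rate, config.optimizer)
    history: list[LossBreakdown] = []
    diagnostics: dict = {"Q_history": [], "P_history": []} if config.record_assignments else {}
    q = model.soft_assignment(h, params["mu"])
    p = model.target_distribution(q)
    prev_labels = np.argmax(q, axis=1)
    for epoch in range(config.finetune_epochs):
        if epoch > 0 and epoch % config.p_refresh_interval == 0:
            labels_now = np.argmax(q, axis=1)
            change = float(np.mean(labels_now != prev_labels))
            logger.debug("finetune epoch %d: label change %.4f", epoch, change)
            if change < config.convergence_tol:
                break
            prev_labels = labels_now
            p = model.target_distribution(q)
        loss, grads, aux = model.loss_and_grads(
            params, prep.x_list, prep.t_list, prep.idx_list, prep.a_list,
            prep.n, config.alpha, config.beta, p_target=p,
        )
        if not np.isfinite(loss.total):
            raise FloatingPointError(f"non-finite loss at fine-tune epoch {epoch}")
        history.append(loss)
        q = aux["Q"]
        if config.record_assignments:
            diagnostics["Q_history"].append(q.copy())
            diagnostics["P_history"].append(p.copy())
        opt.step(_flat_params(params), _flat_grads(grads, with_mu=True))

    h = model.model_forward(params, prep.x_list, prep.t_list, prep.idx_list, prep.n)["H"]
    k = config.k_neighbors or graphs.default_k(h.shape[0])
    k = max(1, min(k, h.shape[0] - 1))
    sim = spectral.build_similarity(h, k, config.similarity_t)
    lap = spectral.normalized_laplacian(sim)
    sol = spectral.spectral_cluster(lap, c, config.seed)
    return FitResult(
        H=h,
        labels=sol.labels,
        n_clusters=c,
        loss_history=history,
        n_pretrain_epochs=0,
        config=config,
        sample_ids=list(dataset.intact_ids),
        diagnostics=diagnostics,
    )


def fit_predict(dataset, config: TrainConfig | None = None, use_indicators: bool = True) -> FitResult:
    """Full pipeline: normalize, build graphs, pretrain, fine-tune, cluster.

    Works unchanged on partial cohorts (omics covering only a subset of the
    intact sample universe); ``use_indicators=False`` is a full-data-only
    path without the indicator machinery, to which the default path reduces
    exactly when every omics is complete.
    """
    config = config or TrainConfig()
    try:
        prep = prepare(dataset, config, use_indicators=use_indicators)
    except Exception as exc:
        raise type(exc)(f"[prepare] {exc}") from exc
    try:
        params, h, pre_hist = pretrain(dataset, config, prepared=prep)
    except Exception as exc:
        raise type(exc)(f"[pretrain] {exc}") from exc
    try:
        result = finetune(params, dataset, config, prepared=prep)
    except Exception as exc:
        raise type(exc)(f"[finetune] {exc}") from exc
    result.loss_history = pre_hist + result.loss_history
    result.n_pretrain_epochs = len(pre_hist)
    return result


def save_checkpoint(params: dict, config: TrainConfig, path: str | Path) -> None:
    """Serialize all weight matrices (and mu, if set) plus a config echo."""
    arrays: dict[str, np.ndarray] = {}
    for v, ws in enumerate(params["enc"]):
        for m, w in enumerate(ws):
            arrays[f"enc_{v}_{m}"] = w
    for v, ws in enumerate(params["dec"]):
        for m, w in enumerate(ws):
            arrays[f"dec_{v}_{m}"] = w
    for v, w in enumerate(params["graph"]):
        arrays[f"graph_{v}"] = w
    if params["mu"] is not None:
        arrays["mu"] = params["mu"]
    arrays["config_json"] = np.array(json.dumps(asdict(config)))
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> tuple[dict, TrainConfig]:
    with np.load(path, allow_pickle=False) as data:
        config = TrainConfig(**json.loads(str(data["config_json"])))
        n_omics = max(int(k.split("_")[1]) for k in data.files if k.startswith("graph_")) + 1
        params: dict = {"enc": [], "dec": [], "graph": [], "mu": None}
        for v in range(n_omics):
            for key in ("enc", "dec"):
                ws = []
                m = 0
                while f"{key}_{v}_{m}" in data:
                    ws.append(data[f"{key}_{v}_{m}"])
                    m += 1
                params[key].append(ws)
            params["graph"].append(data[f"graph_{v}"])
        if "mu" in data:
            params["mu"] = data["mu"]
    return params, config
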