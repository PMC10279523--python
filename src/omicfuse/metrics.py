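"""Clustering-quality metrics for validating subtype assignments."""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.metrics import (
    adjusted_rand_score,
    normalized_mutual_info_score,
    silhouette_score,
)

from .model import ConsensusEmbedding, _as_h


def evaluate_clustering(
    labels: np.ndarray,
    truth: np.ndarray | None = None,
    h: np.ndarray | ConsensusEmbedding | None = None,
) -> dict:
    """Silhouette on the embedding (always, when given) plus ARI/NMI vs truth.

    A single-cluster labeling has no defined silhouette; it is reported as
    None with a warning rather than an error, since degenerate runs are
    themselves diagnostic.
    """
    labels = np.asarray(labels, dtype=int)
    report: dict = {"n_clusters": int(len(np.unique(labels)))}
    if h is not None:
        hm = _as_h(h)
        if len(np.unique(labels)) < 2:
            warnings.warn("silhouette undefined for a single cluster", stacklevel=2)
            report["silhouette"] = None
        else:
            report["silhouette"] = float(silhouette_score(hm, labels))
    if truth is not None:
        truth = np.asarray(truth, dtype=int)
        if truth.shape != labels.shape:
            raise ValueError(
                f"labels and truth differ in length: {labels.shape} vs {truth.shape}"
            )
        report["ari"] = float(adjusted_rand_score(truth, labels))
        report["nmi"] = float(normalized_mutual_info_score(truth, labels))
    return report
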