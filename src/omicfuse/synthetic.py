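"""Synthetic multi-omics cohorts with planted subtype structure.

Real multi-omics subtyping studies integrate V expression matrices (e.g. DNA
methylation, mRNA, miRNA) measured on an overlapping patient set.  This module
generates the analogous synthetic inputs: V matrices that share one latent
C-cluster partition of N patients, with per-omics feature dimensions, Gaussian
noise, and an optional "partial cohort" condition in which a fraction theta of
the patients is deleted from a single omics (whole rows removed, mimicking
patients who were never profiled on that platform).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a planted-cluster multi-omics cohort.

    Parameters
    ----------
    n_samples : int
        Number of patients N in the intact cohort.
    n_omics : int
        Number of omics layers V.
    n_clusters : int
        Number of planted subtypes C (labels balanced to within +/-1).
    dims : sequence of int
        Feature count D_v of each omics layer; length must equal ``n_omics``.
    separation : float
        Distance between cluster centroids, in units of ``noise_sd``.
    noise_sd : float
        Standard deviation of the i.i.d. Gaussian noise added per entry.
    seed : int
        Seed for the generator; output is bit-reproducible given the spec.
    """

    n_samples: int
    n_omics: int
    n_clusters: int
    dims: tuple[int, ...]
    separation: float = 8.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        if self.n_clusters < 2:
            raise ValueError(f"n_clusters must be >= 2, got {self.n_clusters}")
        if self.n_samples < self.n_clusters:
            raise ValueError(
                f"n_samples must be >= n_clusters, got n_samples={self.n_samples}"
            )
        if self.n_omics < 1:
            raise ValueError(f"n_omics must be >= 1, got {self.n_omics}")
        if len(self.dims) != self.n_omics:
            raise ValueError(
                f"dims must have n_omics={self.n_omics} entries, got {len(self.dims)}"
            )
        if any(d < 1 for d in self.dims):
            raise ValueError(f"all dims must be >= 1, got {self.dims}")
        if not self.noise_sd > 0:
            raise ValueError(f"noise_sd must be > 0, got {self.noise_sd}")
        if self.separation < 0:
            raise ValueError(f"separation must be >= 0, got {self.separation}")


@dataclass
class SyntheticDataset:
    """A multi-omics cohort with known subtype labels.

    ``omics[v]`` is an (N_v x D_v) matrix whose rows are identified by
    ``sample_ids[v]``; every per-omics ID appears in ``intact_ids`` (length N).
    ``true_labels`` gives the planted subtype of each intact sample.
    """

    omics: list[np.ndarray]
    sample_ids: list[list[str]]
    feature_names: list[list[str]]
    intact_ids: list[str]
    true_labels: np.ndarray
    spec: SyntheticSpec | None = field(default=None, repr=False)

    @property
    def n_omics(self) -> int:
        return len(self.omics)

    @property
    def n_samples(self) -> int:
        return len(self.intact_ids)


def _balanced_labels(n: int, c: int, rng: np.random.Generator) -> np.ndarray:
    # round-robin then shuffle: cluster sizes differ by at most 1
    labels = np.arange(n) % c
    rng.shuffle(labels)
    return labels


def generate_multiomics(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw a full multi-omics cohort with a shared planted partition.

    Each omics v places its C cluster centroids ``separation * noise_sd``
    apart along mutually orthogonal random directions in R^{D_v}, then adds
    i.i.d. Gaussian noise of SD ``noise_sd``.  All omics index the centroids
    by the SAME label vector, so the layers carry consensus cluster
    information, while their feature spaces are independent.
    """
    rng = np.random.default_rng(spec.seed)
    n, c = spec.n_samples, spec.n_clusters
    labels = _balanced_labels(n, c, rng)
    intact_ids = [f"s{i:04d}" for i in range(n)]

    omics: list[np.ndarray] = []
    feature_names: list[list[str]] = []
    for v, d_v in enumerate(spec.dims):
        # orthonormal directions via QR of a Gaussian matrix (d_v x c);
        # if d_v < c some centroids coincide in direction, which is the
        # best that dimension allows.
        raw = rng.standard_normal((d_v, max(c, 1)))
        q, _ = np.linalg.qr(raw)
        directions = q[:, np.arange(c) % q.shape[1]].T  # (c, d_v)
        centroids = directions * (spec.separation * spec.noise_sd)
        x = centroids[labels] + rng.standard_normal((n, d_v)) * spec.noise_sd
        omics.append(x)
        feature_names.append([f"om{v}_f{j}" for j in range(d_v)])

    return SyntheticDataset(
        omics=omics,
        sample_ids=[list(intact_ids) for _ in range(spec.n_omics)],
        feature_names=feature_names,
        intact_ids=list(intact_ids),
        true_labels=labels,
        spec=spec,
    )


def apply_missingness(
    ds: SyntheticDataset, omics_index: int, theta: float, seed: int
) -> SyntheticDataset:
    """Delete a random fraction theta of the rows of one omics layer.

    Emulates the partial-cohort protocol in which a fraction of patients
    has one omics removed entirely.  Exactly ``round(theta * N_v)`` rows
    (and their IDs) are dropped from omics ``omics_index``; the other omics
    and the intact sample universe are unchanged.
    """
    if not 0 <= theta < 1:
        raise ValueError(f"theta must be in [0, 1), got {theta}")
    if not 0 <= omics_index < ds.n_omics:
        raise ValueError(
            f"omics_index must be in [0, {ds.n_omics}), got {omics_index}"
        )
    n_v = ds.omics[omics_index].shape[0]
    n_drop = int(round(theta * n_v))
    if n_drop >= n_v:
        raise ValueError(
            f"removing {n_drop} of {n_v} rows would empty omics {omics_index}"
        )
    rng = np.random.default_rng(seed)
    drop = rng.choice(n_v, size=n_drop, replace=False)
    keep = np.setdiff1d(np.arange(n_v), drop)

    omics = [x.copy() for x in ds.omics]
    sample_ids = [list(ids) for ids in ds.sample_ids]
    omics[omics_index] = omics[omics_index][keep]
    sample_ids[omics_index] = [sample_ids[omics_index][i] for i in keep]
    return dataclasses.replace(
        ds,
        omics=omics,
        sample_ids=sample_ids,
        feature_names=[list(f) for f in ds.feature_names],
        intact_ids=list(ds.intact_ids),
        true_labels=ds.true_labels.copy(),
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write each omics as TSV (sample IDs first column) plus a labels TSV.

    Returns a dict with keys ``omics`` (list of paths) and ``labels``.
    Values use 12 significant digits so a reload round-trips within 1e-9
    absolute for the magnitudes these cohorts produce.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    for v, x in enumerate(ds.omics):
        df = pd.DataFrame(x, index=ds.sample_ids[v], columns=ds.feature_names[v])
        df.index.name = "sample_id"
        p = outdir / f"omics_{v}.tsv"
        df.to_csv(p, sep="\t", float_format="%.12g")
        paths.append(p)
    labels = pd.DataFrame(
        {"sample_id": ds.intact_ids, "label": ds.true_labels.astype(int)}
    )
    labels_path = outdir / "true_labels.tsv"
    labels.to_csv(labels_path, sep="\t", index=False)
    return {"omics": paths, "labels": labels_path}
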