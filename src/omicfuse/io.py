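"""Loading and writing delimited multi-omics matrices with ID alignment."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class MultiOmicsDataset:
    """V expression matrices aligned by sample ID to an intact universe.

    ``intact_ids`` is the union of all per-omics sample IDs in first-seen
    order; each omics keeps its own row order and may cover only a subset.
    """

    omics: list[np.ndarray]
    sample_ids: list[list[str]]
    feature_names: list[list[str]]
    intact_ids: list[str]
    true_labels: np.ndarray | None = None

    @property
    def n_omics(self) -> int:
        return len(self.omics)


def _delimiter(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _read_matrix(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_delimiter(path), index_col=0, dtype=str)
    ids = df.index.astype(str)
    dup = ids[ids.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate sample ID {dup[0]!r}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = next(
                i for i, cell in enumerate(df[col])
                if pd.to_numeric(pd.Series([cell]), errors="coerce").isna()[0]
            )
            raise ValueError(
                f"{path}: non-numeric value {df[col].iloc[bad]!r} at "
                f"sample {ids[bad]!r}, column {col!r}"
            ) from exc
    if not np.isfinite(values).all():
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"{path}: non-finite value at sample {ids[i]!r}, column {df.columns[j]!r}"
        )
    out = pd.DataFrame(values, index=list(ids), columns=list(df.columns))
    return out


def load_multiomics(paths: Sequence[str | Path]) -> MultiOmicsDataset:
    """Read V delimited matrices (sample-ID first column, feature header).

    The intact sample universe is the union of all per-omics IDs in
    first-seen order, so full and partial cohorts load through the same
    code path.
    """
    if not paths:
        raise ValueError("need at least one omics file")
    frames = [_read_matrix(Path(p)) for p in paths]
    intact: list[str] = []
    seen: set[str] = set()
    for df in frames:
        for sid in df.index:
            if sid not in seen:
                seen.add(sid)
                intact.append(sid)
    return MultiOmicsDataset(
        omics=[df.to_numpy() for df in frames],
        sample_ids=[list(df.index) for df in frames],
        feature_names=[list(df.columns) for df in frames],
        intact_ids=intact,
    )


def write_embedding(h: np.ndarray, sample_ids: Sequence[str], path: str | Path) -> None:
    df = pd.DataFrame(h, index=list(sample_ids),
                      columns=[f"dim{j}" for j in range(h.shape[1])])
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.12g")


def write_labels(labels: np.ndarray, sample_ids: Sequence[str], path: str | Path) -> None:
    pd.DataFrame({"sample_id": list(sample_ids), "cluster": np.asarray(labels, int)}).to_csv(
        path, sep="\t", index=False
    )


def read_labels(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep=_delimiter(Path(path)))
    ids = df.iloc[:, 0].astype(str).tolist()
    return ids, df.iloc[:, 1].to_numpy(dtype=int)


def read_embedding(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep=_delimiter(Path(path)), index_col=0)
    return [str(i) for i in df.index], df.to_numpy(dtype=float)
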