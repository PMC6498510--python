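"""Readers and writers for the plain-text formats the tools exchange.

Distance matrices and coordinate tables travel as delimited text with a
header row and a first column of labels; the delimiter is inferred from the
extension (``.csv`` comma, anything else tab).  Count matrices are accepted
as dense TSV (features as rows) or MatrixMarket ``.mtx`` with sidecar
feature/sample id files, one id per line.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

from .core import CountMatrix, DistanceMatrix, Embedding2D, GroupAssignment, validate_distance_matrix

__all__ = [
    "read_distance_matrix", "write_distance_matrix",
    "read_embedding", "write_embedding",
    "read_counts_tsv", "write_counts_tsv",
    "read_counts_mtx", "write_counts_mtx",
    "read_groups", "write_groups",
]


def _sep(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_distance_matrix(path, check_triangle: bool = False) -> DistanceMatrix:
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    return validate_distance_matrix(
        df.to_numpy(dtype=float), [str(x) for x in df.index], check_triangle=check_triangle
    )


def write_distance_matrix(dist: DistanceMatrix, path) -> None:
    dist.to_frame().to_csv(path, sep=_sep(path))


def read_embedding(path) -> Embedding2D:
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    cols = [c for c in df.columns if c.lower() in ("x", "y")]
    coords = df[cols].to_numpy(dtype=float) if len(cols) == 2 else df.iloc[:, :2].to_numpy(dtype=float)
    return Embedding2D(labels=tuple(str(x) for x in df.index), coords=coords)


def write_embedding(emb: Embedding2D, path, extra: pd.DataFrame | None = None) -> None:
    df = emb.to_frame()
    if extra is not None:
        df = df.join(extra)
    df.to_csv(path, sep=_sep(path), index_label="label")


def read_counts_tsv(path) -> CountMatrix:
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    return CountMatrix(
        feature_ids=tuple(str(x) for x in df.index),
        sample_ids=tuple(str(c) for c in df.columns),
        counts=df.to_numpy(dtype=float),
    )


def write_counts_tsv(counts: CountMatrix, path) -> None:
    counts.to_frame().to_csv(path, sep=_sep(path))


def _read_ids(path) -> tuple[str, ...]:
    return tuple(line.strip() for line in Path(path).read_text().splitlines() if line.strip())


def read_counts_mtx(path, features_path, samples_path) -> CountMatrix:
    m = mmread(path)
    x = np.asarray(m.todense() if hasattr(m, "todense") else m, dtype=float)
    return CountMatrix(
        feature_ids=_read_ids(features_path), sample_ids=_read_ids(samples_path), counts=x
    )


def write_counts_mtx(counts: CountMatrix, path, features_path, samples_path) -> None:
    mmwrite(str(path), coo_matrix(counts.counts))
    Path(features_path).write_text("\n".join(counts.feature_ids) + "\n")
    Path(samples_path).write_text("\n".join(counts.sample_ids) + "\n")


def read_groups(path) -> GroupAssignment:
    df = pd.read_csv(path, sep=_sep(path))
    if df.shape[1] < 2:
        raise ValueError("group table needs two columns: label, group")
    return GroupAssignment(
        labels=tuple(str(x) for x in df.iloc[:, 0]),
        groups=tuple(str(x) for x in df.iloc[:, 1]),
    )


def write_groups(groups: GroupAssignment, path) -> None:
    pd.DataFrame({"label": groups.labels, "group": groups.groups}).to_csv(
        path, sep=_sep(path), index=False
    )
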