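"""Embedding-fidelity diagnostics: raw stress, Shepard pairs, per-point distortion.

All diagnostics relate a 2-D embedding ``D_ij`` (planar Euclidean distances of
the plotted coordinates) back to the feature-space dissimilarities ``d_ij``.
The headline quantity is the raw squared-residual stress

    stress = sum_{i<j} (D_ij - d_ij)^2

summed over unordered pairs.  A normalised variant (Kruskal-style stress-1,
``sqrt(sum (D-d)^2 / sum D^2)``) is provided for comparability across
datasets whose distances live on different scales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes

from .core import DistanceMatrix, Embedding2D, ValidationError

__all__ = [
    "ShepardData",
    "total_stress",
    "normalized_stress",
    "shepard",
    "per_point_distortion",
    "procrustes_residual",
]


@dataclass(frozen=True)
class ShepardData:
    """All unordered point pairs with feature-space and embedded distances.

    Sorted by ``d`` ascending (ties by label pair) for stable output; a
    perfect embedding puts every pair on the identity line ``D = d``.
    """

    labels_i: tuple[str, ...]
    labels_j: tuple[str, ...]
    d: np.ndarray
    D: np.ndarray

    def __len__(self) -> int:
        return len(self.d)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"i": self.labels_i, "j": self.labels_j, "d": self.d, "D": self.D}
        )


def _aligned(dist: DistanceMatrix, emb: Embedding2D) -> tuple[np.ndarray, np.ndarray]:
    """Feature-space and embedded distance matrices in a common label order."""
    if set(dist.labels) != set(emb.labels):
        missing = sorted(set(dist.labels) ^ set(emb.labels))
        raise ValidationError(f"label mismatch between distances and embedding: {missing}")
    perm = [emb.index(lab) for lab in dist.labels]
    coords = emb.coords[perm]
    diff = coords[:, None, :] - coords[None, :, :]
    D = np.sqrt((diff**2).sum(axis=-1))
    return dist.values, D


def total_stress(dist: DistanceMatrix, emb: Embedding2D) -> float:
    """Raw stress ``sum_{i<j} (D_ij - d_ij)^2`` over unordered pairs."""
    d, D = _aligned(dist, emb)
    iu = np.triu_indices(len(d), k=1)
    return float(((D[iu] - d[iu]) ** 2).sum())


def normalized_stress(dist: DistanceMatrix, emb: Embedding2D) -> float:
    """Kruskal-style stress-1 of an embedding: ``sqrt(sum (D-d)^2 / sum D^2)``."""
    d, D = _aligned(dist, emb)
    iu = np.triu_indices(len(d), k=1)
    denom = (D[iu] ** 2).sum()
    if denom == 0:
        return 0.0 if np.allclose(d[iu], 0) else float("inf")
    return float(np.sqrt(((D[iu] - d[iu]) ** 2).sum() / denom))


def shepard(dist: DistanceMatrix, emb: Embedding2D) -> ShepardData:
    """Shepard-plot data: every unordered pair with both distances."""
    d, D = _aligned(dist, emb)
    n = len(d)
    iu, ju = np.triu_indices(n, k=1)
    order = sorted(range(len(iu)), key=lambda k: (d[iu[k], ju[k]], dist.labels[iu[k]], dist.labels[ju[k]]))
    iu, ju = iu[order], ju[order]
    return ShepardData(
        labels_i=tuple(dist.labels[i] for i in iu),
        labels_j=tuple(dist.labels[j] for j in ju),
        d=d[iu, ju].copy(),
        D=D[iu, ju].copy(),
    )


def per_point_distortion(dist: DistanceMatrix, emb: Embedding2D) -> pd.Series:
    """Per-point stress ``sum_{j != i} (D_ij - d_ij)^2``.

    Each unordered pair contributes to both of its endpoints, so the values
    sum to twice :func:`total_stress`.  Useful for spotting the individual
    points a plot most misrepresents.
    """
    d, D = _aligned(dist, emb)
    res = (D - d) ** 2
    np.fill_diagonal(res, 0.0)
    return pd.Series(res.sum(axis=1), index=list(dist.labels), name="distortion")


def procrustes_residual(
    reference: np.ndarray, test: np.ndarray, allow_scaling: bool = False
) -> float:
    """Relative misfit of one configuration onto another after alignment.

    Centres both point sets, finds the optimal rotation/reflection (and a
    uniform scale when ``allow_scaling``), and returns
    ``||aligned - reference||_F / ||reference||_F``.  Zero means the
    configurations agree up to the allowed rigid motions.
    """
    a = np.asarray(reference, dtype=float)
    b = np.asarray(test, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    na = np.linalg.norm(a)
    if na == 0:
        return float(np.linalg.norm(b))
    R, scale = orthogonal_procrustes(b, a)
    aligned = b @ R
    if allow_scaling:
        nb2 = (b**2).sum()
        aligned = aligned * (scale / nb2 if nb2 > 0 else 1.0)
    return float(np.linalg.norm(aligned - a) / na)
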