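"""Domain containers and the distance functions the rest of the package builds on.

The central object is :class:`DistanceMatrix`: a symmetric, nonnegative matrix
``d_ij`` with zero diagonal and one label per point.  Any such matrix is a valid
input to the embedding and diagnostic routines — it does not need to come from a
metric, although the optional triangle-inequality check is available for inputs
that should be metric by construction.

Three distance constructors cover the preprocessing recipes used downstream:
Manhattan distances between sample profiles (drug-sensitivity vectors),
Euclidean distances (e.g. between principal-component scores), and the
``1 - Spearman`` correlation dissimilarity between samples.  Note the Spearman
dissimilarity is not guaranteed to satisfy the triangle inequality; it is a
legitimate input regardless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

__all__ = [
    "ValidationError",
    "DistanceMatrix",
    "Embedding2D",
    "CountMatrix",
    "GroupAssignment",
    "validate_distance_matrix",
    "manhattan_distances",
    "euclidean_distances",
    "spearman_distance",
]

#: absolute tolerance below which small asymmetries are repaired by averaging
SYMMETRY_ATOL = 1e-9


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


def _check_labels(labels: Sequence[str], n: int) -> tuple[str, ...]:
    labels = tuple(str(x) for x in labels)
    if len(labels) != n:
        raise ValidationError(f"{len(labels)} labels for {n} points")
    if len(set(labels)) != len(labels):
        dup = sorted({x for x in labels if labels.count(x) > 1})
        raise ValidationError(f"duplicate labels: {dup}")
    return labels


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative dissimilarities ``d_ij`` with labelled points.

    Construct via :func:`validate_distance_matrix` rather than directly, so
    the invariants (symmetry, zero diagonal, nonnegativity) are enforced.
    """

    labels: tuple[str, ...]
    values: np.ndarray

    @property
    def n(self) -> int:
        return len(self.labels)

    def __len__(self) -> int:
        return self.n

    def index(self, label: str) -> int:
        try:
            return self.labels.index(str(label))
        except ValueError:
            raise KeyError(f"unknown point label: {label!r}") from None

    def row(self, label: str) -> np.ndarray:
        """Distances from one point to all points, in label order."""
        return self.values[self.index(label)]

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy's condensed (pdist) order."""
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))


@dataclass(frozen=True)
class Embedding2D:
    """Labelled 2-D coordinates produced by any embedding method."""

    labels: tuple[str, ...]
    coords: np.ndarray

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValidationError(f"coords must be n x 2, got shape {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise ValidationError("coords contain non-finite values")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "labels", _check_labels(self.labels, coords.shape[0]))

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(str(label))
        except ValueError:
            raise KeyError(f"unknown point label: {label!r}") from None

    def pairwise_distances(self) -> np.ndarray:
        """Euclidean distances ``D_ij`` realised by the plotted coordinates."""
        return squareform(pdist(self.coords))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.coords, index=list(self.labels), columns=["x", "y"])


@dataclass(frozen=True)
class CountMatrix:
    """Nonnegative feature-by-sample matrix (genes x cells, drugs x samples)."""

    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if not np.all(np.isfinite(counts)):
            raise ValidationError("counts contain non-finite values")
        if np.any(counts < 0):
            raise ValidationError("counts contain negative values")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "feature_ids", _check_labels(self.feature_ids, counts.shape[0]))
        object.__setattr__(self, "sample_ids", _check_labels(self.sample_ids, counts.shape[1]))

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.feature_ids), columns=list(self.sample_ids))


@dataclass(frozen=True)
class GroupAssignment:
    """Categorical group per point, e.g. patient strata or cell types."""

    labels: tuple[str, ...]
    groups: tuple[str, ...]

    def __post_init__(self):
        labels = _check_labels(self.labels, len(self.labels))
        groups = tuple(str(g) for g in self.groups)
        if len(groups) != len(labels):
            raise ValidationError("one group per label required")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "groups", groups)

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.labels, self.groups))

    def group_of(self, label: str) -> str:
        return self.as_dict()[str(label)]


# ---------------------------------------------------------------------------
# validation

def validate_distance_matrix(
    values: np.ndarray,
    labels: Sequence[str] | None = None,
    check_triangle: bool = False,
    atol: float = SYMMETRY_ATOL,
) -> DistanceMatrix:
    """Validate (and lightly repair) a square dissimilarity matrix.

    Asymmetries up to ``atol`` (absolute) are symmetrised by averaging — CSV
    round-trips routinely introduce residue at that scale — while anything
    larger is rejected with the first offending pair named.  The diagonal must
    be zero and all entries nonnegative.  ``check_triangle`` additionally
    verifies ``d_ik <= d_ij + d_jk`` for all triples; this is O(n^3) and meant
    for small inputs (correlation-based dissimilarities may legitimately fail
    it and should not be checked).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValidationError(f"matrix must be square, got shape {values.shape}")
    n = values.shape[0]
    if labels is None:
        labels = [f"p{i}" for i in range(n)]
    labels = _check_labels(labels, n)

    if not np.all(np.isfinite(values)):
        raise ValidationError("matrix contains non-finite values")
    asym = np.abs(values - values.T)
    if np.any(asym > atol):
        i, j = np.unravel_index(int(np.argmax(asym)), asym.shape)
        raise ValidationError(
            f"matrix is asymmetric at ({labels[i]}, {labels[j]}): "
            f"{values[i, j]!r} vs {values[j, i]!r}"
        )
    values = 0.5 * (values + values.T)
    diag = np.diag(values)
    if np.any(diag != 0):
        i = int(np.nonzero(diag)[0][0])
        raise ValidationError(f"nonzero diagonal at {labels[i]}: {diag[i]!r}")
    if np.any(values < 0):
        i, j = np.unravel_index(int(np.argmin(values)), values.shape)
        raise ValidationError(f"negative distance at ({labels[i]}, {labels[j]}): {values[i, j]!r}")

    if check_triangle:
        tol = 1e-9
        for k in range(n):
            # d_ij <= d_ik + d_kj for all i, j
            slack = values - (values[:, k][:, None] + values[k][None, :])
            if np.any(slack > tol):
                i, j = np.unravel_index(int(np.argmax(slack)), slack.shape)
                raise ValidationError(
                    f"triangle inequality violated on ({labels[i]}, {labels[j]}, {labels[k]}): "
                    f"d={values[i, j]:g} > {values[i, k]:g} + {values[k, j]:g}"
                )
    return DistanceMatrix(labels=labels, values=values)


# ---------------------------------------------------------------------------
# distance constructors

def _as_feature_array(features) -> tuple[np.ndarray, tuple[str, ...]]:
    """Coerce input to (features x samples array, sample labels)."""
    if isinstance(features, CountMatrix):
        return features.counts, features.sample_ids
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=float), tuple(str(c) for c in features.columns)
    x = np.asarray(features, dtype=float)
    if x.ndim != 2:
        raise ValidationError("feature matrix must be 2-D (features x samples)")
    return x, tuple(f"s{i}" for i in range(x.shape[1]))


def _finish(dist: np.ndarray, labels: Sequence[str]) -> DistanceMatrix:
    dist = 0.5 * (dist + dist.T)
    np.fill_diagonal(dist, 0.0)  # suppress floating-point residue
    return validate_distance_matrix(dist, labels)


def manhattan_distances(features) -> DistanceMatrix:
    """Pairwise L1 distances between samples (columns).

    This is the drug-sensitivity recipe: each sample is a vector of scores
    (one per drug) and ``d_ij = sum_f |x_fi - x_fj|``.
    """
    x, labels = _as_feature_array(features)
    if x.shape[1] < 2:
        raise ValidationError("need at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValidationError("feature matrix contains non-finite values")
    return _finish(squareform(pdist(x.T, metric="cityblock")), labels)


def euclidean_distances(features, by_columns: bool = True) -> DistanceMatrix:
    """Pairwise L2 distances over the designated axis (columns by default)."""
    if isinstance(features, (CountMatrix, pd.DataFrame)) or by_columns:
        x, labels = _as_feature_array(features)
        pts = x.T
    else:
        x = np.asarray(features, dtype=float)
        pts = x
        labels = tuple(f"s{i}" for i in range(x.shape[0]))
    if pts.shape[0] < 2:
        raise ValidationError("need at least 2 points")
    if not np.all(np.isfinite(pts)):
        raise ValidationError("feature matrix contains non-finite values")
    return _finish(squareform(pdist(pts, metric="euclidean")), labels)


def spearman_distance(features) -> DistanceMatrix:
    """``1 - Spearman`` rank-correlation dissimilarity between samples.

    Ranks use the average-rank convention for ties.  A sample whose profile is
    constant has undefined rank correlation and is rejected with its label.
    The result is a dissimilarity, not a metric: values lie in [0, 2] and the
    triangle inequality is not guaranteed.
    """
    x, labels = _as_feature_array(features)
    if x.shape[0] < 2:
        raise ValidationError("need at least 2 features (observations) per sample")
    if not np.all(np.isfinite(x)):
        raise ValidationError("feature matrix contains non-finite values")
    ranks = rankdata(x, axis=0)  # average ranks down each column
    sd = ranks.std(axis=0)
    if np.any(sd == 0):
        bad = int(np.nonzero(sd == 0)[0][0])
        raise ValidationError(
            f"sample {labels[bad]!r} has a constant profile; Spearman correlation undefined"
        )
    rho = np.corrcoef(ranks, rowvar=False)
    return _finish(1.0 - rho, labels)
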