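"""Kruskal-style nonmetric MDS baseline, with classical (Torgerson) scaling.

This is the conventional all-pairs embedding the focused method is compared
against, and the default layout for distance-net plots when no coordinates
are supplied.  Nonmetric MDS minimises Kruskal's stress-1

    stress1 = sqrt( sum (D_ij - dhat_ij)^2 / sum D_ij^2 )

where the disparities ``dhat`` are a monotone (isotonic) regression of the
embedded distances onto the rank order of the input dissimilarities: only the
ordering of ``d`` matters, not its scale.  The solver alternates isotonic
fits (pool-adjacent-violators) with Guttman-transform coordinate updates and
backtracks on any step that would increase stress-1, so the reported stress
sequence is non-increasing by construction.  A metric variant (disparities
equal to the raw distances) is available via ``metric=True``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from .core import DistanceMatrix, Embedding2D, ValidationError

__all__ = ["MDSResult", "classical_scaling", "kruskal_mds"]


@dataclass(frozen=True)
class MDSResult:
    embedding: Embedding2D
    stress1: float
    iterations: int
    converged: bool
    stress_history: tuple[float, ...] = ()


def classical_scaling(dist: DistanceMatrix, k: int = 2) -> np.ndarray:
    """Torgerson classical scaling: eigendecomposition of the centred Gram matrix.

    Double-centres the squared distances, ``B = -1/2 J D^2 J``, and returns the
    top-``k`` eigenvector coordinates scaled by the root eigenvalues.  Exact
    for distances that genuinely come from a ``k``-dimensional configuration.
    Sign convention: in each dimension the largest-magnitude loading is made
    positive.  If fewer than ``k`` positive eigenvalues exist the remaining
    dimensions are zero-padded with a warning.
    """
    n = dist.n
    if n < k + 1:
        raise ValidationError(f"classical scaling in {k}-D needs at least {k + 1} points")
    d2 = dist.values**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    B = 0.5 * (B + B.T)
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:k]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(vals.max(), 0) * 1e-12 if vals.size else np.zeros(0, bool)
    if pos.sum() < k:
        warnings.warn(
            f"only {int(pos.sum())} positive eigenvalues for {k} requested dimensions; "
            "padding with zeros",
            stacklevel=2,
        )
    coords = np.zeros((n, k))
    for m in range(k):
        if pos[m]:
            v = vecs[:, m] * np.sqrt(vals[m])
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            coords[:, m] = v
    return coords


def _stress1_and_disparities(
    d: np.ndarray, D: np.ndarray, iso: IsotonicRegression, metric: bool
) -> tuple[float, np.ndarray]:
    dhat = d if metric else iso.fit(d, D).predict(d)
    denom = (D**2).sum()
    if denom == 0:
        return float("inf"), dhat
    return float(np.sqrt(((D - dhat) ** 2).sum() / denom)), dhat


def _guttman(X: np.ndarray, dhat: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Guttman transform: majorisation step toward the disparities."""
    n = X.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(D > 0, dhat / D, 0.0)
    B = -squareform(ratio)
    np.fill_diagonal(B, -B.sum(axis=1))
    return (B @ X) / n


def kruskal_mds(
    dist: DistanceMatrix,
    init: Embedding2D | np.ndarray | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
    metric: bool = False,
) -> MDSResult:
    """Nonmetric (Kruskal) MDS of a distance matrix into the plane.

    ``init`` defaults to classical scaling, making the whole procedure
    deterministic.  Iteration stops when the stress-1 improvement drops below
    ``tol`` or no descending step can be found (backtracking halves any
    Guttman step that would increase stress-1).
    """
    if dist.n < 3:
        raise ValidationError("nonmetric MDS needs at least 3 points")
    d = dist.condensed()
    if np.all(d == 0):
        raise ValidationError("all distances are zero; configuration is degenerate")

    if init is None:
        X = classical_scaling(dist, k=2)
    elif isinstance(init, Embedding2D):
        perm = [init.index(lab) for lab in dist.labels]
        X = init.coords[perm].astype(float).copy()
    else:
        X = np.asarray(init, dtype=float).copy()
        if X.shape != (dist.n, 2):
            raise ValidationError(f"init must be {dist.n} x 2, got {X.shape}")
    if np.allclose(pdist(X), 0):
        # degenerate start (e.g. all points coincide): tiny deterministic spread
        t = np.linspace(0, 2 * np.pi, dist.n, endpoint=False)
        X = X + 1e-3 * max(d.max(), 1.0) * np.column_stack([np.cos(t), np.sin(t)])

    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    D = pdist(X)
    s, dhat = _stress1_and_disparities(d, D, iso, metric)
    history = [s]
    converged = False
    iterations = 0
    for _ in range(max_iter):
        Xn = _guttman(X, dhat, D)
        Dn = pdist(Xn)
        sn, dhatn = _stress1_and_disparities(d, Dn, iso, metric)
        tries = 0
        while sn > s and tries < 30:
            Xn = 0.5 * (X + Xn)
            Dn = pdist(Xn)
            sn, dhatn = _stress1_and_disparities(d, Dn, iso, metric)
            tries += 1
        if sn > s:  # no descending step exists at this resolution
            converged = True
            break
        iterations += 1
        improvement = s - sn
        X, D, s, dhat = Xn, Dn, sn, dhatn
        history.append(s)
        if improvement < tol:
            converged = True
            break
    emb = Embedding2D(labels=dist.labels, coords=X)
    return MDSResult(
        embedding=emb,
        stress1=float(s),
        iterations=iterations,
        converged=converged,
        stress_history=tuple(history),
    )
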