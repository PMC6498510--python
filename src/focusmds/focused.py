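"""Focused multidimensional scaling: greedy polar placement around a focal point.

Given dissimilarities ``d_ij``, one point is chosen as the *focus* and placed
at the origin.  Every other point ``i`` is placed in polar coordinates
``(r_i, phi_i)`` with the radius fixed *exactly* at ``r_i = d(focus, i)`` — the
defining guarantee of the method: all distances to the focal point are shown
without error.  Only the angle ``phi_i`` is free, and it is chosen greedily,
one point at a time from the focus outward, to minimise the stress against the
points already placed:

    stress_i(phi) = sum_j ( D_ij(phi) - d_ij )^2

where ``D_ij`` is the planar distance between ``(r_i, phi)`` and the placed
``(r_j, phi_j)``, via the law of cosines

    D_ij = sqrt( r_i^2 + r_j^2 - 2 r_i r_j cos(phi - phi_j) ).

Each insertion is a one-dimensional minimisation, solved with a bounded
Brent-type optimiser seeded from a global candidate scan (see
:func:`choose_angle`); the costly simultaneous optimisation over all
coordinates is deliberately avoided, making the method fast enough for
interactive use at ~1000 points.

Refocusing (moving a different point to the centre) is a full re-solve: the
radii guarantee is relative to the focus, so none of the old geometry carries
over.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .core import DistanceMatrix, Embedding2D, ValidationError

__all__ = [
    "PolarPlacement",
    "minimize_univariate",
    "angular_stress",
    "choose_angle",
    "place_focused",
    "refocus",
]

TWO_PI = 2.0 * math.pi

#: number of candidate seeds retained for Brent refinement per insertion
_MAX_REFINE = 16


@dataclass(frozen=True)
class PolarPlacement:
    """Result of a focused embedding.

    ``labels`` lists the non-focal points in the order they were inserted;
    ``radii[k]`` and ``angles[k]`` are the polar coordinates of ``labels[k]``
    relative to the focus at the origin.  ``placement_stress`` is the sum of
    the per-insertion stresses, i.e. the total squared-residual stress over
    all pairs of non-focal points (focal pairs contribute exactly zero).
    """

    focus: str
    labels: tuple[str, ...]
    radii: np.ndarray
    angles: np.ndarray
    placement_stress: float

    @property
    def coords(self) -> np.ndarray:
        """Cartesian n x 2 coordinates; row 0 is the focus at the origin."""
        xy = np.column_stack([self.radii * np.cos(self.angles), self.radii * np.sin(self.angles)])
        return np.vstack([[0.0, 0.0], xy])

    @property
    def all_labels(self) -> tuple[str, ...]:
        return (self.focus,) + self.labels

    def to_embedding(self) -> Embedding2D:
        return Embedding2D(labels=self.all_labels, coords=self.coords)

    def to_records(self) -> list[dict]:
        """One record per point (focus first), for tabular/JSON export."""
        recs = [dict(label=self.focus, x=0.0, y=0.0, radius=0.0, angle=0.0)]
        xy = self.coords[1:]
        for k, lab in enumerate(self.labels):
            recs.append(
                dict(label=lab, x=float(xy[k, 0]), y=float(xy[k, 1]),
                     radius=float(self.radii[k]), angle=float(self.angles[k]))
            )
        return recs


# ---------------------------------------------------------------------------
# univariate minimisation

def minimize_univariate(
    f: Callable[[float], float], lower: float, upper: float, tol: float = 1e-8
) -> tuple[float, float]:
    """Locate a local minimum of ``f`` on ``[lower, upper]`` to within ``tol``.

    Uses the bounded Brent scheme (golden-section search combined with
    successive parabolic interpolation).  Returns ``(argmin, f(argmin))``.
    """
    if not tol > 0:
        raise ValueError(f"tol must be positive, got {tol!r}")
    if not lower < upper:
        raise ValueError(f"need lower < upper, got [{lower!r}, {upper!r}]")

    def wrapped(x: float) -> float:
        y = f(x)
        if not np.isfinite(y):
            raise ValueError(f"objective returned non-finite value {y!r} at x={x!r}")
        return float(y)

    res = minimize_scalar(
        wrapped, bounds=(lower, upper), method="bounded", options={"xatol": 0.5 * tol}
    )
    x = float(res.x)
    fx = wrapped(x)
    # one parabolic polish step: the bounded solver stops at a sqrt(eps)-scale
    # interval; fitting a parabola through symmetric neighbours localises a
    # smooth minimum one or two orders of magnitude tighter
    delta = max(tol, (upper - lower) * 1e-7)
    x1, x2 = x - delta, x + delta
    if x1 > lower and x2 < upper:
        f1, f2 = wrapped(x1), wrapped(x2)
        denom = f1 - 2.0 * fx + f2
        if denom > 0:
            step = 0.5 * delta * (f1 - f2) / denom
            if abs(step) < delta:
                xc = x + step
                fc = wrapped(xc)
                if fc <= fx:
                    x, fx = xc, fc
    return x, fx


# ---------------------------------------------------------------------------
# angular stress

def _stress_profile(
    phis: np.ndarray, radius: float, placed_radii: np.ndarray,
    placed_angles: np.ndarray, targets: np.ndarray,
) -> np.ndarray:
    """Vectorised stress at each candidate angle (law of cosines)."""
    # (m, k) squared planar distances between the candidate and each placed point
    d2 = (
        radius**2
        + placed_radii[None, :] ** 2
        - 2.0 * radius * placed_radii[None, :] * np.cos(phis[:, None] - placed_angles[None, :])
    )
    d = np.sqrt(np.maximum(d2, 0.0))
    return ((d - targets[None, :]) ** 2).sum(axis=1)


def angular_stress(
    candidate_phi: float,
    radius: float,
    placed_radii: Sequence[float],
    placed_angles: Sequence[float],
    targets: Sequence[float],
) -> float:
    """Stress of placing a new point at ``(radius, candidate_phi)``.

    ``placed_radii``/``placed_angles`` are the polar coordinates of the points
    already placed and ``targets`` their feature-space distances ``d_ij`` to
    the new point.  An empty placed set yields stress 0.
    """
    pr = np.asarray(placed_radii, dtype=float)
    pa = np.asarray(placed_angles, dtype=float)
    t = np.asarray(targets, dtype=float)
    if pr.size == 0:
        return 0.0
    if not (np.isfinite(candidate_phi) and np.isfinite(radius)
            and np.all(np.isfinite(pr)) and np.all(np.isfinite(pa)) and np.all(np.isfinite(t))):
        raise ValueError("non-finite input to angular_stress")
    return float(_stress_profile(np.array([candidate_phi], dtype=float), radius, pr, pa, t)[0])


def _intersection_angles(
    radius: float, placed_radii: np.ndarray, placed_angles: np.ndarray, targets: np.ndarray
) -> np.ndarray:
    """Angles where the new point's circle meets each target sphere exactly.

    For each placed point j the equation ``D_ij(phi) = d_ij`` has (when
    feasible) the two solutions ``phi_j +/- arccos(c_j)`` with
    ``c_j = (r_i^2 + r_j^2 - d_ij^2) / (2 r_i r_j)``.  These are the natural
    seeds for the global search: minima of the summed stress sit at or near
    them.  Infeasible constraints clip to the nearest attainable angle
    (``phi_j`` or ``phi_j + pi``).
    """
    ok = (radius > 0) & (placed_radii > 0)
    if not np.any(ok):
        return np.empty(0)
    rj = placed_radii[ok]
    pj = placed_angles[ok]
    dj = targets[ok]
    c = np.clip((radius**2 + rj**2 - dj**2) / (2.0 * radius * rj), -1.0, 1.0)
    a = np.arccos(c)
    return np.concatenate([pj + a, pj - a])


def choose_angle(
    radius: float,
    placed_radii: Sequence[float],
    placed_angles: Sequence[float],
    targets: Sequence[float],
    grid_size: int = 64,
    tol: float = 1e-8,
) -> tuple[float, float]:
    """Pick the angle for a new point by global scan plus Brent refinement.

    Candidates are a uniform grid of ``grid_size`` angles over ``[0, 2*pi)``
    together with the exact circle-circle intersection angles against each
    placed point.  The best few local minima among the candidates are refined
    with :func:`minimize_univariate` on brackets of width ``2*pi/grid_size``
    either side.  Returns ``(phi in [0, 2*pi), stress at phi)``.

    The first point to be placed has an empty stress sum; by convention it
    goes to ``phi = 0`` (the overall rotation of any MDS plot is arbitrary).
    """
    if grid_size < 3:
        raise ValueError("grid_size must be >= 3")
    pr = np.asarray(placed_radii, dtype=float)
    pa = np.asarray(placed_angles, dtype=float)
    t = np.asarray(targets, dtype=float)
    if pr.size == 0:
        return 0.0, 0.0
    if pr.shape != pa.shape or pr.shape != t.shape:
        raise ValueError("placed_radii, placed_angles and targets must have equal length")

    h = TWO_PI / grid_size
    grid = np.arange(grid_size) * h
    extra = _intersection_angles(radius, pr, pa, t) % TWO_PI
    cands = np.concatenate([grid, extra])
    vals = _stress_profile(cands, radius, pr, pa, t)

    # seeds: circular local minima of the uniform grid, plus every analytic angle
    g = vals[:grid_size]
    is_locmin = (g <= np.roll(g, 1)) & (g <= np.roll(g, -1))
    seed_phis = np.concatenate([grid[is_locmin], extra])
    seed_vals = np.concatenate([g[is_locmin], vals[grid_size:]])
    order = np.argsort(seed_vals, kind="stable")[:_MAX_REFINE]

    best_i = int(np.argmin(vals))
    best_phi, best_val = float(cands[best_i]), float(vals[best_i])

    def f(phi: float) -> float:
        return float(_stress_profile(np.array([phi]), radius, pr, pa, t)[0])

    for i in order:
        s = float(seed_phis[i])
        x, v = minimize_univariate(f, s - h, s + h, tol)
        if v < best_val:
            best_phi, best_val = x, v
    return best_phi % TWO_PI, best_val


# ---------------------------------------------------------------------------
# placement

def _insertion_order(dist: DistanceMatrix, focus_idx: int, order: str) -> np.ndarray:
    others = np.array([i for i in range(dist.n) if i != focus_idx])
    if order == "input":
        return others
    if order != "sorted":
        raise ValueError(f"unknown insertion order {order!r}")
    # from the focus outward: increasing focal distance, ties by label order
    d0 = dist.values[focus_idx, others]
    keys = sorted(range(len(others)), key=lambda k: (d0[k], dist.labels[others[k]]))
    return others[np.array(keys)]


def place_focused(
    dist: DistanceMatrix,
    focus: str,
    grid_size: int = 64,
    tol: float = 1e-8,
    order: str = "sorted",
) -> PolarPlacement:
    """Embed all points around ``focus`` with exact focal radii.

    Non-focal points are inserted in order of increasing distance to the focus
    (``order="input"`` preserves the matrix order instead).  Each point gets
    radius ``d(focus, i)`` exactly and the stress-minimising angle against the
    points placed before it.  Deterministic given its arguments.
    """
    if not isinstance(dist, DistanceMatrix):
        raise TypeError("dist must be a DistanceMatrix (use validate_distance_matrix)")
    f_idx = dist.index(focus)  # KeyError for unknown focus
    order_idx = _insertion_order(dist, f_idx, order)
    m = len(order_idx)

    radii = dist.values[f_idx, order_idx].astype(float)
    angles = np.zeros(m)
    total = 0.0
    for k in range(m):
        targets = dist.values[order_idx[k], order_idx[:k]]
        phi, s = choose_angle(radii[k], radii[:k], angles[:k], targets, grid_size, tol)
        angles[k] = phi
        total += s
    return PolarPlacement(
        focus=dist.labels[f_idx],
        labels=tuple(dist.labels[i] for i in order_idx),
        radii=radii,
        angles=angles,
        placement_stress=float(total),
    )


def refocus(
    dist: DistanceMatrix,
    placement: PolarPlacement | None,
    new_focus: str,
    grid_size: int = 64,
    tol: float = 1e-8,
) -> PolarPlacement:
    """Re-embed with a different focal point.

    The exact-radius guarantee is relative to the focus, so the previous
    geometry cannot be reused; this is a full re-solve equivalent to
    ``place_focused(dist, new_focus, ...)``.  The previous placement argument
    is accepted for interface symmetry with interactive use.
    """
    return place_focused(dist, new_focus, grid_size=grid_size, tol=tol)
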