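"""Distance-net overlays: threshold graphs drawn over an existing 2-D layout.

A distnet connects every pair of points whose *feature-space* distance is at
or below a movable threshold ``t``, regardless of where the layout puts them
on the page.  Pairs that sit close on the plot but carry no edge are exactly
the discrepancies a dimension reduction has introduced.  Near the threshold
the edges fade out over a band of width ``s`` (the "softness"): weight 1 for
``d <= t - s``, then a linear ramp ``(t - d)/s`` down to 0 at ``d = t``.

Edges depend only on the distances; the layout affects rendering only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DistanceMatrix, Embedding2D, GroupAssignment, ValidationError

__all__ = ["DistnetGraph", "build_distnet", "scale_bounds", "edge_presence", "render_svg"]

#: weights below 1/255 are invisible at 8-bit opacity; rendering may drop them
MIN_RENDER_WEIGHT = 1.0 / 255.0


@dataclass(frozen=True)
class DistnetGraph:
    """Layout plus the weighted edge list under a soft threshold ``(t, s)``."""

    layout: Embedding2D
    threshold: float
    softness: float
    edges: pd.DataFrame  # columns: i, j, d, weight

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_json(self, groups: GroupAssignment | None = None, bounds=None) -> str:
        payload = {
            "threshold": self.threshold,
            "softness": self.softness,
            "nodes": [
                {"label": lab, "x": float(x), "y": float(y)}
                for lab, (x, y) in zip(self.layout.labels, self.layout.coords)
            ],
            "edges": self.edges.to_dict(orient="records"),
        }
        if groups is not None:
            g = groups.as_dict()
            for node in payload["nodes"]:
                node["group"] = g.get(node["label"])
        if bounds is not None:
            payload["scale_bounds"] = {"min": bounds[0], "max": bounds[1]}
        return json.dumps(payload, indent=1)


def scale_bounds(dist: DistanceMatrix) -> tuple[float, float]:
    """Minimum and maximum off-diagonal pairwise distance (the scale bar)."""
    if dist.n < 2:
        raise ValidationError("scale bounds need at least 2 points")
    off = dist.condensed()
    return float(off.min()), float(off.max())


def edge_presence(dist: DistanceMatrix, i: str, j: str, threshold: float) -> bool:
    """Whether the pair (i, j) is connected at this threshold (``d_ij <= t``)."""
    return bool(dist.values[dist.index(i), dist.index(j)] <= threshold)


def _edge_weight(d: np.ndarray, t: float, s: float) -> np.ndarray:
    if s == 0:
        return np.ones_like(d)
    # an included edge sitting exactly at d == t would ramp to 0; floor it at a
    # tiny positive weight so inclusion (d <= t) always implies weight > 0
    return np.where(d <= t - s, 1.0, np.maximum((t - d) / s, 1e-12))


def build_distnet(
    dist: DistanceMatrix,
    layout: Embedding2D | None = None,
    threshold: float | None = None,
    softness: float | None = None,
) -> DistnetGraph:
    """Construct the threshold graph over a layout.

    ``threshold`` defaults to the midpoint of the distance scale and is
    clipped (with a warning) to ``[min off-diagonal d, max d]``.  ``softness``
    defaults to 10% of the scale width.  Without a layout, coordinates come
    from the nonmetric MDS baseline (:func:`focusmds.baseline.kruskal_mds`).
    """
    if layout is not None and set(layout.labels) != set(dist.labels):
        missing = sorted(set(layout.labels) ^ set(dist.labels))
        raise ValidationError(f"label mismatch between distances and layout: {missing}")
    lo, hi = scale_bounds(dist)
    if threshold is None:
        threshold = 0.5 * (lo + hi)
    if softness is None:
        softness = 0.1 * (hi - lo)
    if softness < 0:
        raise ValidationError(f"softness must be >= 0, got {softness!r}")
    if not lo <= threshold <= hi:
        clipped = float(np.clip(threshold, lo, hi))
        warnings.warn(
            f"threshold {threshold:g} outside distance scale [{lo:g}, {hi:g}]; "
            f"clipped to {clipped:g}",
            stacklevel=2,
        )
        threshold = clipped

    if layout is None:
        from .baseline import kruskal_mds  # deferred: avoids an import cycle

        layout = kruskal_mds(dist).embedding

    iu, ju = np.triu_indices(dist.n, k=1)
    d = dist.values[iu, ju]
    keep = d <= threshold
    iu, ju, d = iu[keep], ju[keep], d[keep]
    w = _edge_weight(d, threshold, softness)
    edges = pd.DataFrame(
        {
            "i": [dist.labels[a] for a in iu],
            "j": [dist.labels[b] for b in ju],
            "d": d,
            "weight": w,
        }
    )
    return DistnetGraph(layout=layout, threshold=float(threshold), softness=float(softness), edges=edges)


def render_svg(
    graph: DistnetGraph,
    path: str,
    groups: GroupAssignment | None = None,
    colors: dict[str, str] | None = None,
    point_size: float = 30.0,
) -> None:
    """Static SVG of the distnet: points plus edges at opacity = weight."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    coords = {lab: xy for lab, xy in zip(graph.layout.labels, graph.layout.coords)}
    for rec in graph.edges.itertuples(index=False):
        if rec.weight < MIN_RENDER_WEIGHT:
            continue
        (x0, y0), (x1, y1) = coords[rec.i], coords[rec.j]
        ax.plot([x0, x1], [y0, y1], color="#1f3b8f", alpha=float(min(rec.weight, 1.0)), lw=0.8, zorder=1)

    if groups is not None:
        gmap = groups.as_dict()
        names = sorted(set(gmap.values()))
        cmap = plt.get_cmap("tab10")
        default = {g: cmap(k % 10) for k, g in enumerate(names)}
        for g in names:
            pts = np.array([coords[lab] for lab in graph.layout.labels if gmap.get(lab) == g])
            c = (colors or {}).get(g, default[g])
            ax.scatter(pts[:, 0], pts[:, 1], s=point_size, color=c, label=g, zorder=2)
        ax.legend(fontsize=8, frameon=False)
    else:
        ax.scatter(graph.layout.coords[:, 0], graph.layout.coords[:, 1], s=point_size,
                   color="#444444", zorder=2)
    ax.set_aspect("equal")
    ax.set_title(f"distnet  t={graph.threshold:g}  s={graph.softness:g}")
    fig.savefig(path, format="svg", bbox_inches="tight")
    plt.close(fig)
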