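"""Seeded synthetic generators for every input class the package consumes.

Three generators emulate the study conditions of the tool's motivating
datasets without shipping any data:

* :func:`planted_2d` — points sampled in the plane with exact (optionally
  noise-perturbed) Euclidean distances.  The ground truth makes zero-stress
  recovery checkable: an exact planar configuration must embed with
  negligible stress and be recovered up to rigid motion.
* :func:`clustered_features` — a drug-response-style score matrix
  (features x samples) with Gaussian clusters of samples, shaped after an
  ex-vivo drug-sensitivity screen (~300 drugs, ~60 patient samples, a few
  response strata).
* :func:`synthetic_counts` — an overdispersed sparse UMI count matrix with
  cell-type expression programs, heterogeneous sequencing depths placed
  deterministically on both sides of the 2500-molecule QC cut, and a block
  of near-silent genes straddling the 25-molecule gene cut, so every QC
  branch is exercised.

All generators are pure functions of their arguments (including the seed).
Corrupt-fixture helpers produce the invalid inputs the validators must
reject.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core import CountMatrix, DistanceMatrix, GroupAssignment, validate_distance_matrix

__all__ = [
    "PlantedConfig",
    "planted_2d",
    "clustered_features",
    "synthetic_counts",
    "corrupt_asymmetric",
    "corrupt_negative",
    "zero_total_cell",
    "constant_gene",
]


@dataclass(frozen=True)
class PlantedConfig:
    """Ground-truth configuration behind a generated distance matrix."""

    true_coords: np.ndarray
    noise_sd: float
    seed: int
    metric: str = "euclidean"


def planted_2d(n: int, seed: int, noise_sd: float = 0.0) -> tuple[PlantedConfig, DistanceMatrix]:
    """Exact planar configuration and its pairwise Euclidean distances.

    With ``noise_sd = 0`` the matrix is metric by construction and exactly
    embeddable in 2-D.  Positive ``noise_sd`` adds symmetric Gaussian
    perturbation to the off-diagonal distances (clipped at 0), producing
    realistic not-quite-planar inputs.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    rng = np.random.default_rng(seed)
    coords = rng.uniform(-10.0, 10.0, size=(n, 2))
    d = squareform(pdist(coords))
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=d.shape)
        noise = 0.5 * (noise + noise.T)
        d = np.clip(d + noise, 0.0, None)
        np.fill_diagonal(d, 0.0)
    dm = validate_distance_matrix(d, [f"p{i}" for i in range(n)])
    return PlantedConfig(true_coords=coords, noise_sd=float(noise_sd), seed=int(seed)), dm


def clustered_features(
    n_samples: int = 58,
    n_features: int = 308,
    n_clusters: int = 4,
    separation: float = 5.0,
    seed: int = 0,
) -> tuple[np.ndarray, GroupAssignment]:
    """Cluster-structured score matrix (features x samples) with true labels.

    Cluster centres are drawn N(0, separation^2) per feature and samples
    scatter N(centre, 1), so ``separation`` is the between/within spread in
    within-cluster standard-deviation units; ``separation = 0`` plants no
    structure.  Defaults mirror a drug screen of ~300 compounds on ~60
    patient samples in four response groups.
    """
    if n_clusters > n_samples:
        raise ValueError("n_clusters must be <= n_samples")
    rng = np.random.default_rng(seed)
    centres = rng.normal(0.0, separation, size=(n_clusters, n_features))
    assign = np.arange(n_samples) % n_clusters  # balanced, deterministic
    x = centres[assign].T + rng.normal(0.0, 1.0, size=(n_features, n_samples))
    groups = GroupAssignment(
        labels=tuple(f"s{i}" for i in range(n_samples)),
        groups=tuple(f"Gr{assign[i] + 1}" for i in range(n_samples)),
    )
    return x, groups


def synthetic_counts(
    n_genes: int = 400,
    n_cells: int = 120,
    n_types: int = 3,
    depth_range: tuple[int, int] = (1200, 9000),
    dropout: float = 0.3,
    seed: int = 0,
    low_depth_fraction: float = 0.25,
    n_silent_genes: int | None = None,
) -> tuple[CountMatrix, GroupAssignment]:
    """Overdispersed UMI-style counts with cell types and planted QC failures.

    Per-cell depths are fixed deterministically: a ``low_depth_fraction`` of
    cells get totals drawn below 2500 (down to ``depth_range[0]``) and the
    rest at or above 2500 (up to ``depth_range[1]``); counts are multinomial
    given the depth, so column totals — and hence which cells a 2500-cut
    removes — are exact.  Gene rates are gamma-perturbed (gamma-Poisson style
    overdispersion) with type-specific marker programs; ``n_silent_genes``
    near-silent genes have expected totals straddling the 25-molecule cut.
    ``dropout`` zeroes that fraction of gene-cell rates before sampling.
    """
    lo, hi = depth_range
    if n_silent_genes is None:
        n_silent_genes = max(4, n_genes // 10)
    if not (0 <= dropout < 1):
        raise ValueError("dropout must be in [0, 1)")
    if lo >= hi or lo < 1:
        raise ValueError("depth_range must satisfy 1 <= lo < hi")
    rng = np.random.default_rng(seed)

    n_low = int(round(low_depth_fraction * n_cells))
    depths = np.concatenate([
        rng.integers(lo, min(2500, hi), size=n_low),
        rng.integers(min(2500, hi), hi + 1, size=n_cells - n_low),
    ])
    perm = rng.permutation(n_cells)
    depths = depths[perm]
    types = (np.arange(n_cells) % n_types)[rng.permutation(n_cells)]

    n_expr = n_genes - n_silent_genes
    if n_expr < 2 * n_types:
        raise ValueError("too few expressed genes for the requested structure")
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_expr)
    mu = np.tile(base[:, None], (1, n_types))
    markers_per_type = min(n_expr, max(2, n_expr // (4 * n_types)))
    for t in range(n_types):
        sel = rng.choice(n_expr, size=markers_per_type, replace=False)
        mu[sel, t] *= rng.uniform(4.0, 10.0, size=markers_per_type)

    # gamma-Poisson style overdispersion, realised through per-cell multinomials
    shape = 2.0
    rates = np.empty((n_genes, n_cells))
    rates[:n_expr] = mu[:, types] * rng.gamma(shape, 1.0 / shape, size=(n_expr, n_cells))
    # near-silent genes: tiny flat rates whose expected totals straddle 25
    silent_expected = np.linspace(5.0, 60.0, n_silent_genes)
    mean_depth = depths.mean()
    silent_rate = silent_expected / n_cells / mean_depth * base.sum()
    rates[n_expr:] = silent_rate[:, None]
    if dropout > 0:
        rates[: n_expr] *= rng.random((n_expr, n_cells)) >= dropout

    counts = np.empty((n_genes, n_cells))
    for c in range(n_cells):
        p = rates[:, c]
        tot = p.sum()
        if tot == 0:
            p = np.ones(n_genes)
            tot = float(n_genes)
        counts[:, c] = rng.multinomial(int(depths[c]), p / tot)

    cm = CountMatrix(
        feature_ids=tuple(f"g{i}" for i in range(n_genes)),
        sample_ids=tuple(f"c{i}" for i in range(n_cells)),
        counts=counts,
    )
    groups = GroupAssignment(
        labels=cm.sample_ids,
        groups=tuple(f"type{t}" for t in types),
    )
    return cm, groups


# ---------------------------------------------------------------------------
# corrupt fixtures: inputs each validator must reject

def corrupt_asymmetric(n: int = 5, seed: int = 0, magnitude: float = 0.5) -> np.ndarray:
    """Square matrix with an asymmetry well beyond the repair tolerance."""
    _, dm = planted_2d(n, seed)
    bad = dm.values.copy()
    bad[0, 1] += magnitude
    return bad


def corrupt_negative(n: int = 5, seed: int = 0) -> np.ndarray:
    """Symmetric matrix with a negative off-diagonal entry."""
    _, dm = planted_2d(n, seed)
    bad = dm.values.copy()
    bad[0, 1] = bad[1, 0] = -1.0
    return bad


def zero_total_cell(n_genes: int = 20, n_cells: int = 6) -> CountMatrix:
    """Count matrix whose last cell has zero total (breaks normalisation)."""
    x = np.ones((n_genes, n_cells))
    x[:, -1] = 0.0
    return CountMatrix(
        feature_ids=tuple(f"g{i}" for i in range(n_genes)),
        sample_ids=tuple(f"c{i}" for i in range(n_cells)),
        counts=x,
    )


def constant_gene(n_genes: int = 10, n_cells: int = 8, seed: int = 0) -> CountMatrix:
    """Count matrix whose first gene is constant (undefined correlation)."""
    rng = np.random.default_rng(seed)
    x = rng.poisson(5.0, size=(n_genes, n_cells)).astype(float)
    x[0] = 3.0
    return CountMatrix(
        feature_ids=tuple(f"g{i}" for i in range(n_genes)),
        sample_ids=tuple(f"c{i}" for i in range(n_cells)),
        counts=x,
    )
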