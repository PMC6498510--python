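"""Distance-preprocessing recipes for count and score matrices.

Three pipelines turn raw feature-by-sample matrices into the distance
matrices the embedding tools consume:

``manhattan_dss``
    Manhattan (L1) distances between sample profiles of drug-sensitivity
    scores.  No filtering — the scores are already summarised per drug.

``correlation``
    Single-cell UMI counts: QC filter (cells with < 2500 total molecules and
    genes with < 25 molecules over all cells are dropped), a correlation-based
    gene filter (genes keeping at least 5 partners above the 90th percentile
    of the gene-gene correlation matrix), per-cell normalisation
    ``log2(count / cell_total * 1e3 + 1)``, selection of the 200 most
    variable genes, then ``1 - Spearman`` distances between cells.

``pca_euclidean``
    Same QC/normalisation, then the first 50 principal components of the
    normalised matrix and Euclidean distances between cells in PC space.

Every stage records its input/output dimensions in a :class:`QCReport`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.decomposition import PCA

from .core import (
    CountMatrix,
    DistanceMatrix,
    ValidationError,
    euclidean_distances,
    manhattan_distances,
    spearman_distance,
)

__all__ = [
    "QCReport",
    "qc_filter",
    "correlation_gene_filter",
    "normalize_log",
    "top_variable_genes",
    "pca_reduce",
    "run_recipe",
    "RECIPES",
]

log = logging.getLogger(__name__)

RECIPES = ("correlation", "pca_euclidean", "manhattan_dss")


@dataclass
class QCReport:
    """Counts of what each filtering stage kept, plus the computed correlation cutoff."""

    cells_in: int = 0
    cells_kept: int = 0
    genes_in: int = 0
    genes_kept_by_total: int = 0
    genes_kept_by_correlation: int | None = None
    correlation_threshold_value: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def qc_filter(
    counts: CountMatrix,
    min_cell_total: float = 2500,
    min_gene_total: float = 25,
) -> tuple[CountMatrix, QCReport]:
    """Drop low-depth cells, then low-count genes.

    Cells with total molecules strictly below ``min_cell_total`` go first;
    gene totals are then computed over the *surviving* cells and genes
    strictly below ``min_gene_total`` are dropped.  Both thresholds are
    strict "< " cuts: a cell at exactly 2500 is kept.
    """
    x = counts.counts
    report = QCReport(cells_in=counts.n_samples, genes_in=counts.n_features)
    cell_keep = x.sum(axis=0) >= min_cell_total
    x2 = x[:, cell_keep]
    report.cells_kept = int(cell_keep.sum())
    gene_keep = x2.sum(axis=1) >= min_gene_total
    report.genes_kept_by_total = int(gene_keep.sum())
    if report.cells_kept == 0 or report.genes_kept_by_total == 0:
        raise ValidationError(f"QC filter removed everything: {report.to_dict()}")
    out = CountMatrix(
        feature_ids=tuple(g for g, k in zip(counts.feature_ids, gene_keep) if k),
        sample_ids=tuple(c for c, k in zip(counts.sample_ids, cell_keep) if k),
        counts=x2[gene_keep],
    )
    log.info("qc_filter: cells %d -> %d, genes %d -> %d",
             report.cells_in, report.cells_kept, report.genes_in, report.genes_kept_by_total)
    return out, report


def correlation_gene_filter(
    counts: CountMatrix,
    percentile: float = 90,
    min_partners: int = 5,
    method: str = "pearson",
) -> tuple[CountMatrix, QCReport]:
    """Keep genes that co-vary with enough other genes.

    Computes the gene-gene correlation matrix, sets the cutoff at the given
    percentile of its off-diagonal values, and keeps genes with at least
    ``min_partners`` other genes correlating strictly above the cutoff.
    Constant genes have undefined correlation; they are excluded from the
    correlation (with a warning) and always dropped.
    """
    if counts.n_features < 2 or counts.n_samples < 3:
        raise ValidationError("correlation filter needs >= 2 genes and >= 3 cells")
    x = counts.counts
    if method == "spearman":
        from scipy.stats import rankdata

        x = rankdata(x, axis=1)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    sd = x.std(axis=1)
    usable = sd > 0
    if not np.all(usable):
        warnings.warn(
            f"{int((~usable).sum())} constant gene(s) excluded from the correlation filter",
            stacklevel=2,
        )
    report = QCReport(
        cells_in=counts.n_samples, cells_kept=counts.n_samples,
        genes_in=counts.n_features, genes_kept_by_total=counts.n_features,
    )
    idx = np.nonzero(usable)[0]
    if len(idx) < 2:
        raise ValidationError("fewer than 2 non-constant genes; correlation filter impossible")
    corr = np.corrcoef(x[idx])
    off = corr[np.triu_indices(len(idx), k=1)]
    cutoff = float(np.percentile(off, percentile))
    partners = (corr > cutoff).sum(axis=1) - (np.diag(corr) > cutoff).astype(int)
    keep_idx = idx[partners >= min_partners]
    report.correlation_threshold_value = cutoff
    report.genes_kept_by_correlation = int(len(keep_idx))
    if len(keep_idx) == 0:
        raise ValidationError(f"correlation filter removed every gene: {report.to_dict()}")
    out = CountMatrix(
        feature_ids=tuple(counts.feature_ids[i] for i in keep_idx),
        sample_ids=counts.sample_ids,
        counts=counts.counts[keep_idx],
    )
    log.info("correlation_gene_filter: cutoff %.4f, genes %d -> %d",
             cutoff, report.genes_in, report.genes_kept_by_correlation)
    return out, report


def normalize_log(
    counts: CountMatrix | np.ndarray,
    scale: float = 1e3,
    pseudocount: float = 1.0,
    log_base: float = 2.0,
) -> np.ndarray:
    """Depth-normalise and log-transform: ``log2(count / cell_total * 1e3 + 1)``.

    Each cell's counts are divided by that cell's total, scaled, offset by a
    pseudocount and logged; zeros map to exactly 0.  Monotone within a cell.
    """
    x = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts, dtype=float)
    totals = x.sum(axis=0)
    if np.any(totals <= 0):
        bad = int(np.nonzero(totals <= 0)[0][0])
        raise ValidationError(f"cell {bad} has zero total count; run qc_filter first")
    return np.log(x / totals[None, :] * scale + pseudocount) / np.log(log_base)


def top_variable_genes(normalized: np.ndarray, n_genes: int = 200) -> np.ndarray:
    """Row indices of the ``n_genes`` most variable genes (ties by row order)."""
    x = np.asarray(normalized, dtype=float)
    if n_genes > x.shape[0]:
        raise ValidationError(f"requested {n_genes} genes but only {x.shape[0]} available")
    var = x.var(axis=1)
    # stable sort on negated variance keeps earlier rows on ties
    order = np.argsort(-var, kind="stable")[:n_genes]
    return np.sort(order)


def pca_reduce(normalized: np.ndarray, n_components: int = 50) -> np.ndarray:
    """Principal-component scores per cell (samples x components).

    Genes are centred across cells; components are deterministic up to the
    usual sign convention (largest-magnitude loading positive).  Requests for
    more components than the data supports are clipped with a warning.
    """
    x = np.asarray(normalized, dtype=float)
    max_comp = min(x.shape[0], x.shape[1])
    if n_components > max_comp:
        warnings.warn(
            f"n_components clipped from {n_components} to {max_comp}", stacklevel=2
        )
        n_components = max_comp
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x.T)
    # deterministic signs independent of the SVD backend
    comps = pca.components_
    for m in range(scores.shape[1]):
        j = int(np.argmax(np.abs(comps[m])))
        if comps[m, j] < 0:
            scores[:, m] = -scores[:, m]
    return scores


def run_recipe(counts, recipe: str, **params) -> tuple[DistanceMatrix, QCReport]:
    """Run one of the named preprocessing recipes end to end.

    ``params`` override stage defaults (``min_cell_total``, ``percentile``,
    ``n_genes``, ``n_components``, ...).  Returns the sample-by-sample
    distance matrix and the merged QC report.  The ``manhattan_dss`` recipe
    accepts any real feature x sample matrix (scores may be negative); the
    count-based recipes require a :class:`CountMatrix`.
    """
    if recipe == "manhattan_dss":
        dist = manhattan_distances(counts)
        n_feat = counts.n_features if isinstance(counts, CountMatrix) else np.asarray(counts).shape[0]
        report = QCReport(
            cells_in=dist.n, cells_kept=dist.n,
            genes_in=n_feat, genes_kept_by_total=n_feat,
        )
        return dist, report
    if not isinstance(counts, CountMatrix):
        raise TypeError(f"recipe {recipe!r} requires a CountMatrix")
    if recipe not in ("correlation", "pca_euclidean"):
        raise ValueError(f"unknown recipe {recipe!r}; choose from {RECIPES}")

    filtered, report = qc_filter(
        counts,
        min_cell_total=params.get("min_cell_total", 2500),
        min_gene_total=params.get("min_gene_total", 25),
    )
    filtered, corr_report = correlation_gene_filter(
        filtered,
        percentile=params.get("percentile", 90),
        min_partners=params.get("min_partners", 5),
        method=params.get("correlation_method", "pearson"),
    )
    report.genes_kept_by_correlation = corr_report.genes_kept_by_correlation
    report.correlation_threshold_value = corr_report.correlation_threshold_value
    norm = normalize_log(filtered)

    if recipe == "correlation":
        sel = top_variable_genes(norm, n_genes=min(params.get("n_genes", 200), norm.shape[0]))
        sub = norm[sel]
        import pandas as pd

        frame = pd.DataFrame(sub, columns=list(filtered.sample_ids))
        dist = spearman_distance(frame)
    else:
        scores = pca_reduce(norm, n_components=params.get("n_components", 50))
        import pandas as pd

        frame = pd.DataFrame(scores.T, columns=list(filtered.sample_ids))
        dist = euclidean_distances(frame)
    log.info("run_recipe(%s): %d samples -> distance matrix", recipe, dist.n)
    return dist, report
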