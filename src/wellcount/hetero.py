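"""Expression heterogeneity: normalization, HVG selection, clustering, scoring.

The analysis chain mirrors standard practice for UMI-count matrices:

1. normalize each cell's molecule counts to fractions of its total
   (these fractions are the expression levels; log(1 + scale*x) where a log
   scale is needed);
2. select highly variable genes (HVGs) by a dispersion analysis — genes
   detected in >= 5 cells are binned into 50 evenly-spaced bins of log mean
   expression, and a gene is highly variable when the z-score of its log CV
   within its bin exceeds 3 and it is detected in >= 10% of cells;
3. compute the cells x cells Pearson correlation matrix over log expression
   restricted to HVGs, feed its rows to t-SNE, and assign discrete clusters
   with DBSCAN (Euclidean metric) on the 2-D embedding;
4. score per-cell expression of marker gene sets (e.g. glioma subtype
   classifiers) and test cluster enrichment of above-median scores with the
   hypergeometric tail.

The subtype score for cell i and a gene set is

    S = (n_subtype_i / N_subtype) / n_genes_i

with n_subtype_i the subtype genes detected (count >= 1) in cell i,
N_subtype the subtype genes detected anywhere in the dataset, and
n_genes_i the genes detected in cell i: the detection fraction of the
subtype's genes normalized by the cell's overall detection breadth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.cluster import DBSCAN
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors

from .molcount import CountMatrix, knee_point

__all__ = [
    "ExpressionMatrix",
    "normalize",
    "select_hvg",
    "correlation_matrix",
    "ClusterResult",
    "embed_and_cluster",
    "SubtypeScores",
    "subtype_score",
    "load_subtype_gene_sets",
    "EnrichmentResult",
    "enrichment_test",
]


@dataclass
class ExpressionMatrix:
    """Per-cell normalized expression (molecule fractions) with labels."""

    barcodes: list[str]
    genes: list[str]
    fractions: sp.csr_matrix  # rows sum to 1
    scale: float = 1e4

    def log_values(self, genes: Sequence[str] | None = None) -> np.ndarray:
        """Dense log(1 + scale * fraction), optionally restricted to genes."""
        if genes is None:
            M = self.fractions
        else:
            index = {g: j for j, g in enumerate(self.genes)}
            cols = [index[g] for g in genes]
            M = self.fractions[:, cols]
        return np.log1p(self.scale * M.toarray())

    @property
    def detected(self) -> sp.csr_matrix:
        return (self.fractions > 0).tocsr()


def normalize(matrix: CountMatrix, scale: float = 1e4) -> ExpressionMatrix:
    """Normalize molecule counts by each cell's total molecule count."""
    totals = matrix.n_molecules.astype(float)
    if (totals == 0).any():
        bad = [bc for bc, t in zip(matrix.barcodes, totals) if t == 0]
        raise ValueError(f"empty cell(s) with zero molecules: {bad[:5]}")
    inv = sp.diags(1.0 / totals)
    return ExpressionMatrix(
        barcodes=list(matrix.barcodes),
        genes=list(matrix.genes),
        fractions=(inv @ matrix.X).tocsr(),
        scale=scale,
    )


def select_hvg(
    expr: ExpressionMatrix,
    n_bins: int = 50,
    z_thresh: float = 3.0,
    min_cells: int = 5,
    min_frac: float = 0.10,
) -> pd.DataFrame:
    """Dispersion-binned highly-variable-gene selection.

    Genes detected in at least ``min_cells`` cells enter the CV-vs-mean
    analysis; ``n_bins`` evenly-spaced bins partition the range of
    log10 mean expression, and each gene's z-score is computed on log10 CV
    against the other members of its bin.  Selected genes satisfy
    z > ``z_thresh``, detected fraction >= ``min_frac`` and detected cells
    >= ``min_cells``.  Bins with fewer than 2 eligible genes give their
    members z = 0 (no dispersion baseline, cannot be selected).  The report
    is invariant to gene and cell order.
    """
    F = expr.fractions
    n_cells = F.shape[0]
    dense = F.toarray()
    detected_cells = (dense > 0).sum(axis=0)
    mean = dense.mean(axis=0)
    sd = dense.std(axis=0, ddof=1) if n_cells > 1 else np.zeros_like(mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)

    eligible = detected_cells >= min_cells
    z = np.zeros(len(expr.genes))
    bin_index = np.full(len(expr.genes), -1)
    if eligible.sum() >= 2:
        log_mean = np.log10(mean[eligible])
        lo, hi = log_mean.min(), log_mean.max()
        if hi == lo:
            bins = np.zeros(len(log_mean), dtype=int)
        else:
            edges = np.linspace(lo, hi, n_bins + 1)
            bins = np.clip(np.digitize(log_mean, edges) - 1, 0, n_bins - 1)
        bin_index[eligible] = bins
        log_cv = np.full(len(log_mean), np.nan)
        ok = cv[eligible] > 0
        log_cv[ok] = np.log10(cv[eligible][ok])
        z_elig = np.zeros(len(log_mean))
        for b in np.unique(bins):
            members = (bins == b) & ~np.isnan(log_cv)
            if members.sum() < 2:
                continue
            mu = log_cv[members].mean()
            s = log_cv[members].std(ddof=0)
            if s > 0:
                z_members = (log_cv[members] - mu) / s
                z_elig[members] = z_members
        z[eligible] = z_elig

    detected_frac = detected_cells / n_cells
    selected = (z > z_thresh) & (detected_frac >= min_frac) & (detected_cells >= min_cells)
    return pd.DataFrame(
        {
            "gene_id": expr.genes,
            "mean_expression": mean,
            "cv": cv,
            "bin": bin_index + 1,  # 1-based; 0 = not binned
            "dispersion_z": z,
            "detected_cells": detected_cells,
            "detected_fraction": detected_frac,
            "selected": selected,
        }
    ).set_index("gene_id")


def hvg_gene_list(report: pd.DataFrame, min_genes: int = 30) -> list[str]:
    """Genes to cluster on: the selected HVGs, topped up when too few pass.

    Small or shallow datasets can leave almost no gene above the z
    threshold; in that case the list is topped up to ``min_genes`` with the
    highest-dispersion genes that pass the detection filters, which keeps
    the downstream correlation analysis meaningful.
    """
    selected = list(report.index[report["selected"]])
    if len(selected) >= min_genes:
        return selected
    eligible = report[report["bin"] > 0].sort_values(
        "dispersion_z", ascending=False, kind="stable"
    )
    for g in eligible.index:
        if g not in selected:
            selected.append(g)
        if len(selected) >= min_genes:
            break
    return selected


def correlation_matrix(expr: ExpressionMatrix, hvg_genes: Sequence[str]) -> np.ndarray:
    """Cells x cells Pearson correlation over log expression of the HVGs.

    Symmetric with unit diagonal; a cell with zero variance across the HVGs
    gets zero correlation with every other cell.
    """
    if len(hvg_genes) < 2:
        raise ValueError("need at least 2 highly variable genes")
    L = expr.log_values(hvg_genes)
    sd = L.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(L)
    C = np.atleast_2d(C)
    C[~np.isfinite(C)] = 0.0
    np.fill_diagonal(C, 1.0)
    if (sd == 0).any():
        zero = np.where(sd == 0)[0]
        C[zero, :] = 0.0
        C[:, zero] = 0.0
        np.fill_diagonal(C, 1.0)
    return C


@dataclass
class ClusterResult:
    cells: pd.DataFrame       # barcode/index, x, y, cluster (-1 = noise)
    clusters: pd.DataFrame    # cluster, size, median_molecules (if provided)
    eps: float
    seed: int

    @property
    def labels(self) -> np.ndarray:
        return self.cells["cluster"].to_numpy()


def _eps_from_knn(coords: np.ndarray, k: int) -> float:
    """eps heuristic: elbow of the ascending sorted k-NN distance curve.

    The elbow is the point farthest below the chord joining the curve's
    endpoints — where per-cell neighbourhood distances stop growing smoothly
    and shoot up into the sparse tail.  A cushion factor of 1.5 places eps
    just past the elbow, inside the dense regime.
    """
    nn = NearestNeighbors(n_neighbors=min(k + 1, len(coords))).fit(coords)
    dist, _ = nn.kneighbors(coords)
    kth = np.sort(dist[:, -1])
    x = np.arange(len(kth), dtype=float)
    dx, dy = x[-1] - x[0], kth[-1] - kth[0]
    norm = float(np.hypot(dx, dy))
    if norm == 0:
        return float(np.median(kth)) or 1.0
    signed = (dx * (kth - kth[0]) - dy * (x - x[0])) / norm
    elbow = int(np.argmin(signed))  # most negative = farthest below the chord
    eps = 1.5 * float(kth[elbow])
    if eps <= 0:
        eps = float(np.median(kth)) or 1.0
    return eps


def embed_and_cluster(
    corr: np.ndarray,
    perplexity: float = 30.0,
    eps: float | None = None,
    min_samples: int = 10,
    seed: int = 0,
    matrix: CountMatrix | None = None,
    as_distance: bool = False,
) -> ClusterResult:
    """t-SNE embedding of the correlation matrix plus DBSCAN cluster labels.

    The rows of the cells x cells correlation matrix are the feature vectors
    fed to t-SNE (``as_distance=True`` instead feeds 1 - r as a precomputed
    distance).  DBSCAN runs on the 2-D coordinates with the Euclidean
    metric; ``eps`` defaults to the knee of the ``min_samples``-NN distance
    curve.  Deterministic given ``seed``.  Per-cluster median molecule
    counts are reported when the originating count matrix is supplied
    (a check that coverage is not what separates the clusters).
    """
    corr = np.asarray(corr, dtype=float)
    n = corr.shape[0]
    if corr.shape != (n, n):
        raise ValueError("expected a square cells x cells correlation matrix")
    min_cells = max(int(3 * perplexity), 10)
    if n < min_cells:
        raise ValueError(
            f"{n} cells < required minimum {min_cells} for perplexity {perplexity}"
        )
    if as_distance:
        emb = TSNE(
            n_components=2,
            perplexity=perplexity,
            metric="precomputed",
            init="random",
            random_state=seed,
        ).fit_transform(1.0 - corr)
    else:
        emb = TSNE(
            n_components=2,
            perplexity=perplexity,
            init="pca",
            random_state=seed,
        ).fit_transform(corr)
    chosen_eps = eps if eps is not None else _eps_from_knn(emb, min_samples)
    labels = DBSCAN(eps=chosen_eps, min_samples=min_samples).fit_predict(emb)

    cells = pd.DataFrame({"x": emb[:, 0], "y": emb[:, 1], "cluster": labels})
    if matrix is not None:
        cells.index = matrix.barcodes
        cells["n_molecules"] = matrix.n_molecules
    cluster_rows = []
    for c in sorted(set(labels)):
        mask = labels == c
        row = {"cluster": c, "size": int(mask.sum())}
        if matrix is not None:
            row["median_molecules"] = float(np.median(matrix.n_molecules[mask]))
        cluster_rows.append(row)
    return ClusterResult(
        cells=cells, clusters=pd.DataFrame(cluster_rows), eps=chosen_eps, seed=seed
    )


@dataclass
class SubtypeScores:
    scores: pd.DataFrame   # barcode-indexed: n_subtype, n_genes, score
    n_subtype_dataset: int

    @property
    def values(self) -> pd.Series:
        return self.scores["score"]


def subtype_score(matrix: CountMatrix, gene_set: Iterable[str]) -> SubtypeScores:
    """Per-cell detection score for a marker gene set (see module docstring).

    Detection means molecule count >= 1.  S = 0 for a cell detecting none of
    the set; halving follows doubling of the cell's detected-gene total.
    """
    gene_set = set(gene_set)
    cols = [j for j, g in enumerate(matrix.genes) if g in gene_set]
    detected_any = (
        np.asarray((matrix.X[:, cols] > 0).sum(axis=0)).ravel() > 0 if cols else np.array([])
    )
    n_dataset = int(detected_any.sum()) if cols else 0
    if n_dataset == 0:
        raise ValueError("subtype genes absent from dataset")
    live_cols = [c for c, d in zip(cols, detected_any) if d]
    n_sub = np.asarray((matrix.X[:, live_cols] > 0).sum(axis=1)).ravel()
    n_genes = matrix.n_genes_detected
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(n_genes > 0, (n_sub / n_dataset) / np.maximum(n_genes, 1), 0.0)
    scores = pd.DataFrame(
        {"n_subtype": n_sub, "n_genes": n_genes, "score": s}, index=matrix.barcodes
    )
    return SubtypeScores(scores=scores, n_subtype_dataset=n_dataset)


def load_subtype_gene_sets(path: str) -> dict[str, list[str]]:
    """Load ``subtype<TAB>gene`` TSV into subtype -> gene list."""
    df = pd.read_csv(path, sep="\t", header=None, names=["subtype", "gene"], comment="#")
    sets = {s: list(sub["gene"]) for s, sub in df.groupby("subtype", sort=False)}
    if not sets:
        raise ValueError("no subtype gene sets found")
    return sets


@dataclass(frozen=True)
class EnrichmentResult:
    p_value: float
    overlap: int        # above-median cells inside the cluster
    cluster_size: int
    n_successes: int    # above-median cells in the population
    population: int


def enrichment_test(
    scores: pd.Series | np.ndarray,
    labels: np.ndarray,
    cluster: int,
    include_noise: bool = False,
) -> EnrichmentResult:
    """Hypergeometric test for above-median scores concentrating in a cluster.

    Population = all clustered cells (noise label -1 excluded unless
    ``include_noise``); successes = cells with score strictly above the
    population median; the p-value is the upper tail P(X >= overlap) for the
    cluster treated as a draw without replacement.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    pop_mask = np.ones(len(labels), bool) if include_noise else labels != -1
    if not pop_mask.any():
        raise ValueError("empty population")
    in_cluster = pop_mask & (labels == cluster)
    if not in_cluster.any():
        raise ValueError(f"cluster {cluster} is empty")
    pop_scores = scores[pop_mask]
    median = float(np.median(pop_scores))
    success_mask = pop_mask & (scores > median)  # ties at the median: not above
    M = int(pop_mask.sum())
    K = int(success_mask.sum())
    n = int(in_cluster.sum())
    k = int((success_mask & in_cluster).sum())
    p = float(stats.hypergeom.sf(k - 1, M, K, n))
    return EnrichmentResult(p_value=p, overlap=k, cluster_size=n, n_successes=K, population=M)
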