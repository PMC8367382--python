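"""Embedding, Leiden clustering, phenotyping and differential expression.

Gated, within-cell-normalized PAC profiles are embedded with UMAP
(15 nearest neighbours) and clustered per animal with Leiden community
detection on a kNN graph, scanning the resolution parameter for the
value that yields five clusters.  Marker genes then map clusters to
phenotypes — Synpr -> core, Nnat -> shell, Ctgf -> deep layer 6, with
the remaining clusters ranked cortical by Pcp4.  Differential
expression between cell groups uses two-sided Mann-Whitney U tests
with Bonferroni correction across the genes tested.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neighbors import kneighbors_graph

from .quantification import PACMatrix

log = logging.getLogger(__name__)

DEFAULT_MARKER_MAP = {"core": "Synpr", "shell": "Nnat", "deep_L6": "Ctgf"}
CORTEX_RANK_GENE = "Pcp4"
DEFAULT_RESOLUTION_GRID = np.round(np.arange(0.1, 2.0001, 0.05), 4)


@dataclass
class ClusterResult:
    labels: np.ndarray                    # per-cell cluster ids, 0..k-1
    resolution: float
    n_clusters: int
    cell_index: pd.Index
    cluster_means: pd.DataFrame | None = None   # cluster x gene raw-PAC means
    phenotype_map: dict[int, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def phenotypes(self) -> pd.Series:
        """Per-cell phenotype names (cluster id where unassigned)."""
        return pd.Series(
            [self.phenotype_map.get(c, f"cluster_{c}") for c in self.labels],
            index=self.cell_index, name="phenotype")


def embed_umap(pac_norm: PACMatrix, n_neighbors: int = 15,
               seed: int = 0) -> np.ndarray:
    """2-D UMAP of normalized profiles; deterministic for a fixed seed."""
    import umap  # deferred: numba compilation is slow at import

    n = pac_norm.n_cells
    if n < n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors + 1 = {n_neighbors + 1} cells, got {n}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # umap warns that seeding disables parallelism
        reducer = umap.UMAP(n_neighbors=n_neighbors, n_components=2,
                            random_state=seed)
        coords = reducer.fit_transform(pac_norm.values.to_numpy(dtype=float))
    if not np.all(np.isfinite(coords)):
        raise RuntimeError("non-finite embedding coordinates")
    return np.asarray(coords, dtype=float)


def _knn_igraph(x: np.ndarray, n_neighbors: int):
    """Undirected, unweighted symmetrized kNN graph (Euclidean)."""
    import igraph as ig

    adj = kneighbors_graph(x, n_neighbors=min(n_neighbors, len(x) - 1),
                           mode="connectivity", include_self=False)
    adj = adj.maximum(adj.T).tocoo()
    edges = {(min(i, j), max(i, j)) for i, j in zip(adj.row, adj.col)}
    g = ig.Graph(n=len(x), edges=sorted(edges), directed=False)
    return g


def cluster_leiden(
    pac_norm: PACMatrix,
    target_k: int = 5,
    resolution_grid: np.ndarray | None = None,
    seed: int = 0,
    n_neighbors: int = 15,
) -> ClusterResult:
    """Leiden partition at the first grid resolution giving ``target_k``.

    The grid is scanned in ascending order; if no resolution yields
    exactly ``target_k`` clusters, the resolution minimizing
    ``|k - target_k|`` is returned (ties -> lower resolution) with a
    warning recorded on the result.
    """
    import leidenalg

    grid = np.asarray(DEFAULT_RESOLUTION_GRID if resolution_grid is None
                      else resolution_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty resolution grid")
    n = pac_norm.n_cells
    if n < target_k:
        raise ValueError(f"need at least target_k={target_k} cells, got {n}")

    x = pac_norm.values.to_numpy(dtype=float)
    g = _knn_igraph(x, n_neighbors)
    best: tuple[int, float, np.ndarray] | None = None
    notes: list[str] = []
    for res in np.sort(grid):
        part = leidenalg.find_partition(
            g, leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=float(res), seed=int(seed))
        labels = np.asarray(part.membership)
        k = int(labels.max()) + 1
        if k == target_k:
            best = (k, float(res), labels)
            break
        if best is None or abs(k - target_k) < abs(best[0] - target_k):
            best = (k, float(res), labels)
    k, res, labels = best
    if k != target_k:
        msg = (f"no grid resolution produced {target_k} clusters; "
               f"using resolution {res} with k={k}")
        warnings.warn(msg, stacklevel=2)
        notes.append(msg)
    log.info("leiden: k=%d at resolution %.2f (n=%d cells)", k, res, n)
    return ClusterResult(labels=labels, resolution=res, n_clusters=k,
                         cell_index=pac_norm.values.index, warnings=notes)


def assign_phenotypes(
    clusters: ClusterResult,
    pac_raw: PACMatrix,
    marker_map: dict[str, str] | None = None,
) -> ClusterResult:
    """Map clusters to phenotypes by maximal mean raw marker PAC.

    Markers are consumed in the fixed order core (Synpr), shell (Nnat),
    deep_L6 (Ctgf): each takes the highest-mean unassigned cluster.
    Remaining clusters are labeled cortex_a / cortex_b by descending
    mean Pcp4.  Ties break toward the lower cluster id.  Assignment is
    invariant to any relabeling of cluster ids.
    """
    markers = marker_map or DEFAULT_MARKER_MAP
    values = pac_raw.values.loc[clusters.cell_index]
    means = values.groupby(clusters.labels).mean()
    means.index.name = "cluster"
    unassigned = list(means.index)
    phenotype_map: dict[int, str] = {}
    notes = list(clusters.warnings)

    for pheno, gene in markers.items():
        if gene not in means.columns:
            raise KeyError(f"marker gene {gene!r} missing from PAC matrix")
        if not unassigned:
            msg = f"no cluster left for phenotype {pheno}"
            warnings.warn(msg, stacklevel=2)
            notes.append(msg)
            continue
        col = means.loc[unassigned, gene]
        top = col.max()
        tied = [c for c in unassigned if col.loc[c] == top]
        if len(tied) > 1:
            msg = (f"marker {gene} tied across clusters {tied}; "
                   "assigning lowest id")
            warnings.warn(msg, stacklevel=2)
            notes.append(msg)
        chosen = min(tied)
        phenotype_map[chosen] = pheno
        unassigned.remove(chosen)

    if unassigned:
        if CORTEX_RANK_GENE in means.columns:
            order = sorted(unassigned,
                           key=lambda c: (-means.loc[c, CORTEX_RANK_GENE], c))
        else:
            order = sorted(unassigned)
        for name, c in zip(("cortex_a", "cortex_b"), order):
            phenotype_map[c] = name
        extra = order[2:]
        if extra:
            msg = f"clusters {extra} left unphenotyped"
            warnings.warn(msg, stacklevel=2)
            notes.append(msg)
    if len(means) < len(markers):
        msg = "fewer clusters than marker phenotypes; partial assignment"
        if msg not in notes:
            notes.append(msg)

    return ClusterResult(labels=clusters.labels, resolution=clusters.resolution,
                         n_clusters=clusters.n_clusters,
                         cell_index=clusters.cell_index,
                         cluster_means=means, phenotype_map=phenotype_map,
                         warnings=notes)


_STAR_BINS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p_adj: float) -> str:
    """ns: p >= 0.05; * < 0.05; ** < 0.01; *** < 0.001 (on adjusted p)."""
    for cut, stars in _STAR_BINS:
        if p_adj < cut:
            return stars
    return "ns"


def differential_expression(
    pac_raw: PACMatrix | pd.DataFrame,
    group_a: pd.Index | np.ndarray,
    group_b: pd.Index | np.ndarray,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Per-gene two-sided Mann-Whitney U with Bonferroni correction.

    ``group_a`` / ``group_b`` index rows of the raw PAC matrix.  The
    correction multiplies each raw p by the number of genes tested in
    this call (capped at 1).  Uses the exact null distribution for
    small tie-free samples, the normal approximation otherwise (scipy's
    default policy).
    """
    values = pac_raw.values if isinstance(pac_raw, PACMatrix) else pac_raw
    a = values.loc[group_a]
    b = values.loc[group_b]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    genes = list(genes) if genes is not None else list(values.columns)
    m = len(genes)
    rows = []
    for gene in genes:
        xa = a[gene].to_numpy(dtype=float)
        xb = b[gene].to_numpy(dtype=float)
        if np.ptp(np.concatenate([xa, xb])) == 0:
            u, p = len(xa) * len(xb) / 2.0, 1.0
        else:
            u, p = stats.mannwhitneyu(xa, xb, alternative="two-sided")
        p_adj = min(1.0, p * m)
        rows.append({
            "gene": gene, "U": float(u), "p": float(p), "p_adj": p_adj,
            "stars": significance_stars(p_adj),
            "median_a": float(np.median(xa)), "median_b": float(np.median(xb)),
        })
    return pd.DataFrame(rows).set_index("gene")


def box_summary(x: np.ndarray) -> dict[str, float]:
    """Box-plot summary: quartile hinges and 1.5*IQR whiskers.

    Whiskers extend to the most extreme data points within 1.5 IQR of
    the hinges; values beyond the whiskers are omitted from the summary.
    """
    x = np.asarray(x, dtype=float)
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo = x[x >= q1 - 1.5 * iqr]
    hi = x[x <= q3 + 1.5 * iqr]
    return {"q1": float(q1), "median": float(med), "q3": float(q3),
            "whisker_lo": float(lo.min()) if lo.size else float(q1),
            "whisker_hi": float(hi.max()) if hi.size else float(q3),
            "n": int(x.size)}


__all__ = [
    "ClusterResult", "embed_umap", "cluster_leiden", "assign_phenotypes",
    "differential_expression", "significance_stars", "box_summary",
    "DEFAULT_MARKER_MAP", "DEFAULT_RESOLUTION_GRID",
]
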