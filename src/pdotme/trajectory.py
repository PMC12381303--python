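"""Rooted pseudotime, trajectory-associated genes, co-expression modules.

Pseudotime is computed on a principal tree built deterministically: PCA of
the normalized expression, cluster centroids, a Euclidean minimum spanning
tree over the centroids, and orthogonal projection of every cell onto its
cluster's incident tree edges.  A cell's pseudotime is the geodesic
distance along the tree from the root cluster's centroid to the cell's
projection, shifted so the root cluster starts at 0.

Genes varying smoothly along the trajectory are detected by Moran's I
spatial autocorrelation on a symmetric k-nearest-neighbor graph of the
embedding, with the analytic normal approximation for significance.
Significant genes are grouped into co-expression modules by
average-linkage hierarchical clustering of correlation distance, with the
module count chosen by silhouette.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.sparse as sp
import scipy.sparse.csgraph
import scipy.spatial.distance
import scipy.stats

from .core import ExpressionMatrix, ValidationError, normalize_log1p
from .diffexpr import bh_adjust, hurdle_de

logger = logging.getLogger("pdotme")

__all__ = [
    "TrajectoryResult",
    "fit_pseudotime",
    "knn_graph",
    "morans_i",
    "graph_autocorrelation",
    "find_gene_modules",
    "branch_contrast",
]


@dataclass
class TrajectoryResult:
    embedding: np.ndarray  # cells x d
    centroids: np.ndarray  # clusters x d
    cluster_names: list[str]
    edges: list[tuple[int, int, float]]  # MST over centroids
    root_cluster: str
    pseudotime: np.ndarray
    branch_id: np.ndarray
    cell_cluster: np.ndarray


def _pca(X: np.ndarray, d: int) -> np.ndarray:
    from sklearn.decomposition import PCA

    d = int(min(d, X.shape[0] - 1, X.shape[1]))
    return PCA(n_components=d, svd_solver="auto", random_state=0).fit_transform(X)


def fit_pseudotime(
    expr: ExpressionMatrix,
    cluster_col: str | np.ndarray = "cluster",
    root_cluster: str = "",
    d: int = 30,
) -> TrajectoryResult:
    """Centroid-MST pseudotime rooted at ``root_cluster``."""
    clusters = (
        expr.cell_table[cluster_col].to_numpy()
        if isinstance(cluster_col, str)
        else np.asarray(cluster_col)
    )
    names = sorted(pd.unique(clusters).tolist())
    if root_cluster not in names:
        raise ValidationError(f"root cluster {root_cluster!r} not present")
    if len(names) < 2:
        raise ValidationError("need >= 2 clusters")
    if expr.normalized is None:
        normalize_log1p(expr)
    X = np.asarray(expr.normalized.todense()).T  # cells x genes
    emb = _pca(X, d)

    centroids = np.stack([emb[clusters == c].mean(axis=0) for c in names])
    k = len(names)
    dmat = scipy.spatial.distance.squareform(scipy.spatial.distance.pdist(centroids))
    mst = scipy.sparse.csgraph.minimum_spanning_tree(dmat)
    mst_sym = mst + mst.T
    coo = sp.coo_matrix(sp.triu(mst_sym))
    edges = [(int(i), int(j), float(w)) for i, j, w in zip(coo.row, coo.col, coo.data)]

    root_idx = names.index(root_cluster)
    node_dist = scipy.sparse.csgraph.dijkstra(mst_sym, indices=root_idx)

    # project each cell onto the incident edges of its cluster centroid
    cidx = np.array([names.index(c) for c in clusters])
    incident: dict[int, list[tuple[int, int, float]]] = {i: [] for i in range(k)}
    for i, j, w in edges:
        incident[i].append((i, j, w))
        incident[j].append((i, j, w))
    pseudotime = np.empty(len(clusters))
    branch_edge = np.empty(len(clusters), dtype=int)
    edge_index = {(i, j): e for e, (i, j, _) in enumerate(edges)}
    for ci in range(k):
        cells = np.flatnonzero(cidx == ci)
        if cells.size == 0:
            continue
        cand_pt = []
        cand_res = []
        for i, j, w in incident[ci] or []:
            u, v = centroids[i], centroids[j]
            seg = v - u
            L = np.linalg.norm(seg)
            t = np.clip((emb[cells] - u) @ seg / (L**2), 0.0, 1.0)
            proj = u + t[:, None] * seg
            resid = np.linalg.norm(emb[cells] - proj, axis=1)
            pt = np.minimum(node_dist[i] + t * L, node_dist[j] + (1 - t) * L)
            cand_pt.append(pt)
            cand_res.append(resid)
            cand_edge = edge_index[(i, j)]
            # keep per-edge results; chosen below by minimal residual
            if len(cand_pt) == 1:
                best_pt, best_res = pt.copy(), resid.copy()
                best_edge = np.full(cells.size, cand_edge)
            else:
                better = resid < best_res
                best_pt[better] = pt[better]
                best_res[better] = resid[better]
                best_edge[better] = cand_edge
        pseudotime[cells] = best_pt
        branch_edge[cells] = best_edge

    root_cells = cidx == root_idx
    pseudotime -= pseudotime[root_cells].min()
    pseudotime = np.maximum(pseudotime, 0.0)

    branch_of_edge = _branch_labels(edges, root_idx, k)
    branch_id = np.array([branch_of_edge[e] for e in branch_edge])
    return TrajectoryResult(
        embedding=emb,
        centroids=centroids,
        cluster_names=names,
        edges=edges,
        root_cluster=root_cluster,
        pseudotime=pseudotime,
        branch_id=branch_id,
        cell_cluster=clusters,
    )


def _branch_labels(edges, root: int, k: int) -> dict[int, str]:
    """Assign each tree edge to the branch below its last root-side fork."""
    adj: dict[int, list[tuple[int, int]]] = {i: [] for i in range(k)}
    for e, (i, j, _) in enumerate(edges):
        adj[i].append((j, e))
        adj[j].append((i, e))
    labels: dict[int, str] = {}
    counter = [0]

    def walk(node: int, parent: int, branch: str) -> None:
        children = [(c, e) for c, e in adj[node] if c != parent]
        fork = len(children) > 1 or node == root
        for c, e in children:
            b = branch
            if fork:
                counter[0] += 1
                b = f"B{counter[0]}"
            labels[e] = b
            walk(c, node, b)

    walk(root, -1, "B0")
    return labels


# --------------------------------------------------------------------------
# graph autocorrelation


def knn_graph(embedding: np.ndarray, k: int = 15) -> sp.csr_matrix:
    """Symmetric (union) binary kNN adjacency on the embedding."""
    from sklearn.neighbors import NearestNeighbors

    n = embedding.shape[0]
    if k < 2 or k >= n:
        raise ValidationError("k must satisfy 2 <= k < n_cells")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    A = nn.kneighbors_graph(embedding, mode="connectivity")
    A.setdiag(0)
    A.eliminate_zeros()
    W = ((A + A.T) > 0).astype(float)
    return sp.csr_matrix(W)


def morans_i(values: np.ndarray, W: sp.spmatrix) -> np.ndarray:
    """Moran's I for one gene (1-D) or many genes (genes x cells)."""
    V = np.atleast_2d(np.asarray(values, dtype=float))
    Z = V - V.mean(axis=1, keepdims=True)
    w_sum = W.sum()
    ZW = (W @ Z.T).T  # sparse-dense product, genes x cells
    num = np.einsum("gc,gc->g", ZW, Z)
    den = np.einsum("gc,gc->g", Z, Z)
    n = V.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (n / w_sum) * num / den
    out[den == 0] = 0.0
    return out if np.asarray(values).ndim > 1 else float(out[0])


def graph_autocorrelation(
    expr: ExpressionMatrix,
    embedding: np.ndarray,
    k: int = 15,
) -> pd.DataFrame:
    """Per-gene Moran's I on the kNN graph with analytic normal p-values.

    The test is one-sided (greater): trajectory-variable genes show
    positive spatial autocorrelation.  Constant genes are flagged with
    I = 0, p = 1.
    """
    W = knn_graph(embedding, k)
    if expr.normalized is None:
        normalize_log1p(expr)
    V = np.asarray(expr.normalized.todense())
    n = V.shape[1]
    I = morans_i(V, W)
    constant = V.std(axis=1) == 0
    I[constant] = 0.0

    # analytic moments under the normality assumption (symmetric binary W)
    w_sum = float(W.sum())
    deg = np.asarray(W.sum(axis=1)).ravel()
    s1 = 2.0 * w_sum  # 0.5 * sum (w_ij + w_ji)^2 for binary symmetric W
    s2 = float(np.sum((2.0 * deg) ** 2))
    e_i = -1.0 / (n - 1)
    var = (n**2 * s1 - n * s2 + 3 * w_sum**2) / (w_sum**2 * (n**2 - 1)) - e_i**2
    z = (I - e_i) / np.sqrt(var)
    p = scipy.stats.norm.sf(z)
    p[constant] = 1.0
    out = pd.DataFrame(
        {
            "gene_id": expr.gene_ids,
            "morans_i": I,
            "z": z,
            "p": p,
            "p_adj": bh_adjust(p),
            "constant": constant,
        }
    )
    return out


def find_gene_modules(
    autocorr: pd.DataFrame,
    expr: ExpressionMatrix,
    alpha: float = 0.05,
    n_modules_hint: int = 12,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> tuple[pd.Series, pd.DataFrame]:
    """Cluster trajectory-significant genes into co-expression modules.

    Significant genes (``p_adj < alpha``) are clustered on correlation
    distance (1 - Pearson across cells) with average linkage; the module
    count is chosen by silhouette over 2..``n_modules_hint`` (degenerate
    distances collapse to a single module, flagged).  Returns the module
    assignment per gene and a cells x modules score table computed with
    the bin-matched module scorer.
    """
    from sklearn.metrics import silhouette_score

    from .signatures import module_score

    sig = autocorr.loc[(autocorr["p_adj"] < alpha) & ~autocorr["constant"], "gene_id"]
    if len(sig) < 2:
        raise ValidationError("fewer than 2 significant genes; relax alpha")
    gidx = pd.Index(expr.gene_ids).get_indexer(sig)
    if expr.normalized is None:
        normalize_log1p(expr)
    V = np.asarray(expr.normalized.todense())[gidx]
    corr = np.corrcoef(V)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)

    cond = scipy.spatial.distance.squareform(dist, checks=False)
    if np.allclose(cond, 0):
        logger.warning("find_gene_modules: degenerate distances; single module")
        assignment = pd.Series(1, index=sig.to_numpy(), name="module")
    else:
        linkage = scipy.cluster.hierarchy.linkage(cond, method="average")
        best_k, best_s, best_lab = 1, -np.inf, None
        for k in range(2, min(n_modules_hint, len(sig) - 1) + 1):
            lab = scipy.cluster.hierarchy.fcluster(linkage, k, criterion="maxclust")
            if len(np.unique(lab)) < 2:
                continue
            s = silhouette_score(dist, lab, metric="precomputed")
            if s > best_s + 1e-15:
                best_k, best_s, best_lab = k, s, lab
        if best_lab is None:
            assignment = pd.Series(1, index=sig.to_numpy(), name="module")
        else:
            assignment = pd.Series(best_lab, index=sig.to_numpy(), name="module")

    scores = {}
    symbols = expr.gene_table.set_index("gene_id")["symbol"]
    for mod in sorted(assignment.unique()):
        members = symbols.loc[assignment.index[assignment == mod]].tolist()
        scores[f"module_{mod}"] = module_score(
            expr, members, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed + int(mod)
        )
    return assignment, pd.DataFrame(scores)


def branch_contrast(
    traj: TrajectoryResult,
    expr: ExpressionMatrix,
    branch_a: str,
    branch_b: str,
    batch: np.ndarray | None = None,
    **de_kwargs,
) -> pd.DataFrame:
    """Hurdle DE between the cells of two trajectory branches."""
    mask = np.isin(traj.branch_id, [branch_a, branch_b])
    if not np.any(traj.branch_id == branch_a) or not np.any(traj.branch_id == branch_b):
        raise ValidationError("both branches must be non-empty")
    sub = expr.subset_cells(mask)
    group = traj.branch_id[mask]
    b = None if batch is None else np.asarray(batch)[mask]
    return hurdle_de(sub, group, batch=b, **de_kwargs)
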