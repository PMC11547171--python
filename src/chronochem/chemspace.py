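"""Chemical-space embeddings: property/fingerprint PCA, MST tree map, and a
classical metric (Torgerson) embedding of fragment distance matrices.

PCA operates on z-scored columns with a deterministic sign convention (the
largest-magnitude loading of each component is made positive), so coordinates
are reproducible across runs and row orders.  The tree map is an exact
minimum spanning tree over pairwise Jaccard (Tanimoto) distances with a
lexicographic tie-break, laid out by a seeded force-directed placement.  The
nonlinear map is classical multidimensional scaling via eigendecomposition of
the double-centred squared-distance matrix — exact on Euclidean-embeddable
inputs and fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA


@dataclass
class Embedding:
    coordinates: np.ndarray  # n x 2
    explained_variance: np.ndarray | None = None  # all components (PCA only)
    loadings: pd.DataFrame | None = None  # property x component (property PCA)
    color_key: list | None = None
    degenerate: bool = False


@dataclass
class TreeMap:
    nodes: list[str]
    edges: list[tuple[int, int, float]]  # (i, j, jaccard distance)
    positions: np.ndarray  # n x 2 force-directed layout
    color_key: list | None = None

    @property
    def total_weight(self) -> float:
        return sum(w for _, _, w in self.edges)


def _pca_embed(matrix: np.ndarray, columns: list[str] | None) -> Embedding:
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("PCA needs at least 3 rows")
    std = X.std(axis=0)
    # relative tolerance: a column of identical floats is constant despite
    # accumulation noise in the mean
    keep = std > 1e-12 * (np.abs(X).max(axis=0) + 1.0)
    if not keep.any():
        raise ValueError("all columns are constant")
    X = X[:, keep]
    kept_cols = [c for c, k in zip(columns, keep) if k] if columns else None
    Z = (X - X.mean(axis=0)) / std[keep]
    pca = PCA(n_components=min(Z.shape), svd_solver="full")
    coords = pca.fit_transform(Z)
    components = pca.components_
    # sign convention: largest-magnitude loading of each component positive
    for k in range(components.shape[0]):
        j = np.argmax(np.abs(components[k]))
        if components[k, j] < 0:
            components[k] *= -1
            coords[:, k] *= -1
    loadings = (
        pd.DataFrame(
            components.T,
            index=kept_cols,
            columns=[f"PC{k + 1}" for k in range(components.shape[0])],
        )
        if kept_cols
        else None
    )
    two = coords[:, :2] if coords.shape[1] >= 2 else np.column_stack(
        [coords[:, 0], np.zeros(len(coords))]
    )
    return Embedding(
        coordinates=two,
        explained_variance=pca.explained_variance_ratio_,
        loadings=loadings,
    )


def pca_properties(frame: "pd.DataFrame | np.ndarray", color_key: list | None = None) -> Embedding:
    """PCA of a molecules x descriptors matrix (constant columns dropped)."""
    if isinstance(frame, pd.DataFrame):
        emb = _pca_embed(frame.to_numpy(dtype=float), list(frame.columns))
    else:
        emb = _pca_embed(np.asarray(frame), None)
    emb.color_key = color_key
    return emb


def pca_fingerprints(fps: np.ndarray, color_key: list | None = None) -> Embedding:
    """PCA of a 0/1 fingerprint matrix (substructure keys or hashed bits)."""
    emb = _pca_embed(np.asarray(fps, dtype=float), None)
    emb.color_key = color_key
    return emb


def jaccard_distance_matrix(fps: np.ndarray) -> np.ndarray:
    """Pairwise Jaccard distances of a 0/1 matrix (1 - |A&B|/|A|B|)."""
    X = np.asarray(fps, dtype=bool)
    inter = X.astype(np.int64) @ X.astype(np.int64).T
    sizes = X.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    return 1.0 - sim


def minimum_spanning_tree_edges(dist: np.ndarray) -> list[tuple[int, int, float]]:
    """Exact MST (Kruskal) with deterministic (weight, i, j) tie-break."""
    n = dist.shape[0]
    edges = sorted(
        (float(dist[i, j]), i, j) for i in range(n) for j in range(i + 1, n)
    )
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    out = []
    for w, i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            out.append((i, j, w))
            if len(out) == n - 1:
                break
    return out


def tree_map(
    node_labels: list[str],
    fps: np.ndarray,
    color_key: list | None = None,
    seed: int = 0,
    max_nodes: int = 50_000,
) -> TreeMap:
    """MST tree map over Jaccard distances of node fingerprints."""
    n = len(node_labels)
    if n < 2:
        raise ValueError("tree map needs at least 2 nodes")
    if n > max_nodes:
        raise ValueError(f"{n} nodes exceeds the desk-scale bound {max_nodes}")
    dist = jaccard_distance_matrix(fps)
    edges = minimum_spanning_tree_edges(dist)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_weighted_edges_from(edges)
    pos = nx.spring_layout(g, seed=seed)
    positions = np.array([pos[i] for i in range(n)])
    return TreeMap(nodes=list(node_labels), edges=edges, positions=positions, color_key=color_key)


def classical_mds(dist: np.ndarray, n_components: int = 2) -> tuple[np.ndarray, bool]:
    """Torgerson scaling of a distance matrix; returns (coords, degenerate)."""
    D = np.asarray(dist, dtype=float)
    n = D.shape[0]
    if not np.any(D > 0):
        return np.zeros((n, n_components)), True
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1][:n_components]
    lam = np.clip(eigval[order], 0.0, None)
    coords = eigvec[:, order] * np.sqrt(lam)
    return coords, False


def nonlinear_map(
    dist: np.ndarray, color_key: list | None = None
) -> Embedding:
    """Classical metric embedding of a (fragment) distance matrix in 2D."""
    coords, degenerate = classical_mds(dist, n_components=2)
    return Embedding(coordinates=coords, color_key=color_key, degenerate=degenerate)
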