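"""Cross-drug similarity structure: Jaccard matrix, network backbone, MDS.

Each drug is represented by its set of key-signal PTs.  Pairwise similarity
is the Jaccard coefficient J = |intersection| / |union|; D = 1 - J is a
metric dissimilarity.  The network backbone keeps edges at or above a
percentile of the empirical similarity distribution (80th by default, 70/90
as sensitivity), and a classical (Torgerson) MDS embeds the drugs in 2-D
principal coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .signals import SignalMatrix

__all__ = ["SimilarityMatrix", "NetworkBackbone", "MdsEmbedding",
           "jaccard_matrix", "backbone", "cluster_order", "mds_embed"]


@dataclass
class SimilarityMatrix:
    """Symmetric n×n Jaccard similarity over drugs, with labels and classes."""

    labels: list[str]
    values: np.ndarray
    classes: dict[str, str] | None = None

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def dissimilarity(self) -> np.ndarray:
        """The Jaccard distance view D = 1 - J (zero diagonal)."""
        d = 1.0 - self.values
        np.fill_diagonal(d, 0.0)
        return d

    def pair_values(self) -> np.ndarray:
        """Upper-triangle off-diagonal similarities, row-major order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


def jaccard_matrix(matrix: SignalMatrix, classes: dict[str, str] | None = None
                   ) -> SimilarityMatrix:
    """Pairwise Jaccard similarity of the drugs' key-signal PT sets.

    J = 0 by convention when both sets are empty (a warning is emitted);
    J(A, A) = 1 for non-empty A.
    """
    sets = [matrix.signal_set(d) for d in matrix.drugs]
    n = len(sets)
    J = np.zeros((n, n))
    warned = False
    for i in range(n):
        for j in range(i, n):
            union = sets[i] | sets[j]
            if union:
                J[i, j] = J[j, i] = len(sets[i] & sets[j]) / len(union)
            else:
                if not warned:
                    warnings.warn(
                        "empty-union drug pair: Jaccard set to 0 by convention",
                        stacklevel=2)
                    warned = True
                J[i, j] = J[j, i] = 0.0
    return SimilarityMatrix(labels=list(matrix.drugs), values=J, classes=classes)


@dataclass
class NetworkBackbone:
    """Edges at or above a percentile threshold of pairwise similarity."""

    percentile: float
    threshold: float
    edges: list[tuple[str, str, float]]  # upper-triangle (i < j) pairs

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_set(self) -> frozenset[tuple[str, str]]:
        return frozenset((u, v) for u, v, _ in self.edges)

    def to_graph(self, classes: dict[str, str] | None = None, nodes=None):
        """networkx Graph with target-class node attributes; isolated drugs kept."""
        import networkx as nx

        g = nx.Graph()
        for node in (nodes or []):
            g.add_node(node, target_class=(classes or {}).get(node))
        for u, v, w in self.edges:
            g.add_edge(u, v, weight=w)
            for node in (u, v):
                g.nodes[node]["target_class"] = (classes or {}).get(node)
        return g


def backbone(sim: SimilarityMatrix, percentile: float = 80.0) -> NetworkBackbone:
    """Retain drug pairs with similarity >= the percentile threshold.

    The threshold is the linear-interpolation quantile of the n(n-1)/2
    off-diagonal similarities; ties at the threshold are retained, so the
    surviving fraction can exceed (100 - percentile)%.
    """
    if not (0.0 < percentile < 100.0):
        raise ValueError(f"percentile must be in (0, 100), got {percentile}")
    if sim.n < 2:
        raise ValueError("need at least 2 drugs")
    vals = sim.pair_values()
    threshold = float(np.percentile(vals, percentile))  # type-7 quantile
    edges = []
    for i in range(sim.n):
        for j in range(i + 1, sim.n):
            w = sim.values[i, j]
            if w >= threshold:
                edges.append((sim.labels[i], sim.labels[j], float(w)))
    return NetworkBackbone(percentile=percentile, threshold=threshold, edges=edges)


def cluster_order(sim: SimilarityMatrix) -> list[str]:
    """Heatmap leaf order: average-linkage clustering of D = 1 - J.

    Labels are pre-sorted so the ordering is invariant to the input row
    permutation (ties resolve by label).
    """
    if sim.n < 2:
        raise ValueError("need at least 2 drugs")
    order = np.argsort(np.asarray(sim.labels, dtype=object))
    labels = [sim.labels[i] for i in order]
    D = sim.dissimilarity[np.ix_(order, order)]
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    return [labels[i] for i in hierarchy.leaves_list(Z)]


@dataclass
class MdsEmbedding:
    """2-D principal coordinates plus the centered-matrix eigen spectrum."""

    labels: list[str]
    coords: np.ndarray  # (n, 2)
    eigenvalues: np.ndarray  # descending
    negative_mass_fraction: float


def mds_embed(sim: SimilarityMatrix) -> MdsEmbedding:
    """Classical (Torgerson) MDS of the Jaccard distance D = 1 - J.

    B = -1/2 C D^2 C with C the centering operator; coordinates come from
    the top-2 nonnegative eigenpairs (negative eigenvalues are clamped and
    their absolute mass fraction reported).  The axis sign is fixed by making
    the largest-magnitude coordinate on each axis positive, so the embedding
    is fully deterministic.
    """
    n = sim.n
    if n < 3:
        raise ValueError("need at least 3 drugs for a 2-D embedding")
    D = sim.dissimilarity
    C = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * C @ (D ** 2) @ C
    B = (B + B.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(B)
    idx = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[idx], eigvecs[:, idx]
    total = np.abs(eigvals).sum()
    neg_mass = float(np.clip(-eigvals, 0, None).sum() / total) if total > 0 else 0.0
    coords = np.zeros((n, 2))
    # eigenvalues within round-off of zero are pure null-space noise
    tiny = max(eigvals.max(), 0.0) * 1e-10
    for k in range(2):
        lam = eigvals[k] if eigvals[k] > tiny else 0.0
        coords[:, k] = eigvecs[:, k] * np.sqrt(lam)
        i_max = int(np.argmax(np.abs(coords[:, k])))
        if coords[i_max, k] < 0:
            coords[:, k] = -coords[:, k]
    return MdsEmbedding(labels=list(sim.labels), coords=coords,
                        eigenvalues=eigvals, negative_mass_fraction=neg_mass)
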