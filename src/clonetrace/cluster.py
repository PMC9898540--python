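"""Clone clustering on log2 abundance profiles.

Clones from all mice and both groups are pooled and described by their
log2-normalized abundance over the four cell types at the three analysis
time points (2.5, 5.5, 6.5 months; twelve features).  The profiles are
standardized, rotated by PCA, connected in a shared-nearest-neighbor (SNN)
graph and partitioned by modularity-based (Louvain) community detection —
the generic equivalent of the Seurat FindNeighbors/FindClusters workflow.
The 2-D UMAP embedding is for display only and never feeds the assignment.

Clusters are then categorized by reconstitution timing: *long-term* clusters
keep producing blood at 6.5 months, *short-term* clusters produce only at
2.5 months, and *middle-term* clusters produce at 5.5 months but at neither
reference point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .classify import BiasParameters
from .containers import ClonalAbundanceMatrix

logger = logging.getLogger(__name__)

#: Time points entering the feature matrix (month 3.5 is not analyzed).
DEFAULT_FEATURE_TIMEPOINTS = (2.5, 5.5, 6.5)
#: Pseudocount in %WBC added before log2, two decades below the detection floor.
DEFAULT_PSEUDOCOUNT = 1e-4
DEFAULT_K = 20
DEFAULT_RESOLUTION = 1.0
DEFAULT_SEED = 17

TERM_CATEGORIES = ("long_term", "middle_term", "short_term")
_TP_TO_TERM = {2.5: "short_term", 5.5: "middle_term", 6.5: "long_term"}


@dataclass
class FeatureMatrix:
    """Clone x 12 log2-abundance features, columns (cell_type, timepoint)."""

    features: pd.DataFrame
    groups: dict[str, str] = field(default_factory=dict)

    @property
    def clones(self) -> pd.MultiIndex:
        return self.features.index


@dataclass
class ClusterResult:
    """Cluster assignments (ids ordered by decreasing size), term categories
    and the display embedding."""

    assignments: pd.Series                      # clone -> cluster id
    term_category: dict[int, str]               # cluster id -> term category
    embedding: pd.DataFrame | None = None       # clone x (umap1, umap2)

    @property
    def n_clusters(self) -> int:
        return int(self.assignments.max()) + 1 if len(self.assignments) else 0

    def to_frame(self) -> pd.DataFrame:
        out = self.assignments.rename("cluster").to_frame().reset_index()
        out["term_category"] = out["cluster"].map(self.term_category)
        return out


def build_feature_matrix(
    matrix: ClonalAbundanceMatrix,
    timepoints: Sequence[float] = DEFAULT_FEATURE_TIMEPOINTS,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> FeatureMatrix:
    """log2(abundance + pseudocount) over the requested time points.

    Clones with zero abundance in every selected cell are dropped (count
    logged): an all-pseudocount row carries no information.
    """
    known = set(matrix.timepoints)
    unknown = [tp for tp in timepoints if tp not in known]
    if unknown:
        raise ValueError(f"unknown timepoint(s) {unknown}; matrix has {sorted(known)}")
    cols = [c for c in matrix.abundance.columns if c[1] in set(timepoints)]
    sub = matrix.abundance[cols]
    detected = (sub > 0).any(axis=1)
    n_dropped = int((~detected).sum())
    if n_dropped:
        logger.info("dropping %d clone(s) undetected at all selected cells", n_dropped)
    features = np.log2(sub.loc[detected] + pseudocount)
    return FeatureMatrix(features, dict(matrix.groups))


def run_pca(
    features: FeatureMatrix | pd.DataFrame,
    n_components: int = 12,
    scale: bool = True,
) -> pd.DataFrame:
    """Centered (and by default unit-variance) PCA scores.

    Scores are ordered by decreasing explained variance; each component's
    sign is fixed by making its largest-magnitude loading positive, so the
    decomposition is deterministic.
    """
    X = features.features if isinstance(features, FeatureMatrix) else features
    if len(X) < 2:
        raise ValueError("PCA requires at least 2 clones")
    n_components = min(n_components, X.shape[1], len(X))
    values = X.to_numpy(dtype=float)
    values = values - values.mean(axis=0)
    if scale:
        sd = values.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0  # constant feature: leave centered at zero
        values = values / sd
    pca = PCA(n_components=n_components, svd_solver="full", random_state=0)
    scores = pca.fit_transform(values)
    # deterministic sign convention
    flip = np.sign(pca.components_[np.arange(n_components), np.abs(pca.components_).argmax(axis=1)])
    flip[flip == 0] = 1.0
    scores = scores * flip
    return pd.DataFrame(scores, index=X.index, columns=[f"PC{i + 1}" for i in range(n_components)])


def knn_graph(scores: pd.DataFrame, k: int = DEFAULT_K) -> nx.Graph:
    """Shared-nearest-neighbor graph over clones.

    Nodes are clone positions 0..n-1 (clone ids kept as node attributes).
    i and j are connected when either lies in the other's k nearest
    (Euclidean) neighborhood; the edge weight is the Jaccard overlap of
    their neighborhoods, each taken to include the point itself (so
    coincident points share weight 1).  Zero-weight edges are removed.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    n = len(scores)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of clones ({n})")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(scores.to_numpy())
    _, idx = nn.kneighbors(scores.to_numpy())
    nearest = []       # k nearest neighbors of i, excluding i
    neighborhoods = []  # the same sets plus i itself, for SNN weights
    for i in range(n):
        # with duplicated points the query itself may not appear in its own
        # neighbor list; drop it if present and keep the k nearest
        row = [j for j in idx[i].tolist() if j != i][:k]
        nearest.append(row)
        neighborhoods.append(set(row) | {i})

    graph = nx.Graph()
    for i in range(n):
        graph.add_node(i, clone=tuple(scores.index[i]))
    for i in range(n):
        for j in nearest[i]:
            if graph.has_edge(i, j):
                continue
            inter = len(neighborhoods[i] & neighborhoods[j])
            union = len(neighborhoods[i] | neighborhoods[j])
            w = inter / union if union else 0.0
            if w > 0:
                graph.add_edge(i, j, weight=w)
    return graph


def cluster_graph(
    graph: nx.Graph, resolution: float = DEFAULT_RESOLUTION, seed: int = DEFAULT_SEED
) -> np.ndarray:
    """Louvain community detection; ids relabeled by decreasing community size.

    Isolated nodes become singleton clusters.  Ties in size are broken by the
    smallest member node so relabeling is deterministic.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    communities = nx.community.louvain_communities(
        graph, weight="weight", resolution=resolution, seed=seed
    )
    ordered = sorted(communities, key=lambda c: (-len(c), min(c)))
    assignment = np.empty(graph.number_of_nodes(), dtype=np.int64)
    for cluster_id, members in enumerate(ordered):
        for node in members:
            assignment[node] = cluster_id
    return assignment


def embed_2d(scores: pd.DataFrame, seed: int = DEFAULT_SEED, n_neighbors: int = 15) -> pd.DataFrame:
    """2-D UMAP embedding for plotting only; deterministic given the seed."""
    if len(scores) < 3:
        raise ValueError("embedding requires at least 3 clones")
    import umap  # deferred: numba compilation is expensive

    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=min(n_neighbors, len(scores) - 1),
        random_state=seed,
        n_jobs=1,
    )
    coords = reducer.fit_transform(scores.to_numpy())
    return pd.DataFrame(coords, index=scores.index, columns=["umap1", "umap2"])


def categorize_clusters(
    matrix: ClonalAbundanceMatrix,
    assignments: pd.Series,
    params: BiasParameters | None = None,
    timepoints: Sequence[float] = DEFAULT_FEATURE_TIMEPOINTS,
) -> dict[int, str]:
    """Term category per cluster from majority detection at each time point.

    Per cluster the fraction of member clones detected (any cell type at or
    above the floor) at each time point decides: detected at 6.5 months in
    the majority -> long_term; else majority at 2.5 -> short_term; else
    majority at 5.5 -> middle_term; otherwise the argmax time point decides.
    """
    params = params or BiasParameters()
    presence = matrix.abundance >= params.detect_floor
    detected_at = {
        tp: presence.xs(tp, level="timepoint", axis=1).any(axis=1).reindex(assignments.index)
        for tp in timepoints
    }
    categories: dict[int, str] = {}
    for cluster_id in sorted(assignments.unique()):
        members = assignments == cluster_id
        frac = {tp: float(detected_at[tp][members].mean()) for tp in timepoints}
        if frac.get(6.5, 0.0) >= 0.5:
            cat = "long_term"
        elif frac.get(2.5, 0.0) >= 0.5:
            cat = "short_term"
        elif frac.get(5.5, 0.0) >= 0.5:
            cat = "middle_term"
        else:
            argmax_tp = max(timepoints, key=lambda tp: (frac[tp], tp))
            cat = _TP_TO_TERM.get(argmax_tp, "long_term")
        categories[int(cluster_id)] = cat
    return categories


def run_clustering(
    matrix: ClonalAbundanceMatrix,
    k: int = DEFAULT_K,
    resolution: float = DEFAULT_RESOLUTION,
    seed: int = DEFAULT_SEED,
    n_components: int = 12,
    timepoints: Sequence[float] = DEFAULT_FEATURE_TIMEPOINTS,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    params: BiasParameters | None = None,
    embedding: bool = False,
) -> ClusterResult:
    """Full pipeline: features -> PCA -> SNN graph -> Louvain -> categories."""
    feats = build_feature_matrix(matrix, timepoints=timepoints, pseudocount=pseudocount)
    # canonical clone order: permuting the input permutes the output labels
    # without changing the partition
    feats.features = feats.features.sort_index()
    scores = run_pca(feats, n_components=n_components)
    k_eff = max(1, min(k, -(-len(scores) // 3), len(scores) - 1))  # cap at ceil(n/3), < n
    graph = knn_graph(scores, k=k_eff)
    labels = cluster_graph(graph, resolution=resolution, seed=seed)
    assignments = pd.Series(labels, index=scores.index, name="cluster")
    categories = categorize_clusters(matrix, assignments, params=params, timepoints=timepoints)
    coords = embed_2d(scores, seed=seed) if embedding else None
    return ClusterResult(assignments=assignments, term_category=categories, embedding=coords)
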