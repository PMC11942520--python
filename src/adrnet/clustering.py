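"""Patient-similarity network and modularity community detection.

Patients are nodes; edge weights are binary-profile similarities (Jaccard
by default) between their carrier sets.  Weak background edges are pruned
at a configurable threshold, and the remaining weighted graph is
partitioned by Louvain modularity maximization.  Partitions are
canonicalized (clusters numbered by decreasing size, ties broken by the
lexicographically smallest member) so runs are comparable across seeds.

A low modularity score is not an error here: strongly similar patients can
still split into meaningful groups, so the pipeline only warns below
``Q = 0.05`` and proceeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .cohort import GenotypeMatrix

__all__ = [
    "PatientGraph",
    "Clustering",
    "build_patient_graph",
    "modularity",
    "detect_communities",
    "stability_check",
    "canonicalize_labels",
]

METRICS = ("jaccard", "dice", "hamming_similarity")

#: Below this modularity the pipeline warns (but proceeds).
LOW_MODULARITY = 0.05

#: Default minimum retained edge weight.  Background similarity between
#: unrelated carrier profiles is weak but nonzero; pruning it keeps the
#: community structure visible to modularity optimization.
DEFAULT_EDGE_THRESHOLD = 0.2


@dataclass
class PatientGraph:
    graph: nx.Graph = field(repr=False)
    similarity_metric: str = "jaccard"
    edge_threshold: float = DEFAULT_EDGE_THRESHOLD

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    def edge_frame(self):
        import pandas as pd

        rows = [
            {"source": u, "target": v, "weight": d["weight"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "weight"])


@dataclass
class Clustering:
    """A canonical patient partition with its modularity score."""

    labels: dict
    q: float
    n_clusters: int
    seed: int = 0
    resolution: float = 1.0

    def members(self, cluster: int) -> list:
        return sorted(p for p, c in self.labels.items() if c == cluster)

    def sizes(self) -> list:
        return [len(self.members(c)) for c in range(self.n_clusters)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            sorted(self.labels.items()), columns=["patient_id", "cluster"]
        )

    def label_array(self, patient_ids) -> np.ndarray:
        return np.array([self.labels[p] for p in patient_ids])


def _pairwise_similarity(x: np.ndarray, metric: str) -> np.ndarray:
    x = (np.asarray(x) > 0).astype(float)
    inter = x @ x.T
    sizes = x.sum(axis=1)
    if metric == "jaccard":
        union = sizes[:, None] + sizes[None, :] - inter
        with np.errstate(invalid="ignore", divide="ignore"):
            sim = np.where(union > 0, inter / np.maximum(union, 1e-300), 0.0)
        if np.any((union == 0) & ~np.eye(len(x), dtype=bool)):
            warnings.warn(
                "two patients with empty carrier sets: jaccard similarity set to 0",
                stacklevel=3,
            )
    elif metric == "dice":
        denom = sizes[:, None] + sizes[None, :]
        sim = np.where(denom > 0, 2 * inter / np.maximum(denom, 1e-300), 0.0)
    elif metric == "hamming_similarity":
        n_var = x.shape[1]
        mismatches = sizes[:, None] + sizes[None, :] - 2 * inter
        sim = (n_var - mismatches) / n_var
    else:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    return sim


def build_patient_graph(
    matrix: GenotypeMatrix,
    metric: str = "jaccard",
    edge_threshold: float = DEFAULT_EDGE_THRESHOLD,
) -> PatientGraph:
    """Weighted similarity graph over patients; edges below threshold dropped.

    Isolated nodes are retained.  Node order is the sorted patient id, which
    together with a seeded community search makes detection deterministic.
    """
    ids = matrix.patient_ids
    if len(ids) < 2:
        raise ValueError("need at least two patients")
    if matrix.carrier.shape[1] < 1:
        raise ValueError("need at least one variant column")
    sim = _pairwise_similarity(matrix.carrier, metric)
    order = sorted(range(len(ids)), key=lambda i: ids[i])
    g = nx.Graph()
    g.add_nodes_from(ids[i] for i in order)
    for a in range(len(order)):
        for b in range(a + 1, len(order)):
            i, j = order[a], order[b]
            w = float(sim[i, j])
            if w > 0 and w >= edge_threshold:
                g.add_edge(ids[i], ids[j], weight=w)
    return PatientGraph(graph=g, similarity_metric=metric, edge_threshold=edge_threshold)


def _as_graph(graph) -> nx.Graph:
    return graph.graph if isinstance(graph, PatientGraph) else graph


def modularity(graph, labels: dict) -> float:
    """Weighted Newman-Girvan modularity of a labeled partition.

    ``Q = sum_c (e_cc - a_c^2)`` over clusters, with ``e_cc`` the fraction
    of edge weight inside cluster c and ``a_c`` the fraction of endpoint
    weight attached to c.
    """
    g = _as_graph(graph)
    total = g.size(weight="weight")
    if total <= 0:
        raise ValueError("graph has zero total edge weight")
    missing = [n for n in g.nodes if n not in labels]
    if missing:
        raise ValueError(f"labels missing for node(s): {missing}")
    groups: dict[int, set] = {}
    for node, c in labels.items():
        groups.setdefault(c, set()).add(node)
    communities = [m for m in groups.values() if m]
    return float(nx.community.modularity(g, communities, weight="weight"))


def canonicalize_labels(communities) -> tuple[dict, int]:
    """Number clusters by decreasing size, then smallest member id."""
    comms = sorted((sorted(c) for c in communities if c), key=lambda c: (-len(c), c[0]))
    labels = {}
    for idx, members in enumerate(comms):
        for m in members:
            labels[m] = idx
    return labels, len(comms)


def detect_communities(
    graph, seed: int = 0, resolution: float = 1.0
) -> Clustering:
    """Louvain-style greedy modularity partition, canonicalized and seeded.

    Degenerate edgeless graphs yield the singleton partition with Q = 0.
    If the search somehow lands below the trivial single-cluster score the
    one-cluster partition (Q = 0) is returned instead, so the detected
    modularity is never negative.
    """
    pg = graph if isinstance(graph, PatientGraph) else None
    g = _as_graph(graph)
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if g.number_of_edges() == 0 or g.size(weight="weight") <= 0:
        labels, k = canonicalize_labels([{n} for n in g.nodes])
        return Clustering(labels=labels, q=0.0, n_clusters=k, seed=seed, resolution=resolution)
    comms = nx.community.louvain_communities(
        g, weight="weight", resolution=resolution, seed=seed
    )
    q = float(nx.community.modularity(g, comms, weight="weight"))
    if q < 0:
        comms = [set(g.nodes)]
        q = 0.0
    labels, k = canonicalize_labels(comms)
    if q < LOW_MODULARITY:
        warnings.warn(
            f"low modularity Q={q:.3f} (< {LOW_MODULARITY}): clusters reflect weak "
            "structure over strong overall patient similarity",
            stacklevel=2,
        )
    if pg is not None:
        pass  # reserved for future per-graph metadata
    return Clustering(labels=labels, q=q, n_clusters=k, seed=seed, resolution=resolution)


def stability_check(graph, seeds, resolution: float = 1.0) -> tuple[bool, list]:
    """Re-run detection across seeds; stable iff all canonical partitions agree."""
    seeds = list(seeds)
    if len(seeds) < 2:
        raise ValueError("need at least two runs")
    runs = [detect_communities(graph, seed=s, resolution=resolution) for s in seeds]
    first = runs[0].labels
    stable = all(r.labels == first for r in runs[1:])
    return stable, runs
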