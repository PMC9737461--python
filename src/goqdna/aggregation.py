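"""GOQD self-aggregation statistics.

Two flakes belong to the same cluster when their minimum heavy-atom distance
falls below a linkage cutoff (default 0.35 nm, a van der Waals / stacking
contact distance); clusters are the connected components of the resulting
flake graph.  Hydrogens are ignored for linkage since their positions are
builder-idealized.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from ._errors import SelectionError
from .interaction_metrics import MetricSeries
from .model_core import Selection, Structure, Trajectory

__all__ = ["CLUSTER_CUTOFF_NM", "ClusterResult", "find_clusters", "cluster_timeseries"]

CLUSTER_CUTOFF_NM = 0.35


@dataclass(frozen=True)
class ClusterResult:
    n_clusters: int
    max_cluster_size: int
    membership: dict  # GOQD index -> cluster id (ids keyed by lowest member)


def _heavy_positions(frame: Structure, group: Selection) -> np.ndarray:
    idx = [i for i in group.indices if frame.elements[i] != "H"]
    return frame.positions[idx]


def find_clusters(
    frame: Structure,
    goqd_groups,
    cutoff: float = CLUSTER_CUTOFF_NM,
) -> ClusterResult:
    """Connected-component clustering of GOQD groups in one frame."""
    n = len(goqd_groups)
    if n < 1:
        raise SelectionError("at least one GOQD group is required")
    for i in range(n):
        for j in range(i + 1, n):
            if goqd_groups[i].intersects(goqd_groups[j]):
                raise SelectionError(f"GOQD groups {i} and {j} overlap")
    heavies = [_heavy_positions(frame, g) for g in goqd_groups]
    trees = [cKDTree(h) for h in heavies]
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            # cheap reject on centroid distance before the exact pair query
            ci = heavies[i].mean(axis=0)
            cj = heavies[j].mean(axis=0)
            reach_i = np.linalg.norm(heavies[i] - ci, axis=1).max()
            reach_j = np.linalg.norm(heavies[j] - cj, axis=1).max()
            if np.linalg.norm(ci - cj) > reach_i + reach_j + cutoff:
                continue
            if trees[i].count_neighbors(trees[j], cutoff * (1 - 1e-12)) > 0:
                graph.add_edge(i, j)
    membership = {}
    sizes = []
    for comp in nx.connected_components(graph):
        cid = min(comp)  # deterministic id: lowest member index
        sizes.append(len(comp))
        for member in comp:
            membership[member] = cid
    return ClusterResult(
        n_clusters=len(sizes),
        max_cluster_size=max(sizes),
        membership=membership,
    )


def cluster_timeseries(
    traj: Trajectory,
    goqd_groups,
    cutoff: float = CLUSTER_CUTOFF_NM,
) -> tuple[MetricSeries, MetricSeries]:
    """Per-frame (n_clusters, max_cluster_size) series over a trajectory."""
    n_clusters = []
    max_sizes = []
    for frame in traj:
        res = find_clusters(frame, goqd_groups, cutoff)
        n_clusters.append(res.n_clusters)
        max_sizes.append(res.max_cluster_size)
    return (
        MetricSeries("n_clusters", traj.times, n_clusters, units="clusters"),
        MetricSeries("max_cluster_size", traj.times, max_sizes, units="flakes"),
    )
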