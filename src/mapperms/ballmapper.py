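"""Ball Mapper: greedy ε-net cover graphs of high-dimensional point clouds.

Landmarks are chosen greedily in a stated order: the first point not yet
covered becomes a landmark and every point strictly within ε of it is
marked covered.  The resulting ε-net covers the data with open Euclidean
balls (every point lies in at least one) while keeping landmarks pairwise
farther than ε apart.  Nodes of the Ball Mapper graph are the ball
memberships; an edge joins two nodes whenever at least one point lies in
both balls, encoding continuity between localized clusters.

The net — hence the graph — is order-dependent, not uniquely determined by
the point cloud; downstream ensemble methods exploit this by building many
nets from randomized orderings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "BallCover",
    "BallMapperGraph",
    "greedy_epsilon_net",
    "build_graph",
    "color_by_total_intensity",
    "color_by_label_proportion",
    "resolve_ordering",
]

_CHUNK = 8_388_608  # float64 budget per distance block (~64 MB)


def resolve_ordering(
    n: int, ordering: np.ndarray | int | None
) -> np.ndarray:
    """Turn an ordering spec into a permutation of range(n).

    ``None`` keeps the native data order; an int seeds a uniform random
    permutation; an explicit permutation array is validated and used as-is.
    """
    if ordering is None:
        return np.arange(n)
    if isinstance(ordering, (int, np.integer)):
        return np.random.default_rng(int(ordering)).permutation(n)
    perm = np.asarray(ordering, dtype=int)
    if sorted(perm.tolist()) != list(range(n)):
        raise ValueError("ordering must be a permutation of range(n)")
    return perm


@dataclass
class BallCover:
    """Greedy ε-net over a point set.

    ``landmark_indices`` are point indices in discovery order;
    ``membership[j]`` is the sorted array of point indices in the open ball
    of radius ``epsilon`` around landmark j (the landmark always belongs to
    its own ball).
    """

    epsilon: float
    landmark_indices: np.ndarray
    membership: list[np.ndarray]
    n_points: int

    @property
    def n_landmarks(self) -> int:
        return int(self.landmark_indices.size)

    def validate(self, points: np.ndarray) -> None:
        """Assert coverage (every point in ≥1 ball) and landmark separation."""
        covered = np.zeros(self.n_points, dtype=bool)
        for mem in self.membership:
            covered[mem] = True
        if not covered.all():
            raise AssertionError("cover violates coverage: uncovered points exist")
        L = points[self.landmark_indices]
        if len(L) > 1:
            from scipy.spatial.distance import pdist

            if pdist(L).min() <= self.epsilon:
                raise AssertionError("cover violates separation: landmarks within ε")


def _chunked_dist_lt(points: np.ndarray, center: np.ndarray, eps: float) -> np.ndarray:
    """Boolean mask of points strictly within eps of center, chunked."""
    n, d = points.shape
    step = max(1, _CHUNK // max(d, 1))
    out = np.empty(n, dtype=bool)
    for s in range(0, n, step):
        blk = points[s : s + step] - center
        out[s : s + step] = np.einsum("ij,ij->i", blk, blk) < eps * eps
    return out


def greedy_epsilon_net(
    points: np.ndarray,
    epsilon: float,
    ordering: np.ndarray | int | None = None,
) -> BallCover:
    """Build a greedy ε-net in the Euclidean metric.

    Iterates over the points in the given order; each first-uncovered point
    becomes a landmark and covers all points strictly within ε.  The result
    is deterministic given the ordering; different orderings may yield
    different nets.

    Membership recorded here is the full open-ball membership
    (``points ∩ B_ε(landmark)``), not just the points first covered by the
    landmark — a point may belong to several balls.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] == 0:
        raise ValueError("points must be a non-empty (n, d) array")
    if not epsilon > 0:
        raise ValueError("epsilon must be positive")
    n = points.shape[0]
    perm = resolve_ordering(n, ordering)
    covered = np.zeros(n, dtype=bool)
    landmarks: list[int] = []
    membership: list[np.ndarray] = []
    for idx in perm:
        if covered[idx]:
            continue
        mask = _chunked_dist_lt(points, points[idx], epsilon)
        covered |= mask
        covered[idx] = True  # guard: distance-0 to itself is < ε already
        landmarks.append(int(idx))
        membership.append(np.flatnonzero(mask))
    return BallCover(
        epsilon=float(epsilon),
        landmark_indices=np.array(landmarks, dtype=int),
        membership=membership,
        n_points=n,
    )


@dataclass
class BallMapperGraph:
    """Cover graph: one node per landmark ball, edges on shared points."""

    cover: BallCover
    edges: list[tuple[int, int]]
    node_attributes: dict[str, dict[int, object]] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.cover.n_landmarks

    def node_size(self, j: int) -> int:
        return int(self.cover.membership[j].size)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for j, lm in enumerate(self.cover.landmark_indices):
            attrs = {
                name: vals[j] for name, vals in self.node_attributes.items()
            }
            g.add_node(j, landmark_index=int(lm), size=self.node_size(j), **attrs)
        g.add_edges_from(self.edges)
        return g

    def to_json(self, include_members: bool = True) -> str:
        nodes = []
        for j, lm in enumerate(self.cover.landmark_indices):
            node: dict[str, object] = {
                "id": j,
                "landmark_index": int(lm),
                "size": self.node_size(j),
                "colors": {
                    name: vals[j] for name, vals in self.node_attributes.items()
                },
            }
            if include_members:
                node["members"] = self.cover.membership[j].tolist()
            nodes.append(node)
        return json.dumps(
            {
                "epsilon": self.cover.epsilon,
                "nodes": nodes,
                "edges": [[int(i), int(j)] for i, j in self.edges],
            }
        )

    def write_graphml(self, path) -> None:
        g = self.to_networkx()
        # GraphML cannot hold dict attributes; flatten proportion maps
        for _, data in g.nodes(data=True):
            for key in list(data):
                if isinstance(data[key], dict):
                    sub = data.pop(key)
                    for cat, val in sub.items():
                        data[f"{key}:{cat}"] = float(val)
        nx.write_graphml(g, path)


def build_graph(points: np.ndarray, cover: BallCover) -> BallMapperGraph:
    """Assemble the Ball Mapper graph from a cover.

    An edge joins landmarks i and j iff some point lies in both open balls.
    """
    points = np.asarray(points, dtype=float)
    L = cover.n_landmarks
    # boolean membership matrix (L x n); edge iff row intersection non-empty
    memb = np.zeros((L, cover.n_points), dtype=bool)
    for j, mem in enumerate(cover.membership):
        memb[j, mem] = True
    edges: list[tuple[int, int]] = []
    inter = memb.astype(np.uint8) @ memb.astype(np.uint8).T
    ii, jj = np.nonzero(np.triu(inter, k=1))
    edges = [(int(a), int(b)) for a, b in zip(ii, jj)]
    return BallMapperGraph(cover=cover, edges=edges)


def color_by_total_intensity(
    graph: BallMapperGraph, points: np.ndarray, name: str = "total_intensity"
) -> dict[int, float]:
    """Color each node by the mean component-sum of its member vectors.

    For unit-norm spectra the component sum tracks how spread-out a
    spectrum is over m/z bins; averaging over a ball summarizes the local
    spectral texture.
    """
    points = np.asarray(points, dtype=float)
    sums = points.sum(axis=1)
    colors = {
        j: float(sums[mem].mean()) for j, mem in enumerate(graph.cover.membership)
    }
    graph.node_attributes[name] = colors
    return colors


def color_by_label_proportion(
    graph: BallMapperGraph, labels, name: str = "label_proportion"
) -> dict[int, dict[str, float]]:
    """Per-node proportion of member points carrying each category label.

    A node is "fully" one category if every member point carries it and 0
    if none does; proportions over categories sum to 1 per node.  Raises if
    any member point is unlabeled.
    """
    if not hasattr(labels, "get"):
        labels = dict(enumerate(labels))
    colors: dict[int, dict[str, float]] = {}
    for j, mem in enumerate(graph.cover.membership):
        counts: dict[str, int] = {}
        for p in mem:
            lab = labels.get(int(p))
            if lab is None:
                raise ValueError(f"point {p} has no label")
            counts[str(lab)] = counts.get(str(lab), 0) + 1
        total = mem.size
        colors[j] = {c: cnt / total for c, cnt in sorted(counts.items())}
    graph.node_attributes[name] = colors
    return colors
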