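"""Fiber polylines, the beam-segment graph, and architecture metrics.

A fiber is a polyline with a per-point radius. A :class:`FiberNetwork` is
the shared-node graph obtained by merging nearby polyline points and turning
consecutive points into 2-node segments; connectivity metrics (cluster count,
maximum cluster size) are defined on this graph at the fiber level, while
orientation metrics use the end-to-end chord of each polyline.

All coordinates are micrometres; Y is the skin surface normal.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .domain import DomainSpec

DEFAULT_MERGE_TOLERANCE = 0.5  # um
VERTICAL_ANGLE_DEG = 45.0


@dataclass
class FiberPolyline:
    """Ordered 3D point chain with per-point radii (um)."""

    points: np.ndarray  # (n, 3)
    radii: np.ndarray  # (n,)
    fiber_id: int = 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be (n, 3)")
        if self.points.shape[0] < 2:
            raise ValueError("a fiber polyline needs at least 2 points")
        if self.radii.shape != (self.points.shape[0],):
            raise ValueError("radii must match points")
        if np.any(self.radii <= 0):
            raise ValueError("radii must be positive")
        seg = np.diff(self.points, axis=0)
        if np.any(np.linalg.norm(seg, axis=1) == 0.0):
            raise ValueError("consecutive polyline points must be distinct")

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @property
    def chord(self) -> np.ndarray:
        """End-to-end vector (first point to last point)."""
        return self.points[-1] - self.points[0]

    @property
    def mean_diameter(self) -> float:
        return float(2.0 * self.radii.mean())

    def angle_to_y_deg(self) -> float:
        """Angle of the chord to the Y axis, folded into [0, 90] degrees."""
        v = self.chord
        n = np.linalg.norm(v)
        if n == 0.0:
            return 90.0
        c = abs(v[1]) / n
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    def cylinder_volume(self) -> float:
        """Volume of the per-segment cylinders (um^3)."""
        lens = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        rads = 0.5 * (self.radii[:-1] + self.radii[1:])
        return float(np.sum(np.pi * rads**2 * lens))


@dataclass
class FiberNetwork:
    """Shared-node beam-segment graph built from fiber polylines."""

    fibers: list[FiberPolyline]
    merge_tolerance: float
    nodes: np.ndarray  # (M, 3)
    segments: np.ndarray  # (K, 2) int node indices
    segment_diameters: np.ndarray  # (K,)
    segment_fiber: np.ndarray  # (K,) index into fibers
    fiber_nodes: list[np.ndarray] = field(default_factory=list)

    @property
    def n_fibers(self) -> int:
        return len(self.fibers)

    @property
    def n_nodes(self) -> int:
        return int(self.nodes.shape[0])

    @property
    def n_segments(self) -> int:
        return int(self.segments.shape[0])

    def segment_lengths(self) -> np.ndarray:
        if self.n_segments == 0:
            return np.zeros(0)
        d = self.nodes[self.segments[:, 1]] - self.nodes[self.segments[:, 0]]
        return np.linalg.norm(d, axis=1)

    def total_fiber_volume(self) -> float:
        """Sum of polyline cylinder volumes (um^3)."""
        return float(sum(f.cylinder_volume() for f in self.fibers))


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = np.arange(n)

    def find(self, i: int) -> int:
        p = self.parent
        root = i
        while p[root] != root:
            root = p[root]
        while p[i] != root:
            p[i], i = root, p[i]
        return root

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        # attach larger index under smaller for order stability
        if ra < rb:
            self.parent[rb] = ra
        else:
            self.parent[ra] = rb
        return True


def build_network(
    fibers: list[FiberPolyline],
    merge_tolerance: float = DEFAULT_MERGE_TOLERANCE,
) -> FiberNetwork:
    """Merge polyline points within ``merge_tolerance`` (single linkage) into a
    shared node table and discretize each fiber into 2-node segments.

    Merging is single-linkage: points chained by pairwise distances at or
    below the tolerance collapse into one node, whose coordinates are those
    of the lowest-index member (deterministic, order-stable). Segments whose
    two endpoints collapse to the same node are dropped.
    """
    if merge_tolerance < 0:
        raise ValueError("merge_tolerance must be non-negative")
    fibers = list(fibers)
    if not fibers:
        return FiberNetwork(
            fibers=[],
            merge_tolerance=merge_tolerance,
            nodes=np.zeros((0, 3)),
            segments=np.zeros((0, 2), dtype=int),
            segment_diameters=np.zeros(0),
            segment_fiber=np.zeros(0, dtype=int),
            fiber_nodes=[],
        )

    pts = np.concatenate([f.points for f in fibers], axis=0)
    counts = [f.n_points for f in fibers]
    offsets = np.concatenate([[0], np.cumsum(counts)])

    uf = _UnionFind(pts.shape[0])
    if merge_tolerance > 0 and pts.shape[0] > 1:
        from scipy.spatial import cKDTree

        tree = cKDTree(pts)
        for a, b in sorted(tree.query_pairs(r=merge_tolerance)):
            uf.union(a, b)
    roots = np.array([uf.find(i) for i in range(pts.shape[0])])
    uniq, node_of_point = np.unique(roots, return_inverse=True)
    nodes = pts[uniq]

    seg_list: list[tuple[int, int]] = []
    seg_diam: list[float] = []
    seg_fib: list[int] = []
    fiber_nodes: list[np.ndarray] = []
    for fi, f in enumerate(fibers):
        ids = node_of_point[offsets[fi] : offsets[fi + 1]]
        fiber_nodes.append(np.unique(ids))
        for j in range(len(ids) - 1):
            a, b = int(ids[j]), int(ids[j + 1])
            if a == b:
                continue
            seg_list.append((a, b))
            seg_diam.append(float(f.radii[j] + f.radii[j + 1]))
            seg_fib.append(fi)

    return FiberNetwork(
        fibers=fibers,
        merge_tolerance=merge_tolerance,
        nodes=nodes,
        segments=np.array(seg_list, dtype=int).reshape(-1, 2),
        segment_diameters=np.array(seg_diam),
        segment_fiber=np.array(seg_fib, dtype=int),
        fiber_nodes=fiber_nodes,
    )


def _node_components_bfs(net: FiberNetwork) -> np.ndarray:
    """Connected components over nodes via breadth-first search."""
    n = net.n_nodes
    adj: list[list[int]] = [[] for _ in range(n)]
    for a, b in net.segments:
        adj[a].append(int(b))
        adj[b].append(int(a))
    comp = np.full(n, -1, dtype=int)
    cur = 0
    for start in range(n):
        if comp[start] != -1:
            continue
        comp[start] = cur
        q = deque([start])
        while q:
            u = q.popleft()
            for v in adj[u]:
                if comp[v] == -1:
                    comp[v] = cur
                    q.append(v)
        cur += 1
    return comp


def count_clusters(net: FiberNetwork) -> tuple[int, np.ndarray]:
    """Number of fiber clusters (connected components, via BFS) and the
    per-fiber cluster labels.

    A cluster is a maximal set of fibers mutually reachable through shared
    nodes. Labels are compacted to 0..n_clusters-1 in order of appearance.
    """
    if net.n_fibers == 0:
        return 0, np.zeros(0, dtype=int)
    comp = _node_components_bfs(net)
    raw = np.array([comp[fn[0]] for fn in net.fiber_nodes])
    _, labels = np.unique(raw, return_inverse=True)
    return int(labels.max()) + 1, labels


def max_cluster_size(net: FiberNetwork) -> int:
    """Fiber count of the largest connected component (0 for empty networks)."""
    n, labels = count_clusters(net)
    if n == 0:
        return 0
    return int(np.bincount(labels).max())


def fiber_angles_to_y_deg(net: FiberNetwork) -> np.ndarray:
    return np.array([f.angle_to_y_deg() for f in net.fibers])


def vertical_proportion(
    net: FiberNetwork, angle_threshold_deg: float = VERTICAL_ANGLE_DEG
) -> float:
    """Percentage of fibers whose chord makes an angle strictly below the
    threshold with the Y axis. A fiber at exactly the threshold counts as
    horizontal.
    """
    if net.n_fibers == 0:
        raise ValueError("vertical proportion undefined for an empty network")
    ang = fiber_angles_to_y_deg(net)
    return float(100.0 * np.mean(ang < angle_threshold_deg))


def volume_fraction(net: FiberNetwork, domain: DomainSpec) -> float:
    """Total segment-cylinder volume over domain volume, in percent."""
    vol = domain.volume
    if vol <= 0:
        raise ValueError("domain volume must be positive")
    if net.n_segments == 0:
        return 0.0
    lens = net.segment_lengths()
    v = np.sum(np.pi * net.segment_diameters**2 / 4.0 * lens)
    return float(100.0 * v / vol)


def diameter_stats(net: FiberNetwork) -> tuple[float, float, float]:
    """(mean, min, max) of the per-fiber mean diameters, in um."""
    if net.n_fibers == 0:
        raise ValueError("diameter stats undefined for an empty network")
    d = np.array([f.mean_diameter for f in net.fibers])
    return float(d.mean()), float(d.min()), float(d.max())


def horizontal_orientation_histogram(
    net: FiberNetwork, n_bins: int = 18
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of fiber chord azimuths in the horizontal X-Z plane.

    Angles are atan2(z, x) of the chord folded into [0, 180) degrees.
    Fibers with a (numerically) zero X-Z projection are excluded. Returns
    (counts, bin_edges_deg).
    """
    angles = []
    for f in net.fibers:
        v = f.chord
        proj = np.hypot(v[0], v[2])
        if proj <= 1e-12 * max(1.0, np.linalg.norm(v)):
            continue
        a = np.degrees(np.arctan2(v[2], v[0])) % 180.0
        angles.append(a)
    counts, edges = np.histogram(np.array(angles), bins=n_bins, range=(0.0, 180.0))
    return counts, edges


def split_diameters_by_orientation(
    net: FiberNetwork, angle_threshold_deg: float = VERTICAL_ANGLE_DEG
) -> tuple[np.ndarray, np.ndarray]:
    """Per-fiber mean diameters partitioned into (vertical, horizontal) groups.

    Vertical means chord angle strictly below the threshold; the partition
    is exhaustive and exclusive.
    """
    ang = fiber_angles_to_y_deg(net)
    d = np.array([f.mean_diameter for f in net.fibers])
    mask = ang < angle_threshold_deg
    return d[mask], d[~mask]


@dataclass(frozen=True)
class ArchitectureMetrics:
    """The six per-sample architecture descriptors."""

    mean_fiber_diameter: float  # um
    fiber_count: int
    volume_fraction: float  # percent
    n_clusters: int
    max_cluster_size: int  # fibers in the largest cluster
    vertical_proportion: float  # percent

    def as_dict(self) -> dict:
        return {
            "Mean Fiber Diameter (um)": self.mean_fiber_diameter,
            "Fiber Count": self.fiber_count,
            "Elastin Volume Fraction (%)": self.volume_fraction,
            "Number of Fiber Clusters": self.n_clusters,
            "Maximum Cluster Size": self.max_cluster_size,
            "Vertical Fiber Proportion (%)": self.vertical_proportion,
        }


def architecture_metrics(net: FiberNetwork, domain: DomainSpec) -> ArchitectureMetrics:
    """Compute all six architecture metrics for a network in a domain."""
    n_clu, labels = count_clusters(net)
    max_size = int(np.bincount(labels).max()) if n_clu else 0
    mean_d = diameter_stats(net)[0] if net.n_fibers else 0.0
    vert = vertical_proportion(net) if net.n_fibers else 0.0
    return ArchitectureMetrics(
        mean_fiber_diameter=mean_d,
        fiber_count=net.n_fibers,
        volume_fraction=volume_fraction(net, domain),
        n_clusters=n_clu,
        max_cluster_size=max_size,
        vertical_proportion=vert,
    )
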