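"""Segmentation pipeline: 3D stacks -> binary mask -> fiber centerlines.

Volumes are stored with array axes ordered (x, y, z), Y being the skin
surface normal; voxel centers sit at ``origin + (index + 0.5) * spacing``.
The stage mirrors a standard confocal fiber-segmentation chain: median
denoising, intensity thresholding, morphological opening/closing with a
quasi-spherical structuring element, volume-domain surface smoothing,
topological thinning into centerlines, and local diameter estimation from
the Euclidean distance transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .fibers import FiberPolyline

#: Structuring-element reading of a "3x3x3 spherical" kernel: center plus
#: face and edge neighbors (18-connected ball); the 8 cube corners are
#: excluded as they would make the element cubic.
SE_RADIUS_DEFAULT = 1


@dataclass
class VoxelVolume:
    """3D grayscale volume with physical voxel spacing (um/voxel)."""

    data: np.ndarray  # (nx, ny, nz)
    spacing: np.ndarray  # (3,)
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = np.broadcast_to(np.asarray(self.spacing, dtype=float), (3,)).copy()
        self.origin = np.asarray(self.origin, dtype=float)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("volume must be a non-empty 3D array")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class BinaryMask:
    """Boolean volume on the same grid as its source."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.spacing = np.broadcast_to(np.asarray(self.spacing, dtype=float), (3,)).copy()
        self.origin = np.asarray(self.origin, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def volume_fraction(self) -> float:
        return float(self.data.mean())


@dataclass
class ImageProcConfig:
    median_kernel: int = 3
    threshold: float | str = "auto"
    se_radius_voxels: int = SE_RADIUS_DEFAULT
    smoothing_iterations: int = 2
    smoothing_factor: float = 0.5
    min_branch_length: float = 1.5  # um; spur-pruning scale for skeletons
    junction_max_turn_deg: float = 60.0  # max bend for continuing through a junction
    tangent_window_um: float = 2.0  # arc length used to estimate branch tangents
    centerline_step_um: float = 1.0  # arc-length resampling step of traced fibers


def median_filter_3d(vol: VoxelVolume, kernel: int = 3) -> VoxelVolume:
    """3D median filter with an odd cubic kernel; edges handled by reflection."""
    if kernel % 2 != 1 or kernel < 1:
        raise ValueError("median kernel must be odd and >= 1")
    out = ndimage.median_filter(vol.data, size=kernel, mode="reflect")
    return VoxelVolume(out, vol.spacing.copy(), vol.origin.copy())


def threshold_segment(vol: VoxelVolume, threshold: float | str = "auto") -> BinaryMask:
    """Single-intensity segmentation: mask = intensity >= threshold.

    ``"auto"`` selects the threshold by Otsu's method on the volume
    histogram, standing in for an interactive per-stack choice; a numeric
    value overrides it.
    """
    if vol.data.size == 0:
        raise ValueError("empty volume")
    if isinstance(threshold, str):
        if threshold != "auto":
            raise ValueError(f"unknown threshold mode {threshold!r}")
        from skimage.filters import threshold_otsu

        thr = float(threshold_otsu(vol.data))
    else:
        thr = float(threshold)
    return BinaryMask(vol.data >= thr, vol.spacing.copy(), vol.origin.copy())


def spherical_structuring_element(radius: int) -> np.ndarray:
    """Quasi-spherical binary structuring element.

    Includes offsets with squared distance <= r^2 + r, which for radius 1
    yields the 18-connected ball (center + face + edge neighbors, corners
    excluded).
    """
    if radius < 1:
        raise ValueError("structuring-element radius must be >= 1")
    r = int(radius)
    ax = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    return (dx**2 + dy**2 + dz**2) <= r * r + r


def morphological_open(mask: BinaryMask, se_radius: int = SE_RADIUS_DEFAULT) -> BinaryMask:
    """Erosion followed by dilation (removes small isolated particles).

    Anti-extensive: the output is a subset of the input.
    """
    se = spherical_structuring_element(se_radius)
    er = ndimage.binary_erosion(mask.data, structure=se, border_value=0)
    out = ndimage.binary_dilation(er, structure=se, border_value=0)
    return BinaryMask(out, mask.spacing.copy(), mask.origin.copy())


def morphological_close(mask: BinaryMask, se_radius: int = SE_RADIUS_DEFAULT) -> BinaryMask:
    """Dilation followed by erosion (bridges small gaps).

    Extensive: the output is a superset of the input; outside the image the
    background is treated as empty for the dilation and as full for the
    erosion, which preserves extensivity at the borders.
    """
    se = spherical_structuring_element(se_radius)
    di = ndimage.binary_dilation(mask.data, structure=se, border_value=0)
    out = ndimage.binary_erosion(di, structure=se, border_value=1)
    return BinaryMask(out, mask.spacing.copy(), mask.origin.copy())


def smooth_binary_surface(
    mask: BinaryMask, iterations: int = 2, factor: float = 0.5
) -> BinaryMask:
    """Volume-domain surface smoothing.

    The 0/1 field is repeatedly blended with its local 3x3x3 mean
    (``f <- (1 - factor) f + factor mean(f)``) and re-thresholded at 0.5.
    This reduces voxel stair-step artifacts with the same effect on
    centerlines and diameter estimates as mesh-surface smoothing, while
    staying in the volume domain consumed by the rest of the pipeline.
    """
    if not (0.0 < factor <= 1.0):
        raise ValueError("smoothing factor must be in (0, 1]")
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0:
        return BinaryMask(mask.data.copy(), mask.spacing.copy(), mask.origin.copy())
    f = mask.data.astype(np.float32)
    for _ in range(iterations):
        m = ndimage.uniform_filter(f, size=3, mode="nearest")
        f = (1.0 - factor) * f + factor * m
    return BinaryMask(f >= 0.5, mask.spacing.copy(), mask.origin.copy())


# ---------------------------------------------------------------------------
# Skeleton tracing
# ---------------------------------------------------------------------------

_OFFSETS = np.array(
    [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ],
    dtype=int,
)


def _skeleton_graph(skel: np.ndarray):
    """Voxel adjacency (26-connectivity) of a skeleton as index dicts."""
    coords = np.argwhere(skel)
    index = {tuple(c): i for i, c in enumerate(coords)}
    nbrs: list[list[int]] = [[] for _ in range(len(coords))]
    for i, c in enumerate(coords):
        for off in _OFFSETS:
            t = (c[0] + off[0], c[1] + off[1], c[2] + off[2])
            j = index.get(t)
            if j is not None:
                nbrs[i].append(j)
    return coords, nbrs


def _remove_triangle_chords(phys: np.ndarray, nbrs: list[list[int]]) -> None:
    """Drop the longest edge of every 26-connectivity triangle, in place.

    Diagonal steps in a unit-width skeleton create triangles (two consecutive
    voxels plus their common neighbor) whose chord edges inflate voxel degrees
    and fake junctions. Removing the longest edge of a triangle keeps the
    graph connected through the remaining two; edges are removed longest
    first and only while they still close a triangle of surviving edges.
    """
    candidates: list[tuple[float, int, int]] = []
    for i in range(len(phys)):
        si = set(nbrs[i])
        for j in nbrs[i]:
            if j <= i:
                continue
            if si & set(nbrs[j]):
                candidates.append((float(np.linalg.norm(phys[i] - phys[j])), i, j))
    candidates.sort(reverse=True)
    for d, i, j in candidates:
        if j not in nbrs[i]:
            continue
        common = set(nbrs[i]) & set(nbrs[j])
        # remove only if still the (weakly) longest edge of some triangle
        for k in common:
            dik = np.linalg.norm(phys[i] - phys[k])
            djk = np.linalg.norm(phys[j] - phys[k])
            if d >= dik - 1e-12 and d >= djk - 1e-12:
                nbrs[i].remove(j)
                nbrs[j].remove(i)
                break


def _prune_spurs_graph(
    phys: np.ndarray, nbrs: list[list[int]], max_len: float, passes: int = 2
) -> np.ndarray:
    """Delete dead-end chains shorter than ``max_len`` (um) that terminate at
    a junction voxel; returns the alive-node mask. Isolated chains are kept."""
    alive = np.ones(len(phys), dtype=bool)
    for _ in range(passes):
        deg = np.array([sum(alive[j] for j in nb) for nb in nbrs])
        removed_any = False
        for i in np.flatnonzero(alive & (deg == 1)):
            path = [int(i)]
            prev, cur = -1, int(i)
            length = 0.0
            reached_junction = False
            while True:
                nxt = [n for n in nbrs[cur] if alive[n] and n != prev]
                if not nxt:
                    break
                n = nxt[0]
                length += float(np.linalg.norm(phys[n] - phys[cur]))
                if deg[n] >= 3:
                    reached_junction = True
                    break
                if length > max_len:
                    break
                path.append(n)
                prev, cur = cur, n
                if deg[cur] != 2:
                    break
            if reached_junction and length <= max_len:
                alive[path] = False
                removed_any = True
        if not removed_any:
            break
    return alive


def _smooth_polyline(pts: np.ndarray, iterations: int = 2) -> np.ndarray:
    """Laplacian smoothing of interior points (endpoints fixed); removes the
    half-voxel zig-zag of 26-connected skeleton paths that inflates length."""
    for _ in range(iterations):
        if len(pts) < 3:
            break
        q = pts.copy()
        q[1:-1] = 0.25 * pts[:-2] + 0.5 * pts[1:-1] + 0.25 * pts[2:]
        pts = q
    return pts


def _resample_polyline(pts: np.ndarray, step: float) -> np.ndarray:
    """Arc-length resampling at roughly ``step`` um; endpoints preserved."""
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = float(s[-1])
    if total <= step:
        return np.array([pts[0], pts[-1]])
    n = max(2, int(round(total / step)) + 1)
    t = np.linspace(0.0, total, n)
    return np.column_stack([np.interp(t, s, pts[:, k]) for k in range(3)])


def extract_centerlines(
    mask: BinaryMask,
    min_branch_length: float = 1.5,
    junction_max_turn_deg: float = 60.0,
    tangent_window_um: float = 2.0,
    centerline_step_um: float = 1.0,
) -> list[FiberPolyline]:
    """Skeletonize the mask and trace it into fiber polylines.

    The skeleton voxel graph is cleaned (triangle chords removed, short
    dead-end spurs pruned), adjacent junction voxels are collapsed into
    single junction nodes, and the degree-<=2 chains between them become
    branches. At every junction, branches whose tangents continue within
    ``junction_max_turn_deg`` of a straight line are paired up (most
    collinear first) and merged, so a fiber crossing another one is traced
    through the crossing instead of being cut into four stubs. Radii are
    set to a half-voxel placeholder; use :func:`estimate_local_diameters`
    to fill them from the distance transform.
    """
    if not mask.data.any():
        return []
    from skimage.morphology import skeletonize

    # The library's 3D thinning annihilates objects whose cross-section has an
    # even voxel extent (e.g. a 2x2 or 4x4 tube reduces to nothing). Working
    # on a 2x upsampled grid grown by one voxel on the positive side of each
    # axis forces odd extents everywhere; the half-voxel growth offset cancels
    # exactly in the index-to-physical mapping below: fine voxel j covers
    # original coordinate ((j+0.5)/2)*spacing and the one-sided growth shifts
    # the medial axis by +0.5 fine voxel, so the center is j * spacing/2.
    fine = mask.data
    for ax in range(3):
        fine = np.repeat(fine, 2, axis=ax)
    for ax in range(3):
        shifted = np.roll(fine, 1, axis=ax)
        edge = [slice(None)] * 3
        edge[ax] = 0
        shifted[tuple(edge)] = False
        fine = fine | shifted
    fine_spacing = mask.spacing / 2.0
    skel = skeletonize(fine)

    coords, nbrs = _skeleton_graph(skel)
    if len(coords) == 0:
        return []
    phys = coords * fine_spacing + mask.origin
    _remove_triangle_chords(phys, nbrs)
    alive = _prune_spurs_graph(phys, nbrs, max_len=min_branch_length)
    nbrs = [[j for j in nb if alive[j]] if alive[i] else [] for i, nb in enumerate(nbrs)]
    deg = np.array([len(nb) for nb in nbrs])
    is_junction = alive & (deg >= 3)

    # collapse 26-adjacent junction voxels into junction nodes
    cluster_of = np.full(len(coords), -1, dtype=int)
    cluster_points: list[np.ndarray] = []
    for i in np.flatnonzero(is_junction):
        if cluster_of[i] >= 0:
            continue
        cid = len(cluster_points)
        stack = [int(i)]
        members = []
        cluster_of[i] = cid
        while stack:
            v = stack.pop()
            members.append(v)
            for w in nbrs[v]:
                if is_junction[w] and cluster_of[w] < 0:
                    cluster_of[w] = cid
                    stack.append(w)
        pts = phys[members]
        centroid = pts.mean(axis=0)
        # representative point: the member closest to the centroid, so the
        # junction point is guaranteed to lie on the skeleton (inside the mask)
        cluster_points.append(pts[np.argmin(np.linalg.norm(pts - centroid, axis=1))])

    # trace branches: chains of non-junction voxels between terminals, where a
    # terminal is a junction node, a dead end, or a chain end
    branches: list[dict] = []  # pts (k,3), ends: (cluster_id | None, cluster_id | None)
    visited_edges: set[frozenset] = set()

    def walk(start: int, first: int) -> None:
        key = frozenset((start, first))
        if key in visited_edges:
            return
        visited_edges.add(key)
        idx_path = [start, first]
        prev, cur = start, first
        while not is_junction[cur] and deg[cur] == 2:
            nxt = [x for x in nbrs[cur] if x != prev]
            if not nxt:
                break
            step = int(nxt[0])
            visited_edges.add(frozenset((cur, step)))
            idx_path.append(step)
            prev, cur = cur, step
        pts = [phys[v] for v in idx_path]
        end_a = int(cluster_of[start]) if is_junction[start] else None
        end_b = int(cluster_of[cur]) if is_junction[cur] else None
        if end_a is not None:
            pts[0] = cluster_points[end_a]
        if end_b is not None:
            pts[-1] = cluster_points[end_b]
        branches.append({"pts": np.asarray(pts), "ends": (end_a, end_b)})

    for i in np.flatnonzero(alive):
        if is_junction[i] or deg[i] == 2:
            continue
        for j in nbrs[i]:
            if not is_junction[j]:
                walk(int(i), int(j))
    entered: set[tuple[int, int]] = set()  # (cluster, chain voxel) entry points
    for c in np.flatnonzero(is_junction):
        for j in nbrs[c]:
            if not is_junction[j]:
                key = (int(cluster_of[c]), int(j))
                if key in entered:
                    continue
                entered.add(key)
                walk(int(c), int(j))
    # pure cycles (every voxel degree 2): trace each once
    seen = {v for e in visited_edges for v in e}
    for start in np.flatnonzero(alive & (deg == 2) & ~is_junction):
        if start in seen:
            continue
        path = [int(start)]
        prev, cur = -1, int(start)
        while True:
            seen.add(cur)
            nxt = [x for x in nbrs[cur] if x != prev]
            if not nxt:
                break
            step = int(nxt[0])
            path.append(step)
            prev, cur = cur, step
            if cur == start:
                break
        if len(path) >= 2:
            branches.append({"pts": phys[path], "ends": (None, None)})

    # local mask radius at each junction: the skeleton bends toward the blob
    # center within about one radius of a junction, so tangents for the
    # continuation test are measured beyond that distorted zone
    edt_full = ndimage.distance_transform_edt(mask.data, sampling=mask.spacing)

    def local_radius(p: np.ndarray) -> float:
        vox = np.clip(
            ((p - mask.origin) / mask.spacing).astype(int), 0, np.array(mask.shape) - 1
        )
        return float(edt_full[tuple(vox)])

    # pair branches across junctions by straightest continuation
    def end_tangent(b: dict, end: int, skip: float) -> np.ndarray:
        """Unit tangent pointing into the junction at the given end, measured
        over ``tangent_window_um`` of arc after skipping ``skip`` um from the
        junction (the thinning-distorted zone)."""
        pts = b["pts"] if end == 1 else b["pts"][::-1]
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        total = float(s[-1])
        if total <= 0:
            return np.zeros(3)
        skip = min(skip, 0.5 * total)
        s_near = total - skip
        s_far = max(0.0, s_near - tangent_window_um)
        near = np.array([np.interp(s_near, s, pts[:, k]) for k in range(3)])
        far = np.array([np.interp(s_far, s, pts[:, k]) for k in range(3)])
        t = near - far
        n = np.linalg.norm(t)
        return t / n if n > 0 else np.zeros(3)

    # Dead-end stub detection happens before pairing: thinning forks into a
    # short Y about one local radius before a blunt fiber end, and oblique
    # tubes digitize into staircase rails with short collinear tails past each
    # junction. Such tails would win the continuation test (they are collinear
    # with the incoming branch), so any dead-end branch attached to a junction
    # and shorter than 1.5x the local mask radius is excluded from pairing and
    # from the output.
    def is_dead_stub(b: dict) -> bool:
        end_a, end_b = b["ends"]
        if (end_a is None) == (end_b is None):
            return False
        jp = b["pts"][0] if end_a is not None else b["pts"][-1]
        length = float(np.linalg.norm(np.diff(b["pts"], axis=0), axis=1).sum())
        return length <= 1.5 * local_radius(jp)

    dead_stub = [is_dead_stub(b) for b in branches]

    incident: dict[int, list[tuple[int, int]]] = {}
    for bi, b in enumerate(branches):
        if dead_stub[bi]:
            continue
        for end in (0, 1):
            cid = b["ends"][end]
            if cid is not None:
                incident.setdefault(cid, []).append((bi, end))
    min_cos = float(np.cos(np.radians(junction_max_turn_deg)))
    partner: dict[tuple[int, int], tuple[int, int]] = {}
    for cid, ends in incident.items():
        skip = local_radius(cluster_points[cid])
        tangents = [end_tangent(branches[bi], end, skip) for bi, end in ends]
        scored = []
        for a in range(len(ends)):
            for b2 in range(a + 1, len(ends)):
                if ends[a][0] == ends[b2][0]:
                    continue  # never close a branch onto itself
                s = -float(np.dot(tangents[a], tangents[b2]))
                if s >= min_cos:
                    scored.append((s, a, b2))
        scored.sort(reverse=True)
        used: set[int] = set()
        for s, a, b2 in scored:
            if a in used or b2 in used:
                continue
            used.update((a, b2))
            partner[ends[a]] = ends[b2]
            partner[ends[b2]] = ends[a]

    # Ladder-rung filter (after pairing): where two fibers touch or graze,
    # thinning leaves a short web bridging their skeletons. An unpaired
    # junction-to-junction branch no longer than the sum of the local radii at
    # its ends (the separation of two touching fibers' centerlines) is such a
    # bridge; anything that short is below the resolution of the mask anyway.
    # The fibers traced through the two junctions still share the junction
    # points, so network connectivity at the contact survives without the rung.
    def is_rung(bi: int) -> bool:
        b = branches[bi]
        if (bi, 0) in partner or (bi, 1) in partner:
            return False
        end_a, end_b = b["ends"]
        if end_a is None or end_b is None:
            return False
        length = float(np.linalg.norm(np.diff(b["pts"], axis=0), axis=1).sum())
        return length <= local_radius(b["pts"][0]) + local_radius(b["pts"][-1])

    # stitch paired branches into full fibers
    polylines: list[FiberPolyline] = []
    placeholder = 0.5 * float(np.mean(fine_spacing))
    fid = 0
    done = [dead_stub[bi] or is_rung(bi) for bi in range(len(branches))]

    def oriented(bi: int, start_end: int) -> np.ndarray:
        pts = branches[bi]["pts"]
        return pts if start_end == 0 else pts[::-1]

    def emit(pts: np.ndarray) -> None:
        nonlocal fid
        keep = np.ones(len(pts), dtype=bool)
        keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-9
        pts = pts[keep]
        if len(pts) < 2:
            return
        pts = _resample_polyline(_smooth_polyline(pts), centerline_step_um)
        polylines.append(FiberPolyline(pts, np.full(len(pts), placeholder), fid))
        fid += 1

    for bi in range(len(branches)):
        if done[bi]:
            continue
        # find a free (unpaired) end to start from; fall back to 0 for cycles
        start_end = 0
        for e in (0, 1):
            if (bi, e) not in partner:
                start_end = e
                break
        else:
            start_end = 0
        chain = [oriented(bi, start_end)]
        done[bi] = True
        cur = (bi, 1 - start_end)
        while cur in partner:
            nb, ne = partner[cur]
            if done[nb]:
                break  # pairing cycle
            done[nb] = True
            chain.append(oriented(nb, ne)[1:])  # junction point already emitted
            cur = (nb, 1 - ne)
        emit(np.concatenate(chain))

    # Duplicate-rail filter: two distinct fiber centerlines cannot run closer
    # than the sum of their radii, so a traced fiber whose points mostly lie
    # within the local mask radius of a longer traced fiber is a redundant
    # rail of the same tube (staircase digitization of oblique fibers leaves
    # these). Fibers are kept longest-first.
    if len(polylines) > 1:
        from scipy.spatial import cKDTree

        lengths = [
            float(np.linalg.norm(np.diff(p.points, axis=0), axis=1).sum())
            for p in polylines
        ]
        order = np.argsort(lengths)[::-1]
        kept: list[FiberPolyline] = []
        kept_pts: list[np.ndarray] = []
        shape_arr = np.array(mask.shape)
        for oi in order:
            p = polylines[oi]
            if kept_pts:
                tree = cKDTree(np.concatenate(kept_pts))
                d, _ = tree.query(p.points)
                vox = np.clip(
                    ((p.points - mask.origin) / mask.spacing).astype(int),
                    0,
                    shape_arr - 1,
                )
                r_loc = edt_full[vox[:, 0], vox[:, 1], vox[:, 2]]
                if np.mean(d < r_loc) >= 0.8:
                    continue
            kept.append(p)
            kept_pts.append(p.points)
        polylines = sorted(kept, key=lambda p: p.fiber_id)
        for new_id, p in enumerate(polylines):
            p.fiber_id = new_id

    return polylines


def estimate_local_diameters(
    mask: BinaryMask, fibers: list[FiberPolyline]
) -> list[FiberPolyline]:
    """Fill per-point radii from the Euclidean distance transform.

    Inside a tube the EDT is a cone peaking at the axis,
    ``EDT(v) = r - d(v, axis)``, so the radius at a centerline point is
    estimated as the median of ``EDT(v) + d(v, tangent line)`` over the
    foreground corners of the enclosing voxel cell. This is exact on the
    continuous tube model, whereas interpolating the EDT at the axis clips
    the cone tip and reads up to half a voxel low. Near a fiber tip the
    nearest surface is the end cap rather than the lateral wall, so points
    whose arc distance to either end is smaller than their local radius
    take the radius of the nearest interior point instead. A small floor
    of a quarter voxel keeps radii positive at points grazing the surface.
    Raises if a fiber point falls outside the mask.
    """
    edt = ndimage.distance_transform_edt(mask.data, sampling=mask.spacing)
    mean_sp = float(np.mean(mask.spacing))
    floor = 0.25 * mean_sp
    out: list[FiberPolyline] = []
    shape = np.array(mask.shape)
    corner_off = np.array(
        [(i, j, k) for i in (0, 1) for j in (0, 1) for k in (0, 1)], dtype=int
    )
    for f in fibers:
        pts = f.points
        frac = (pts - mask.origin) / mask.spacing - 0.5  # voxel-center coords
        if np.any(frac < -0.75) or np.any(frac > shape - 0.25):
            raise ValueError("fiber point outside the mask grid")
        interp = ndimage.map_coordinates(edt, frac.T, order=1, mode="nearest")
        if np.any(interp <= 0):
            raise ValueError("fiber point lies in background; inconsistent inputs")
        # unit tangents (central differences, one-sided at the ends)
        tang = np.empty_like(pts)
        tang[1:-1] = pts[2:] - pts[:-2]
        tang[0] = pts[1] - pts[0] if len(pts) > 1 else np.array([1.0, 0, 0])
        tang[-1] = pts[-1] - pts[-2] if len(pts) > 1 else np.array([1.0, 0, 0])
        norms = np.linalg.norm(tang, axis=1, keepdims=True)
        tang = np.divide(tang, norms, out=np.zeros_like(tang), where=norms > 0)
        # enclosing-cell corners: EDT value plus off-axis compensation
        base = np.clip(np.floor(frac).astype(int), 0, np.maximum(shape - 2, 0))
        corners = base[:, None, :] + corner_off[None, :, :]  # (n, 8, 3)
        corners = np.minimum(corners, shape - 1)
        edt_c = edt[corners[..., 0], corners[..., 1], corners[..., 2]]  # (n, 8)
        centers = mask.origin + (corners + 0.5) * mask.spacing
        dvec = centers - pts[:, None, :]
        axial = np.einsum("npk,nk->np", dvec, tang)
        d_line = np.linalg.norm(
            dvec - axial[..., None] * tang[:, None, :], axis=-1
        )
        cand = np.where(edt_c > 0, edt_c + d_line, np.nan)
        with np.errstate(all="ignore"):
            vals = np.nanmedian(cand, axis=1)
        vals = np.where(np.isfinite(vals), vals, interp)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        to_end = np.minimum(s, s[-1] - s)
        interior = to_end >= vals
        if interior.any() and not interior.all():
            idx_in = np.flatnonzero(interior)
            nearest = idx_in[
                np.argmin(np.abs(s[~interior][:, None] - s[idx_in][None, :]), axis=1)
            ]
            vals = vals.copy()
            vals[~interior] = vals[nearest]
        radii = np.maximum(vals, floor)
        out.append(FiberPolyline(pts.copy(), radii, f.fiber_id))
    return out


def segment_stack(
    vol: VoxelVolume, config: ImageProcConfig | None = None
) -> tuple[BinaryMask, list[FiberPolyline]]:
    """Run the full segmentation chain on a raw volume.

    median filter -> threshold -> opening -> closing -> surface smoothing
    -> centerline extraction -> local diameter estimation.
    """
    cfg = config or ImageProcConfig()
    v = median_filter_3d(vol, cfg.median_kernel)
    mask = threshold_segment(v, cfg.threshold)
    mask = morphological_open(mask, cfg.se_radius_voxels)
    mask = morphological_close(mask, cfg.se_radius_voxels)
    mask = smooth_binary_surface(mask, cfg.smoothing_iterations, cfg.smoothing_factor)
    fibers = extract_centerlines(
        mask,
        cfg.min_branch_length,
        cfg.junction_max_turn_deg,
        cfg.tangent_window_um,
        cfg.centerline_step_um,
    )
    fibers = estimate_local_diameters(mask, fibers)
    return mask, fibers
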