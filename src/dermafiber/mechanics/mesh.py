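"""Structured tetrahedral box meshes and beam embedding."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..domain import DomainSpec
from ..fibers import FiberNetwork

# Kuhn subdivision of the unit hexahedron into 6 tetrahedra sharing the main
# diagonal (corner bit patterns along the 6 permutation paths 000 -> 111);
# consistent across cells, so faces match between neighbours.
_KUHN_PATHS = [
    ((0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1)),
    ((0, 0, 0), (1, 0, 0), (1, 0, 1), (1, 1, 1)),
    ((0, 0, 0), (0, 1, 0), (1, 1, 0), (1, 1, 1)),
    ((0, 0, 0), (0, 1, 0), (0, 1, 1), (1, 1, 1)),
    ((0, 0, 0), (0, 0, 1), (1, 0, 1), (1, 1, 1)),
    ((0, 0, 0), (0, 0, 1), (0, 1, 1), (1, 1, 1)),
]


@dataclass
class TetMeshModel:
    """Box tetrahedral mesh with an embedded beam set.

    ``beams`` are 2-node elements whose endpoints are mesh node indices;
    their translational degrees of freedom are shared with the matrix, the
    rotational ones belong to the beams alone.
    """

    nodes: np.ndarray  # (N, 3) um
    tets: np.ndarray  # (M, 4) int
    domain: DomainSpec
    grid_shape: tuple[int, int, int]  # cells per axis
    beams: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), dtype=int))
    beam_diameters: np.ndarray = field(default_factory=lambda: np.zeros(0))
    embedding_report: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return int(self.nodes.shape[0])

    @property
    def n_tets(self) -> int:
        return int(self.tets.shape[0])

    @property
    def n_beams(self) -> int:
        return int(self.beams.shape[0])

    @property
    def cell_spacing(self) -> np.ndarray:
        return self.domain.sizes / np.array(self.grid_shape)

    def tet_volumes(self) -> np.ndarray:
        x = self.nodes[self.tets]
        d = x[:, 1:] - x[:, :1]
        return np.linalg.det(d) / 6.0


def build_box_mesh(domain: DomainSpec, target_edge: float) -> TetMeshModel:
    """Structured grid of hexahedra, each split into 6 positively oriented
    tetrahedra with a consistent diagonal; cell counts are chosen so the cell
    edge is as close as possible to ``target_edge``."""
    sizes = domain.sizes
    if target_edge >= sizes.min():
        raise ValueError("target_edge must be smaller than every box dimension")
    ncell = np.maximum(1, np.round(sizes / target_edge)).astype(int)
    nx, ny, nz = (int(v) for v in ncell)
    xs = np.linspace(0.0, sizes[0], nx + 1)
    ys = np.linspace(0.0, sizes[1], ny + 1)
    zs = np.linspace(0.0, sizes[2], nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    I, J, K = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    I, J, K = I.ravel(), J.ravel(), K.ravel()
    tets = np.empty((len(I) * 6, 4), dtype=int)
    for p, path in enumerate(_KUHN_PATHS):
        for v, (di, dj, dk) in enumerate(path):
            tets[p::6, v] = nid(I + di, J + dj, K + dk)

    model = TetMeshModel(nodes, tets, domain, (nx, ny, nz))
    vols = model.tet_volumes()
    flip = vols < 0
    if np.any(flip):
        tets[flip, 2], tets[flip, 3] = tets[flip, 3].copy(), tets[flip, 2].copy()
        model = TetMeshModel(nodes, tets, domain, (nx, ny, nz))
    return model


def embed_beams(mesh: TetMeshModel, net: FiberNetwork) -> TetMeshModel:
    """Snap each network node to the nearest matrix mesh node and turn the
    network segments into beam elements.

    Beams whose two endpoints snap to the same mesh node are dropped as
    zero-length; the embedding report records snap displacements and the
    dropped length. Raises when the network extends outside the box.
    """
    sizes = mesh.domain.sizes
    if net.n_nodes:
        tol = 1e-6 * sizes.max()
        if np.any(net.nodes < -tol) or np.any(net.nodes > sizes + tol):
            raise ValueError("fiber network extends outside the mesh box")

    h = mesh.cell_spacing
    ncell = np.array(mesh.grid_shape)
    idx = np.clip(np.round(net.nodes / h), 0, ncell).astype(int) if net.n_nodes else np.zeros((0, 3), int)
    ny1, nz1 = mesh.grid_shape[1] + 1, mesh.grid_shape[2] + 1
    snapped = (idx[:, 0] * ny1 + idx[:, 1]) * nz1 + idx[:, 2]
    snap_disp = (
        np.linalg.norm(mesh.nodes[snapped] - net.nodes, axis=1) if net.n_nodes else np.zeros(0)
    )

    beams = []
    diams = []
    dropped_length = 0.0
    seg_len = net.segment_lengths()
    for s, (a, b) in enumerate(net.segments):
        na, nb = int(snapped[a]), int(snapped[b])
        if na == nb:
            dropped_length += float(seg_len[s])
            continue
        beams.append((na, nb))
        diams.append(float(net.segment_diameters[s]))

    report = {
        "n_network_segments": net.n_segments,
        "n_beams": len(beams),
        "n_dropped": net.n_segments - len(beams),
        "dropped_length": dropped_length,
        "network_length": float(seg_len.sum()) if net.n_segments else 0.0,
        "max_snap_displacement": float(snap_disp.max()) if snap_disp.size else 0.0,
        "mean_snap_displacement": float(snap_disp.mean()) if snap_disp.size else 0.0,
    }
    return TetMeshModel(
        mesh.nodes,
        mesh.tets,
        mesh.domain,
        mesh.grid_shape,
        beams=np.array(beams, dtype=int).reshape(-1, 2),
        beam_diameters=np.array(diams),
        embedding_report=report,
    )
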