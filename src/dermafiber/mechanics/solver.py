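"""Quasi-static unconfined compression of the embedded-beam box model.

Boundary conditions: the left (x=0) face is constrained in x, the bottom
(y=0) face in y, the back (z=0) face in z; the top face is driven down to
the prescribed compression; the right and front faces stay planar through
multi-point constraints realized as a single shared master displacement
degree of freedom per face. Loading is incremental with Newton iterations
per increment and automatic step bisection on failure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .beams import BeamBatch
from .materials import MaterialParams
from .mesh import TetMeshModel
from .svk import ElementInversionError, svk_batch, tet_shape_gradients


@dataclass
class CompressionSetup:
    compression_ratio: float = 0.20
    n_increments: int = 10
    newton_tol: float = 1e-8  # relative residual
    max_newton_iter: int = 25

    def __post_init__(self) -> None:
        if not (0.0 < self.compression_ratio < 1.0):
            raise ValueError("compression ratio must be in (0, 1)")
        if self.newton_tol <= 0:
            raise ValueError("newton_tol must be positive")


@dataclass
class DofSystem:
    """Reduced degree-of-freedom bookkeeping.

    ``full_to_red`` maps every full DOF to a reduced index, with -1 for
    homogeneous Dirichlet DOFs and -2 for prescribed (driven) DOFs; tied
    DOFs of a planarity constraint share one master index.
    """

    full_to_red: np.ndarray
    n_red: int
    prescribed_dofs: np.ndarray
    top_nodes: np.ndarray
    bottom_nodes: np.ndarray
    n_full: int
    counts: dict = field(default_factory=dict)


def _beam_dof_layout(model: TetMeshModel):
    """Rotation DOF numbering for nodes touched by beams."""
    n = model.n_nodes
    if model.n_beams == 0:
        return np.zeros(0, dtype=int), np.zeros((0, 12), dtype=int)
    beam_nodes = np.unique(model.beams)
    rot_pos = {int(b): i for i, b in enumerate(beam_nodes)}
    off = 3 * n
    bdofs = np.empty((model.n_beams, 12), dtype=int)
    for b, (n1, n2) in enumerate(model.beams):
        r1, r2 = rot_pos[int(n1)], rot_pos[int(n2)]
        bdofs[b, 0:3] = 3 * n1 + np.arange(3)
        bdofs[b, 3:6] = off + 3 * r1 + np.arange(3)
        bdofs[b, 6:9] = 3 * n2 + np.arange(3)
        bdofs[b, 9:12] = off + 3 * r2 + np.arange(3)
    return beam_nodes, bdofs


def apply_boundary_conditions(model: TetMeshModel, setup: CompressionSetup) -> DofSystem:
    """Classify every DOF as free, fixed, prescribed, or tied to a planarity
    master. Corner nodes on intersecting Dirichlet faces receive the union of
    the (consistent) per-axis constraints."""
    nodes = model.nodes
    sizes = model.domain.sizes
    tol = 1e-6 * sizes.max()
    n = model.n_nodes
    beam_nodes, _ = _beam_dof_layout(model)
    n_full = 3 * n + 3 * len(beam_nodes)

    FREE, FIXED, PRESC, TIE_X, TIE_Z = 0, 1, 2, 3, 4
    kind = np.zeros(n_full, dtype=int)

    x, y, z = nodes[:, 0], nodes[:, 1], nodes[:, 2]
    left, right = x < tol, x > sizes[0] - tol
    bottom, top = y < tol, y > sizes[1] - tol
    back, front = z < tol, z > sizes[2] - tol

    idx = np.arange(n)
    kind[3 * idx[left] + 0] = FIXED
    kind[3 * idx[right] + 0] = TIE_X
    kind[3 * idx[bottom] + 1] = FIXED
    kind[3 * idx[top] + 1] = PRESC
    kind[3 * idx[back] + 2] = FIXED
    kind[3 * idx[front] + 2] = TIE_Z

    full_to_red = np.full(n_full, -1, dtype=int)
    nxt = 0
    master_x = master_z = -1
    if np.any(kind == TIE_X):
        master_x = nxt
        nxt += 1
    if np.any(kind == TIE_Z):
        master_z = nxt
        nxt += 1
    for d in range(n_full):
        k = kind[d]
        if k == FREE:
            full_to_red[d] = nxt
            nxt += 1
        elif k == TIE_X:
            full_to_red[d] = master_x
        elif k == TIE_Z:
            full_to_red[d] = master_z
        elif k == PRESC:
            full_to_red[d] = -2

    counts = {
        "fixed": int(np.sum(kind == FIXED)),
        "prescribed": int(np.sum(kind == PRESC)),
        "tied": int(np.sum(kind == TIE_X) + np.sum(kind == TIE_Z)),
        "free": int(np.sum(kind == FREE)),
    }
    return DofSystem(
        full_to_red=full_to_red,
        n_red=nxt,
        prescribed_dofs=np.flatnonzero(kind == PRESC),
        top_nodes=idx[top],
        bottom_nodes=idx[bottom],
        n_full=n_full,
        counts=counts,
    )


@dataclass
class SimulationResult:
    """Converged state of a compression run."""

    model: TetMeshModel
    displacements: np.ndarray  # (N,3) um
    rotations: np.ndarray  # (n_beam_nodes, 3)
    beam_nodes: np.ndarray
    reaction_force_top: float  # uN, resisting force reported positive
    reaction_force_bottom: float  # uN, same sign convention check
    fiber_axial_forces: np.ndarray  # (B,) uN, tension positive
    element_equivalent_strain: np.ndarray  # (M,)
    converged: bool
    info: dict = field(default_factory=dict)

    @property
    def nominal_top_traction(self) -> float:
        """Reaction per undeformed top area, MPa; negative = compressive."""
        d = self.model.domain
        return -self.reaction_force_top / (d.size_x * d.size_z)


def _equivalent_strain(E: np.ndarray) -> np.ndarray:
    tr = np.trace(E, axis1=1, axis2=2)
    dev = E - tr[:, None, None] / 3.0 * np.eye(3)[None]
    return np.sqrt(2.0 / 3.0 * np.einsum("eij,eij->e", dev, dev))


def solve_compression(
    model: TetMeshModel,
    materials: MaterialParams | None = None,
    setup: CompressionSetup | None = None,
) -> SimulationResult:
    """Incremental Newton solution of the compression problem.

    Raises RuntimeError with diagnostics when the solver cannot converge even
    after bisecting the load increments.
    """
    mat = materials or MaterialParams()
    cfg = setup or CompressionSetup()
    nodes, tets = model.nodes, model.tets
    n = model.n_nodes
    G, V = tet_shape_gradients(nodes, tets)
    tdofs = (3 * tets[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 12)

    beam_nodes, bdofs = _beam_dof_layout(model)
    bb = None
    b_n1 = b_n2 = b_r1 = b_r2 = None
    if model.n_beams:
        bb = BeamBatch(
            nodes[model.beams[:, 0]],
            nodes[model.beams[:, 1]],
            model.beam_diameters,
            mat.E_fiber,
            mat.G_fiber,
        )
        rot_pos = {int(bn): i for i, bn in enumerate(beam_nodes)}
        b_n1, b_n2 = model.beams[:, 0], model.beams[:, 1]
        b_r1 = np.array([rot_pos[int(v)] for v in b_n1])
        b_r2 = np.array([rot_pos[int(v)] for v in b_n2])

    # Grounded rotational springs on the beam rotation DOFs: a straight fiber
    # chain can spin rigidly about its own axis at zero energy (translations
    # are pinned to the matrix but nothing grounds the common twist), which
    # makes the tangent exactly singular. A spring ~1e-6 of the median beam
    # bending stiffness removes the null space with negligible parasitic
    # energy, and enters force and tangent consistently.
    k_rot = 0.0
    rot_dofs = np.arange(3 * n, 3 * n + 3 * len(beam_nodes))
    if model.n_beams:
        bl = np.linalg.norm(
            nodes[model.beams[:, 1]] - nodes[model.beams[:, 0]], axis=1
        )
        I_b = np.pi * model.beam_diameters**4 / 64.0
        k_rot = 1e-6 * float(np.median(mat.E_fiber * I_b / bl))

    dof = apply_boundary_conditions(model, cfg)
    ftr = dof.full_to_red
    valid = np.flatnonzero(ftr >= 0)
    vred = ftr[valid]

    t_rows = ftr[tdofs]
    b_rows = ftr[bdofs] if model.n_beams else None

    u_full = np.zeros(dof.n_full)

    def split_state(uf):
        u3 = uf[: 3 * n].reshape(n, 3)
        theta = uf[3 * n :].reshape(-1, 3)
        return u3, theta

    def assemble(uf, tangent=True):
        u3, theta = split_state(uf)
        f_t, K_t, E = svk_batch(u3, tets, G, V, mat.lam, mat.mu, tangent=tangent)
        f_full = np.zeros(dof.n_full)
        np.add.at(f_full, tdofs.ravel(), f_t.reshape(-1, 12).ravel())
        Nax = np.zeros(model.n_beams)
        K_b = None
        if bb is not None:
            f_b, K_b, Nax = bb.force_tangent(
                u3[b_n1], theta[b_r1], u3[b_n2], theta[b_r2], tangent=tangent
            )
            np.add.at(f_full, bdofs.ravel(), f_b.ravel())
            f_full[rot_dofs] += k_rot * uf[rot_dofs]
        K_red = None
        if tangent:
            rows = np.broadcast_to(t_rows[:, :, None], K_t.shape)
            cols = np.broadcast_to(t_rows[:, None, :], K_t.shape)
            mask = (rows >= 0) & (cols >= 0)
            data, r_idx, c_idx = K_t[mask], rows[mask], cols[mask]
            if K_b is not None:
                rb = np.broadcast_to(b_rows[:, :, None], K_b.shape)
                cb = np.broadcast_to(b_rows[:, None, :], K_b.shape)
                mb = (rb >= 0) & (cb >= 0)
                rr = ftr[rot_dofs]
                sel = rr >= 0
                data = np.concatenate([data, K_b[mb], np.full(sel.sum(), k_rot)])
                r_idx = np.concatenate([r_idx, rb[mb], rr[sel]])
                c_idx = np.concatenate([c_idx, cb[mb], rr[sel]])
            K_red = sp.coo_matrix(
                (data, (r_idx, c_idx)), shape=(dof.n_red, dof.n_red)
            ).tocsc()
        return f_full, K_red, Nax, E

    def residual(f_full):
        return np.bincount(vred, weights=f_full[valid], minlength=dof.n_red)

    H = model.domain.size_y
    abs_floor = 1e-10 * mat.E_matrix * model.domain.volume / H  # ~force scale * 1e-10

    t = 0.0
    base_step = 1.0 / cfg.n_increments
    step = base_step
    min_step = base_step / 64.0
    total_newton = 0
    history: list[dict] = []
    while t < 1.0 - 1e-12:
        t_new = min(1.0, t + step)
        backup = u_full.copy()
        u_full[dof.prescribed_dofs] = -cfg.compression_ratio * H * t_new
        ok = False
        ref = None
        for it in range(cfg.max_newton_iter):
            try:
                f_full, K_red, _, _ = assemble(u_full)
            except (ElementInversionError, RuntimeError):
                break
            r = residual(f_full)
            rn = float(np.linalg.norm(r))
            if ref is None:
                ref = max(rn, abs_floor)
            total_newton += 1
            if rn <= cfg.newton_tol * ref or rn <= abs_floor:
                ok = True
                history.append({"t": t_new, "iters": it, "residual": rn})
                break
            du = spla.spsolve(K_red, -r)
            u_full[valid] += du[vred]
        if ok:
            t = t_new
            step = min(step * 1.5, base_step)
        else:
            u_full = backup
            step *= 0.5
            if step < min_step:
                raise RuntimeError(
                    f"compression solve failed to converge at load factor {t_new:.3f} "
                    f"even with bisected increments (history: {history[-3:]})"
                )

    f_full, _, Nax, E = assemble(u_full, tangent=False)
    u3, theta = split_state(u_full)
    top_y = 3 * dof.top_nodes + 1
    bot_y = 3 * dof.bottom_nodes + 1
    r_top = -float(np.sum(f_full[top_y]))
    r_bot = float(np.sum(f_full[bot_y]))
    return SimulationResult(
        model=model,
        displacements=u3,
        rotations=theta,
        beam_nodes=beam_nodes,
        reaction_force_top=r_top,
        reaction_force_bottom=r_bot,
        fiber_axial_forces=Nax,
        element_equivalent_strain=_equivalent_strain(E),
        converged=True,
        info={
            "newton_iterations": total_newton,
            "increments": history,
            "dof_counts": dof.counts,
            "n_reduced_dofs": dof.n_red,
        },
    )


def equivalent_strain_field(result: SimulationResult) -> np.ndarray:
    """Per-tet equivalent (von Mises) strain of the Green-Lagrange tensor."""
    return result.element_equivalent_strain


def low_strain_mask(result: SimulationResult, threshold: float = 0.1) -> np.ndarray:
    """Flags for elements with equivalent strain below the threshold."""
    return result.element_equivalent_strain < threshold


def extract_fiber_axial_forces(
    result: SimulationResult, bins: int | np.ndarray = 20
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Signed per-beam axial forces (tension positive) and their histogram."""
    forces = result.fiber_axial_forces
    if forces.size:
        hist, edges = np.histogram(forces, bins=bins)
    else:
        hist, edges = np.histogram(np.zeros(0), bins=bins if np.ndim(bins) else 10)
    return forces, (hist, edges)


def homogeneous_compression_oracle(
    materials: MaterialParams | None = None, compression_ratio: float = 0.20
) -> dict:
    """Closed-form homogeneous solution for the fiber-free box.

    With lateral faces traction-free but planar, the deformation is
    F = diag(lt, ly, lt) with ly = 1 - compression_ratio; the lateral
    Green-Lagrange strain Et solves lam (2 Et + Ey) + 2 mu Et = 0, and the
    nominal top traction is ly * Syy. Exact for linear tets because the
    solution field is linear in the reference coordinates.
    """
    mat = materials or MaterialParams()
    ly = 1.0 - compression_ratio
    Ey = 0.5 * (ly**2 - 1.0)
    Et = -mat.lam * Ey / (2.0 * (mat.lam + mat.mu))
    lt = float(np.sqrt(1.0 + 2.0 * Et))
    Syy = mat.lam * (2.0 * Et + Ey) + 2.0 * mat.mu * Ey
    traction = ly * Syy  # nominal (first Piola-Kirchhoff), MPa
    E = np.diag([Et, Ey, Et])[None]
    return {
        "lateral_stretch": lt,
        "nominal_traction": float(traction),
        "equivalent_strain": float(_equivalent_strain(E)[0]),
        "Et": float(Et),
        "Ey": float(Ey),
    }
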