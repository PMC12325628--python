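"""Co-rotational 3D Euler-Bernoulli beams with circular cross-section.

The element state is measured through four frame-invariant deformation
quantities: the chord elongation, the twist about the current chord, and
two nodal bending vectors g_i = e1 x t_i, where e1 is the current chord
direction and t_i the initial tangent rotated by the nodal rotation vector.
All measures vanish identically under rigid-body motion, and the strain
energy is an explicit quadratic form in them, so the internal force is the
exact analytic gradient of the energy. Bending uses the classical
chord-relative end-rotation stiffness (the 4-2-2-4 pattern), torsion and
axial response the usual bar constants; transverse shear deformation is
neglected (slender-beam assumption).

The Newton tangent is the Gauss-Newton part J^T D J plus the axial
geometric stiffness; the omitted rotation-gradient terms only slow, never
bias, convergence (the residual is still driven to tolerance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_I3 = np.eye(3)


@dataclass(frozen=True)
class BeamSection:
    """Circular cross-section properties (um-based units)."""

    diameter: float

    @property
    def area(self) -> float:
        return np.pi * self.diameter**2 / 4.0

    @property
    def inertia(self) -> float:
        """Second moment of area about a diameter."""
        return np.pi * self.diameter**4 / 64.0

    @property
    def torsion_constant(self) -> float:
        return np.pi * self.diameter**4 / 32.0


def _hat(v: np.ndarray) -> np.ndarray:
    """Batched skew-symmetric (cross-product) matrices, (...,3) -> (...,3,3)."""
    out = np.zeros(v.shape[:-1] + (3, 3))
    out[..., 0, 1] = -v[..., 2]
    out[..., 0, 2] = v[..., 1]
    out[..., 1, 0] = v[..., 2]
    out[..., 1, 2] = -v[..., 0]
    out[..., 2, 0] = -v[..., 1]
    out[..., 2, 1] = v[..., 0]
    return out


def _rotate(theta: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Apply exp(theta^) to v, batched; series expansion near zero angle."""
    phi = np.linalg.norm(theta, axis=-1, keepdims=True)
    small = phi[..., 0] < 1e-8
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(phi > 0, theta / np.where(phi > 0, phi, 1.0), 0.0)
    c, s = np.cos(phi), np.sin(phi)
    kv = np.cross(k, v)
    kkv = k * np.sum(k * v, axis=-1, keepdims=True)
    out = v * c + kv * s + kkv * (1.0 - c)
    if np.any(small):
        tv = np.cross(theta, v)
        approx = v + tv + 0.5 * np.cross(theta, tv)
        out = np.where(small[..., None], approx, out)
    return out


def _left_jacobian(theta: np.ndarray) -> np.ndarray:
    """SO(3) left Jacobian J_l(theta), batched (...,3) -> (...,3,3)."""
    phi = np.linalg.norm(theta, axis=-1)
    th_hat = _hat(theta)
    th_hat2 = th_hat @ th_hat
    small = phi < 1e-6
    phi_safe = np.where(small, 1.0, phi)
    a = np.where(small, 0.5 - phi**2 / 24.0, (1.0 - np.cos(phi_safe)) / phi_safe**2)
    b = np.where(small, 1.0 / 6.0 - phi**2 / 120.0, (phi_safe - np.sin(phi_safe)) / phi_safe**3)
    return _I3 + a[..., None, None] * th_hat + b[..., None, None] * th_hat2


class BeamBatch:
    """Vectorized internal forces for a set of beams.

    Degree-of-freedom layout per beam: [u1, theta1, u2, theta2] (12).
    """

    def __init__(
        self,
        X1: np.ndarray,
        X2: np.ndarray,
        diameters: np.ndarray,
        E: float,
        G: float,
    ) -> None:
        self.X1 = np.atleast_2d(X1).astype(float)
        self.X2 = np.atleast_2d(X2).astype(float)
        d = np.atleast_1d(diameters).astype(float)
        t0 = self.X2 - self.X1
        self.L0 = np.linalg.norm(t0, axis=1)
        if np.any(self.L0 <= 0):
            raise ValueError("zero-length beam")
        self.e10 = t0 / self.L0[:, None]
        A = np.pi * d**2 / 4.0
        I = np.pi * d**4 / 64.0
        Jt = np.pi * d**4 / 32.0
        self.kA = E * A / self.L0
        self.kT = G * Jt / self.L0
        self.kB = E * I / self.L0
        self.n = len(self.L0)

    def measures(self, u1, th1, u2, th2):
        x21 = self.X2 + u2 - (self.X1 + u1)
        ln = np.linalg.norm(x21, axis=1)
        if np.any(ln <= 0):
            raise RuntimeError("beam collapsed to zero length during the solve")
        e1 = x21 / ln[:, None]
        ubar = ln - self.L0
        dth = th2 - th1
        tau = np.sum(e1 * dth, axis=1)
        t1 = _rotate(th1, self.e10)
        t2 = _rotate(th2, self.e10)
        g1 = np.cross(e1, t1)
        g2 = np.cross(e1, t2)
        return ln, e1, ubar, dth, tau, t1, t2, g1, g2

    def energy(self, u1, th1, u2, th2) -> float:
        _, _, ubar, _, tau, _, _, g1, g2 = self.measures(u1, th1, u2, th2)
        w = (
            0.5 * self.kA * ubar**2
            + 0.5 * self.kT * tau**2
            + self.kB
            * (
                2.0 * np.sum(g1 * g1, axis=1)
                + 2.0 * np.sum(g2 * g2, axis=1)
                + 2.0 * np.sum(g1 * g2, axis=1)
            )
        )
        return float(np.sum(w))

    def force_tangent(self, u1, th1, u2, th2, tangent: bool = True):
        """Per-beam internal force (B,12), optional tangent (B,12,12), and
        signed axial force (B,) with tension positive."""
        ln, e1, ubar, dth, tau, t1, t2, g1, g2 = self.measures(u1, th1, u2, th2)
        B = self.n
        Q = (_I3[None] - e1[:, :, None] * e1[:, None, :]) / ln[:, None, None]

        J = np.zeros((B, 8, 12))
        J[:, 0, 0:3] = -e1
        J[:, 0, 6:9] = e1
        Qdth = np.einsum("bij,bj->bi", Q, dth)
        J[:, 1, 0:3] = -Qdth
        J[:, 1, 3:6] = -e1
        J[:, 1, 6:9] = Qdth
        J[:, 1, 9:12] = e1
        he1 = _hat(e1)
        for row, t, th in ((2, t1, th1), (5, t2, th2)):
            ht = _hat(t)
            htQ = ht @ Q
            J[:, row : row + 3, 0:3] = htQ
            J[:, row : row + 3, 6:9] = -htQ
            col = 3 if row == 2 else 9
            J[:, row : row + 3, col : col + 3] = -he1 @ ht @ _left_jacobian(th)

        # generalized stresses
        N = self.kA * ubar
        T = self.kT * tau
        m1 = self.kB[:, None] * (4.0 * g1 + 2.0 * g2)
        m2 = self.kB[:, None] * (2.0 * g1 + 4.0 * g2)
        s = np.concatenate([N[:, None], T[:, None], m1, m2], axis=1)
        f = np.einsum("brp,br->bp", J, s)

        K = None
        if tangent:
            D = np.zeros((B, 8, 8))
            D[:, 0, 0] = self.kA
            D[:, 1, 1] = self.kT
            for i in range(3):
                D[:, 2 + i, 2 + i] = 4.0 * self.kB
                D[:, 5 + i, 5 + i] = 4.0 * self.kB
                D[:, 2 + i, 5 + i] = 2.0 * self.kB
                D[:, 5 + i, 2 + i] = 2.0 * self.kB
            K = np.einsum("brp,brs,bsq->bpq", J, D, J)
            geo = N[:, None, None] * Q
            for bi, bj, sgn in ((0, 0, 1.0), (0, 6, -1.0), (6, 0, -1.0), (6, 6, 1.0)):
                K[:, bi : bi + 3, bj : bj + 3] += sgn * geo
        return f, K, N


def beam_internal_forces(
    element_nodes: np.ndarray,
    displacements: np.ndarray,
    rotations: np.ndarray,
    E_fiber: float,
    section: BeamSection,
    G_fiber: float | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Single-beam interface.

    Parameters are the two reference nodes (2,3), nodal translations (2,3)
    and nodal rotation vectors (2,3). Returns (force (12,), tangent (12,12),
    signed axial force with tension positive).
    """
    G = G_fiber if G_fiber is not None else E_fiber / 2.6
    bb = BeamBatch(
        element_nodes[0][None], element_nodes[1][None], np.array([section.diameter]), E_fiber, G
    )
    f, K, N = bb.force_tangent(
        displacements[0][None],
        rotations[0][None],
        displacements[1][None],
        rotations[1][None],
    )
    return f[0], K[0], float(N[0])


def beam_element_energy(
    element_nodes: np.ndarray,
    displacements: np.ndarray,
    rotations: np.ndarray,
    E_fiber: float,
    section: BeamSection,
    G_fiber: float | None = None,
) -> float:
    G = G_fiber if G_fiber is not None else E_fiber / 2.6
    bb = BeamBatch(
        element_nodes[0][None], element_nodes[1][None], np.array([section.diameter]), E_fiber, G
    )
    return bb.energy(
        displacements[0][None],
        rotations[0][None],
        displacements[1][None],
        rotations[1][None],
    )
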