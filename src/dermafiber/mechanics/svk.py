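"""Saint Venant-Kirchhoff linear tetrahedra (total-Lagrangian).

Energy density W = (lambda/2) tr(E)^2 + mu tr(E^2) with the Green-Lagrange
strain E = (F^T F - I)/2; second Piola-Kirchhoff stress
S = lambda tr(E) I + 2 mu E. The deformation gradient is constant per
linear tet, so forces and tangents are exact element integrals.
"""

from __future__ import annotations

import numpy as np

from .materials import MaterialParams

_I3 = np.eye(3)


class ElementInversionError(RuntimeError):
    """Raised when det(F) <= 0 in some element (increment too large)."""


def tet_shape_gradients(nodes: np.ndarray, tets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Reference shape-function gradients G (M,4,3) and volumes V (M,)."""
    x = nodes[tets]
    Dm = x[:, 1:] - x[:, :1]  # rows: edge vectors
    V = np.linalg.det(Dm) / 6.0
    if np.any(V <= 0):
        raise ValueError("mesh contains non-positive tet volumes")
    Dinv = np.linalg.inv(Dm)
    # grad N_j (j = 1..3) is column j-1 of Dm^{-1}; grad N_0 closes the sum.
    G = np.empty((tets.shape[0], 4, 3))
    G[:, 1:, :] = np.transpose(Dinv, (0, 2, 1))
    G[:, 0, :] = -G[:, 1:, :].sum(axis=1)
    return G, V


def _stiffness_tensor(lam: float, mu: float) -> np.ndarray:
    """Constant SVK material tensor C_{MJPQ}."""
    d = _I3
    C = lam * np.einsum("mj,pq->mjpq", d, d) + mu * (
        np.einsum("mp,jq->mjpq", d, d) + np.einsum("mq,jp->mjpq", d, d)
    )
    return C


def svk_batch(
    u: np.ndarray,
    tets: np.ndarray,
    G: np.ndarray,
    V: np.ndarray,
    lam: float,
    mu: float,
    tangent: bool = True,
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray]:
    """Internal forces (M,4,3), optional tangents (M,12,12), and Green-Lagrange
    strains (M,3,3) for all tets at nodal displacements ``u`` (N,3)."""
    ue = u[tets]  # (M,4,3)
    F = _I3[None] + np.einsum("eai,eaJ->eiJ", ue, G)
    detF = np.linalg.det(F)
    if np.any(detF <= 0):
        raise ElementInversionError(
            f"{int(np.sum(detF <= 0))} inverted tetrahedra (min det F = {detF.min():.3e})"
        )
    E = 0.5 * (np.einsum("eiI,eiJ->eIJ", F, F) - _I3[None])
    trE = np.trace(E, axis1=1, axis2=2)
    S = lam * trE[:, None, None] * _I3[None] + 2.0 * mu * E
    P = np.einsum("eiM,eMJ->eiJ", F, S)
    f = V[:, None, None] * np.einsum("eiJ,eaJ->eai", P, G)
    K = None
    if tangent:
        C = _stiffness_tensor(lam, mu)
        A = np.einsum("eim,mJLn,ekn->eiJkL", F, C, F)
        A += np.einsum("ik,eJL->eiJkL", _I3, S)
        K = V[:, None, None, None, None] * np.einsum("eaJ,eiJkL,ebL->eaibk", G, A, G)
        K = K.reshape(tets.shape[0], 12, 12)
    return f, K, E


def svk_batch_energy(
    u: np.ndarray, tets: np.ndarray, G: np.ndarray, V: np.ndarray, lam: float, mu: float
) -> float:
    """Total strain energy of the matrix (uN * um)."""
    ue = u[tets]
    F = _I3[None] + np.einsum("eai,eaJ->eiJ", ue, G)
    E = 0.5 * (np.einsum("eiI,eiJ->eIJ", F, F) - _I3[None])
    trE = np.trace(E, axis1=1, axis2=2)
    W = 0.5 * lam * trE**2 + mu * np.einsum("eIJ,eIJ->e", E, E)
    return float(np.sum(V * W))


def svk_internal_forces(
    element_nodes: np.ndarray, displacements: np.ndarray, materials: MaterialParams
) -> tuple[np.ndarray, np.ndarray]:
    """Single-element interface: internal force (12,) and symmetric tangent
    (12,12) for one tet given its reference nodes (4,3) and nodal
    displacements (4,3)."""
    tets = np.array([[0, 1, 2, 3]])
    G, V = tet_shape_gradients(np.asarray(element_nodes, dtype=float), tets)
    f, K, _ = svk_batch(
        np.asarray(displacements, dtype=float), tets, G, V, materials.lam, materials.mu
    )
    return f[0].reshape(12), K[0]


def svk_element_energy(
    element_nodes: np.ndarray, displacements: np.ndarray, materials: MaterialParams
) -> float:
    tets = np.array([[0, 1, 2, 3]])
    G, V = tet_shape_gradients(np.asarray(element_nodes, dtype=float), tets)
    return svk_batch_energy(
        np.asarray(displacements, dtype=float), tets, G, V, materials.lam, materials.mu
    )


def green_lagrange_strains(
    u: np.ndarray, tets: np.ndarray, G: np.ndarray
) -> np.ndarray:
    """Per-tet Green-Lagrange strain tensors (M,3,3)."""
    ue = u[tets]
    F = _I3[None] + np.einsum("eai,eaJ->eiJ", ue, G)
    return 0.5 * (np.einsum("eiI,eiJ->eIJ", F, F) - _I3[None])
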