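"""Mechanics: elements, meshing/embedding, and the compression solver."""

import numpy as np
import pytest

from dermafiber.domain import DomainSpec
from dermafiber.fibers import FiberPolyline, build_network
from dermafiber.mechanics import (
    BeamSection,
    CompressionSetup,
    MaterialParams,
    beam_internal_forces,
    build_box_mesh,
    embed_beams,
    homogeneous_compression_oracle,
    low_strain_mask,
    solve_compression,
)


def test_material_lame_constants():
    mat = MaterialParams()
    E, nu = mat.E_matrix, mat.nu
    assert mat.lam == pytest.approx(E * nu / ((1 + nu) * (1 - 2 * nu)))
    assert mat.mu == pytest.approx(E / (2 * (1 + nu)))


def test_beam_section_properties():
    sec = BeamSection(2.0)
    assert sec.area == pytest.approx(np.pi)
    assert sec.inertia == pytest.approx(np.pi * 16 / 64)
    assert sec.torsion_constant == pytest.approx(2 * sec.inertia)


def test_beam_rigid_rotation_gives_zero_force():
    X = np.array([[0.1, 0.2, -0.3], [4.0, 1.0, 2.0]])
    theta = np.array([0.3, -0.5, 0.7])
    phi = np.linalg.norm(theta)
    k = theta / phi
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    R = np.eye(3) + np.sin(phi) * K + (1 - np.cos(phi)) * K @ K
    c = np.array([1.0, -2.0, 0.5])
    disp = (X - c) @ R.T + c - X
    f, _, N = beam_internal_forces(
        X, disp, np.array([theta, theta]), 0.5, BeamSection(3.5), 0.5 / 2.6
    )
    assert np.abs(f).max() < 1e-9
    assert abs(N) < 1e-9


def test_beam_axial_force_exact():
    L = 10.0
    sec = BeamSection(3.5)
    E = 0.5
    _, _, N = beam_internal_forces(
        np.array([[0.0, 0, 0], [L, 0, 0]]),
        np.array([[0.0, 0, 0], [0.01, 0, 0]]),
        np.zeros((2, 3)),
        E,
        sec,
        E / 2.6,
    )
    assert N == pytest.approx(E * sec.area * 0.01 / L, rel=1e-9)


def test_build_box_mesh_geometry():
    dom = DomainSpec(40.0, 30.0, 20.0)
    mesh = build_box_mesh(dom, 5.0)
    assert mesh.grid_shape == (8, 6, 4)
    assert mesh.n_tets == 6 * 8 * 6 * 4
    # total tet volume equals the box volume
    n = mesh.nodes
    t = mesh.tets
    v = np.abs(
        np.einsum(
            "ij,ij->i",
            np.cross(n[t[:, 1]] - n[t[:, 0]], n[t[:, 2]] - n[t[:, 0]]),
            n[t[:, 3]] - n[t[:, 0]],
        )
        / 6.0
    )
    assert v.sum() == pytest.approx(dom.volume)
    with pytest.raises(ValueError):
        build_box_mesh(dom, 25.0)


def test_embed_beams_snapping_and_bounds():
    dom = DomainSpec(40.0, 30.0, 20.0)
    mesh = build_box_mesh(dom, 5.0)
    f = FiberPolyline(
        np.array([[6.0, 9.0, 11.0], [21.0, 9.0, 11.0]]), np.full(2, 1.5)
    )
    out = embed_beams(mesh, build_network([f]))
    assert out.n_beams == 1
    assert out.embedding_report["n_dropped"] == 0
    assert (
        out.embedding_report["max_snap_displacement"]
        <= np.linalg.norm(out.cell_spacing) / 2
    )
    # network outside the box is rejected
    g = FiberPolyline(np.array([[0.0, 0, 0], [45.0, 0, 0]]), np.full(2, 1.0))
    with pytest.raises(ValueError):
        embed_beams(mesh, build_network([g]))


def test_compression_setup_validation():
    with pytest.raises(ValueError):
        CompressionSetup(compression_ratio=0.0)
    with pytest.raises(ValueError):
        CompressionSetup(newton_tol=-1.0)


def test_oracle_closed_form_values():
    oracle = homogeneous_compression_oracle(MaterialParams(), 0.20)
    # values verified against an independent symbolic evaluation
    assert oracle["lateral_stretch"] == pytest.approx(1.0829589096544707, abs=1e-12)
    assert oracle["nominal_traction"] == pytest.approx(-0.011519999999999999, abs=1e-12)
    assert oracle["equivalent_strain"] == pytest.approx(0.1776, abs=1e-10)


def test_solve_reactions_balance_and_low_strain():
    dom = DomainSpec(30.0, 25.0, 20.0)
    mesh = build_box_mesh(dom, 5.0)
    res = solve_compression(mesh, MaterialParams(), CompressionSetup(n_increments=4))
    assert res.converged
    # top and bottom platen reactions balance
    assert res.reaction_force_top == pytest.approx(res.reaction_force_bottom, rel=1e-8)
    assert res.reaction_force_top > 0
    # homogeneous strain is well above the low-strain threshold
    assert not low_strain_mask(res).any()
    assert low_strain_mask(res, threshold=0.5).all()


def test_embedded_fiber_stiffens_response():
    dom = DomainSpec(30.0, 25.0, 20.0)
    mesh = build_box_mesh(dom, 5.0)
    res0 = solve_compression(mesh, MaterialParams(), CompressionSetup(n_increments=4))
    f = FiberPolyline(
        np.array([[15.0, 5.0, 10.0], [15.0, 13.0, 10.0], [15.0, 21.0, 10.0]]),
        np.full(3, 1.5),
    )
    meshf = embed_beams(mesh, build_network([f]))
    resf = solve_compression(meshf, MaterialParams(), CompressionSetup(n_increments=4))
    assert resf.converged
    assert resf.reaction_force_top > res0.reaction_force_top
    # a near-vertical fiber under compression carries negative axial force
    assert np.all(resf.fiber_axial_forces < 0)
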