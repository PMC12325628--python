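"""Synthetic generator, fragmentation, and voxelization."""

import numpy as np
import pytest

from dermafiber.domain import DomainSpec
from dermafiber.fibers import build_network, count_clusters
from dermafiber.synthetic import (
    NetworkGenParams,
    VoxelizationParams,
    fragment_network,
    generate_fiber_network,
    voxelize_network,
)

DOM = DomainSpec(60.0, 50.0, 40.0)


def _params(**kw):
    base = dict(
        n_fibers=30,
        diameter_mean=3.0,
        diameter_sd=0.2,
        length_mean=10.0,
        length_sd=3.0,
        vertical_fraction_target=0.3,
        waviness=0.04,
        seed=7,
    )
    base.update(kw)
    return NetworkGenParams(**base)


def test_generation_deterministic_and_in_domain():
    a = generate_fiber_network(DOM, _params())
    b = generate_fiber_network(DOM, _params())
    assert a.n_fibers == 30
    assert a.n_fibers == b.n_fibers
    for fa, fb in zip(a.fibers, b.fibers):
        assert np.array_equal(fa.points, fb.points)
        assert np.array_equal(fa.radii, fb.radii)
    pts = np.concatenate([f.points for f in a.fibers])
    assert np.all(pts >= -1e-9)
    assert np.all(pts <= DOM.sizes + 1e-9)


def test_generation_seed_sensitivity():
    a = generate_fiber_network(DOM, _params(seed=7))
    b = generate_fiber_network(DOM, _params(seed=8))
    pa = np.concatenate([f.points for f in a.fibers])
    pb = np.concatenate([f.points for f in b.fibers])
    assert pa.shape != pb.shape or not np.allclose(pa, pb)


def test_params_validation():
    with pytest.raises(ValueError):
        NetworkGenParams(n_fibers=-1)
    with pytest.raises(ValueError):
        NetworkGenParams(n_fibers=5, diameter_mean=0.0)
    with pytest.raises(ValueError):
        NetworkGenParams(n_fibers=5, vertical_fraction_target=1.5)
    with pytest.raises(ValueError):
        VoxelizationParams(voxel_spacing=0.0)
    with pytest.raises(ValueError):
        VoxelizationParams(background_level=500.0, fiber_level=100.0)


def test_fragmentation_increases_clusters_decreases_volume():
    net = generate_fiber_network(DOM, _params(n_fibers=20))
    n0, _ = count_clusters(net)
    v0 = net.total_fiber_volume()
    frag = fragment_network(net, n_breaks=8, gap=1.5, seed=3)
    n1, _ = count_clusters(frag)
    assert n1 >= n0
    assert frag.total_fiber_volume() < v0
    assert frag.n_fibers > net.n_fibers  # each severing splits one fiber in two
    with pytest.raises(ValueError):
        fragment_network(net, n_breaks=-1)


def test_voxelize_recovers_cylinder_volume():
    dom = DomainSpec(20.0, 20.0, 20.0)
    from dermafiber.fibers import FiberPolyline

    f = FiberPolyline(
        np.array([[2.0, 10.0, 10.0], [18.0, 10.0, 10.0]]), np.full(2, 2.0)
    )
    net = build_network([f])
    vp = VoxelizationParams(voxel_spacing=0.5)
    vol = voxelize_network(net, dom, vp)
    assert vol.shape == (40, 40, 40)
    fg = vol.data >= 0.5 * (vp.background_level + vp.fiber_level)
    measured = fg.sum() * 0.5**3
    # voxels are foreground within the radius of the centerline segment, so
    # the rasterized solid is the cylinder plus two hemispherical end caps
    exact = np.pi * 2.0**2 * 16.0 + 4.0 / 3.0 * np.pi * 2.0**3
    assert measured == pytest.approx(exact, rel=0.05)


def test_voxelize_noise_seeded():
    net = generate_fiber_network(DOM, _params(n_fibers=5))
    vp = VoxelizationParams(voxel_spacing=1.0, noise_sd=50.0, seed=4)
    a = voxelize_network(net, DOM, vp)
    b = voxelize_network(net, DOM, vp)
    assert np.array_equal(a.data, b.data)
    c = voxelize_network(net, DOM, VoxelizationParams(voxel_spacing=1.0, noise_sd=50.0, seed=5))
    assert not np.array_equal(a.data, c.data)
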