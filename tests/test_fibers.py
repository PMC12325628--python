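"""Fiber network construction and architecture metrics."""

import numpy as np
import pytest

from dermafiber.domain import DomainSpec
from dermafiber.fibers import (
    FiberPolyline,
    architecture_metrics,
    build_network,
    count_clusters,
    diameter_stats,
    max_cluster_size,
    split_diameters_by_orientation,
    vertical_proportion,
    volume_fraction,
)


def straight(p0, p1, r=1.0, fid=0):
    return FiberPolyline(np.array([p0, p1], dtype=float), np.full(2, r), fid)


def test_polyline_validation():
    with pytest.raises(ValueError):
        FiberPolyline(np.zeros((1, 3)), np.ones(1))  # too few points
    with pytest.raises(ValueError):
        straight([0, 0, 0], [1, 0, 0], r=-1.0)  # negative radius
    with pytest.raises(ValueError):
        FiberPolyline(np.zeros((2, 3)), np.ones(2))  # coincident points


def test_polyline_geometry():
    f = straight([0, 0, 0], [3, 4, 0], r=0.5)
    assert f.length == pytest.approx(5.0)
    assert f.mean_diameter == pytest.approx(1.0)
    assert f.cylinder_volume() == pytest.approx(np.pi * 0.25 * 5.0)
    # 3-4-0 chord: angle to Y = arccos(4/5)
    assert f.angle_to_y_deg() == pytest.approx(np.degrees(np.arccos(0.8)))
    assert straight([0, 0, 0], [0, 2, 0]).angle_to_y_deg() == pytest.approx(0.0)
    assert straight([0, 0, 0], [2, 0, 0]).angle_to_y_deg() == pytest.approx(90.0)


def test_build_network_merging():
    # two fibers sharing an endpoint within tolerance -> one cluster
    a = straight([0, 0, 0], [5, 0, 0], fid=0)
    b = straight([5.0, 0.3, 0], [5, 6, 0], fid=1)
    net = build_network([a, b], merge_tolerance=0.5)
    assert net.n_nodes == 3
    assert count_clusters(net)[0] == 1
    # out of tolerance -> two clusters
    c = straight([5.0, 0.6, 0], [5, 6, 0], fid=1)
    net2 = build_network([a, c], merge_tolerance=0.5)
    assert net2.n_nodes == 4
    assert count_clusters(net2)[0] == 2


def test_cluster_metrics():
    fibers = [
        straight([0, 0, 0], [5, 0, 0], fid=0),
        straight([5, 0, 0], [5, 5, 0], fid=1),
        straight([5, 5, 0], [0, 5, 0], fid=2),
        straight([20, 0, 0], [25, 0, 0], fid=3),
    ]
    net = build_network(fibers)
    n, labels = count_clusters(net)
    assert n == 2
    assert max_cluster_size(net) == 3
    assert sorted(np.bincount(labels).tolist()) == [1, 3]


def test_empty_network():
    net = build_network([])
    n, labels = count_clusters(net)
    assert n == 0 and labels.size == 0
    assert max_cluster_size(net) == 0
    dom = DomainSpec(10, 10, 10)
    assert volume_fraction(net, dom) == 0.0
    with pytest.raises(ValueError):
        vertical_proportion(net)
    with pytest.raises(ValueError):
        diameter_stats(net)


def test_volume_fraction_exact():
    dom = DomainSpec(10.0, 10.0, 10.0)
    f = straight([0, 5, 5], [10, 5, 5], r=1.0)
    net = build_network([f])
    expected = 100.0 * (np.pi * 1.0**2 * 10.0) / 1000.0
    assert volume_fraction(net, dom) == pytest.approx(expected)


def test_vertical_proportion_threshold():
    # exactly 45 degrees counts as horizontal (strict inequality)
    diag = straight([0, 0, 0], [1, 1, 0])  # 45 deg to Y
    vert = straight([0, 0, 0], [0.1, 1, 0])  # ~5.7 deg
    net = build_network([diag, vert], merge_tolerance=0.0)
    assert vertical_proportion(net) == pytest.approx(50.0)
    dv, dh = split_diameters_by_orientation(net)
    assert len(dv) == 1 and len(dh) == 1


def test_architecture_metrics_dict():
    dom = DomainSpec(20, 20, 20)
    net = build_network([straight([1, 1, 1], [10, 1, 1], r=1.5)])
    m = architecture_metrics(net, dom)
    d = m.as_dict()
    assert d["Fiber Count"] == 1
    assert d["Number of Fiber Clusters"] == 1
    assert d["Maximum Cluster Size"] == 1
    assert d["Mean Fiber Diameter (um)"] == pytest.approx(3.0)
    assert d["Vertical Fiber Proportion (%)"] == 0.0
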