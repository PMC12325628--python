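"""Image processing: thresholding, morphology, centerlines, diameters."""

import numpy as np
import pytest

from dermafiber.fibers import build_network
from dermafiber.imaging import (
    BinaryMask,
    VoxelVolume,
    estimate_local_diameters,
    extract_centerlines,
    median_filter_3d,
    morphological_close,
    morphological_open,
    segment_stack,
    spherical_structuring_element,
    threshold_segment,
)


def cylinder_mask(shape, p0, p1, radius, spacing=0.5):
    """Analytic voxelized cylinder: center-within-radius of the segment."""
    idx = np.indices(shape).reshape(3, -1).T
    centers = (idx + 0.5) * spacing
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    d = p1 - p0
    t = np.clip((centers - p0) @ d / (d @ d), 0.0, 1.0)
    closest = p0 + t[:, None] * d
    dist = np.linalg.norm(centers - closest, axis=1)
    data = (dist <= radius).reshape(shape)
    return BinaryMask(data, np.full(3, spacing))


def test_threshold_modes():
    data = np.zeros((4, 4, 4))
    data[1:3, 1:3, 1:3] = 1000.0
    vol = VoxelVolume(data, np.ones(3))
    m_auto = threshold_segment(vol, "auto")
    m_num = threshold_segment(vol, 500.0)
    assert np.array_equal(m_auto.data, m_num.data)
    assert m_num.data.sum() == 8
    with pytest.raises(ValueError):
        threshold_segment(vol, "magic")


def test_median_filter_removes_salt_noise():
    data = np.full((10, 10, 10), 100.0)
    data[5, 5, 5] = 5000.0  # isolated bright voxel
    vol = VoxelVolume(data, np.ones(3))
    out = median_filter_3d(vol, 3)
    assert out.data[5, 5, 5] == 100.0


def test_morphology_extensive_antiextensive():
    rng = np.random.default_rng(0)
    data = rng.random((16, 16, 16)) > 0.7
    mask = BinaryMask(data, np.ones(3))
    opened = morphological_open(mask, 1)
    closed = morphological_close(mask, 1)
    assert np.all(opened.data <= mask.data)  # opening shrinks
    assert np.all(closed.data >= mask.data)  # closing grows
    se = spherical_structuring_element(2)
    assert se.shape == (5, 5, 5)
    assert se[2, 2, 2] and not se[0, 0, 0]


def test_empty_mask_yields_no_fibers():
    mask = BinaryMask(np.zeros((8, 8, 8), bool), np.ones(3))
    assert extract_centerlines(mask) == []


def test_single_cylinder_traced_as_one_fiber():
    mask = cylinder_mask((60, 40, 40), [3.0, 10.0, 10.0], [27.0, 10.0, 10.0], 1.75)
    fibers = extract_centerlines(mask)
    assert len(fibers) == 1
    f = fibers[0]
    assert f.length == pytest.approx(24.0, rel=0.12)
    # centerline stays near the true axis
    assert np.all(np.abs(f.points[:, 1] - 10.0) < 1.0)
    assert np.all(np.abs(f.points[:, 2] - 10.0) < 1.0)


def test_crossing_cylinders_traced_as_two_fibers():
    m1 = cylinder_mask((60, 60, 40), [3.0, 15.0, 10.0], [27.0, 15.0, 10.0], 1.5)
    m2 = cylinder_mask((60, 60, 40), [15.0, 3.0, 10.0], [15.0, 27.0, 10.0], 1.5)
    mask = BinaryMask(m1.data | m2.data, m1.spacing)
    fibers = extract_centerlines(mask)
    assert len(fibers) == 2
    lengths = sorted(f.length for f in fibers)
    assert lengths[0] == pytest.approx(24.0, rel=0.15)
    assert lengths[1] == pytest.approx(24.0, rel=0.15)


def test_diameter_estimate_on_cylinder():
    mask = cylinder_mask((60, 40, 40), [3.0, 10.0, 10.0], [27.0, 10.0, 10.0], 1.75)
    fibers = estimate_local_diameters(mask, extract_centerlines(mask))
    d = fibers[0].mean_diameter
    assert d == pytest.approx(3.5, rel=0.15)


def test_segment_stack_end_to_end_synthetic_cylinder():
    spacing = 0.5
    shape = (60, 40, 40)
    mask = cylinder_mask(shape, [3.0, 10.0, 10.0], [27.0, 10.0, 10.0], 1.75, spacing)
    rng = np.random.default_rng(1)
    data = np.where(mask.data, 1000.0, 100.0) + rng.normal(0, 40.0, shape)
    vol = VoxelVolume(data, np.full(3, spacing))
    out_mask, fibers = segment_stack(vol)
    assert out_mask.shape == shape
    assert len(fibers) == 1
    net = build_network(fibers)
    assert net.fibers[0].mean_diameter == pytest.approx(3.5, rel=0.2)


def test_estimate_diameters_rejects_outside_points():
    from dermafiber.fibers import FiberPolyline

    mask = cylinder_mask((20, 20, 20), [2.0, 5.0, 5.0], [8.0, 5.0, 5.0], 1.5)
    bad = FiberPolyline(
        np.array([[1.0, 1.0, 1.0], [9.0, 9.0, 9.0]]), np.full(2, 0.5)
    )
    with pytest.raises(ValueError):
        estimate_local_diameters(mask, [bad])
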