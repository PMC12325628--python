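"""Donor-age presets hit their architecture targets."""

import numpy as np
import pytest

from dermafiber.fibers import architecture_metrics
from dermafiber.presets import (
    PRESET_AGES,
    build_preset_network,
    list_preset_ages,
    load_preset,
)
from dermafiber.stats import load_cohort_table


def test_preset_inventory_matches_cohort():
    ages = list_preset_ages()
    assert ages == sorted(PRESET_AGES)
    table = load_cohort_table()
    assert ages == table["Age (years)"].tolist()


def test_preset_targets_match_cohort_rows():
    table = load_cohort_table().set_index("Age (years)")
    for age in PRESET_AGES:
        spec = load_preset(age)
        row = table.loc[age]
        assert spec.fiber_count == int(row["Fiber Count"])
        assert spec.mean_diameter_um == pytest.approx(row["Mean Fiber Diameter (um)"])
        assert spec.n_clusters == int(row["Number of Fiber Clusters"])
        assert spec.volume_fraction_pct == pytest.approx(
            row["Elastin Volume Fraction (%)"]
        )


def test_unknown_age_rejected():
    with pytest.raises(ValueError):
        load_preset(99)
    with pytest.raises(ValueError):
        build_preset_network(38, scale=0.0)


def test_build_preset_hits_targets_at_reduced_scale():
    scale = 0.35
    for age in (39, 78):  # one young, one old donor
        build = build_preset_network(age, scale=scale)
        spec = build.preset
        m = architecture_metrics(build.network, build.domain)
        n_target = max(2, int(round(spec.fiber_count * scale**3)))
        k_target = min(
            int(round((spec.n_clusters - 1) * scale**3)), n_target - 1
        ) + 1
        assert m.fiber_count == n_target
        assert m.n_clusters == k_target
        assert m.mean_fiber_diameter == pytest.approx(spec.mean_diameter_um, abs=1e-9)
        assert m.volume_fraction == pytest.approx(
            spec.volume_fraction_pct, rel=0.15
        )
        assert abs(m.vertical_proportion - spec.vertical_proportion_pct) <= 12.0


def test_build_preset_deterministic():
    a = build_preset_network(59, scale=0.3)
    b = build_preset_network(59, scale=0.3)
    pa = np.concatenate([f.points for f in a.network.fibers])
    pb = np.concatenate([f.points for f in b.network.fibers])
    assert np.array_equal(pa, pb)
    assert a.info["realized"] == b.info["realized"]
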