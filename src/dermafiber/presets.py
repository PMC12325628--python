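"""Donor-age presets: networks matching the cohort architecture by construction.

Each preset (named by donor age) targets one row of the packaged cohort
table. The build grows a connected fiber tree, severs it until the target
cluster count is reached (each severing is accepted only if it raises the
cluster count by exactly one), shifts all radii uniformly so the mean fiber
diameter matches exactly, and calibrates the mean fiber length so the
volume fraction matches the target. Fiber count and cluster count therefore
match the target exactly; mean diameter matches to round-off; volume
fraction to the calibration tolerance; vertical proportion is exact in
expectation at generation. Firmness is never a preset input - it is an
output of the compression simulation.

``scale`` shrinks the box by the given linear factor and the fiber and
break counts by ``scale**3``, keeping fiber sizes and density realistic
while making small, fast study variants.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .domain import DomainSpec
from .fibers import (
    DEFAULT_MERGE_TOLERANCE,
    FiberNetwork,
    FiberPolyline,
    architecture_metrics,
    build_network,
    count_clusters,
    diameter_stats,
    volume_fraction,
)
from .synthetic import NetworkGenParams, _break_fiber, generate_fiber_network

PRESET_AGES = [38, 39, 43, 49, 58, 59, 67, 70, 78]


@dataclass(frozen=True)
class PresetSpec:
    """Targets and generator settings of one donor-age preset."""

    age: int
    fiber_count: int
    mean_diameter_um: float
    volume_fraction_pct: float
    n_clusters: int
    vertical_proportion_pct: float
    seed: int
    length_mean_um: float
    length_sd_um: float
    diameter_sd_um: float
    waviness: float
    break_gap_um: float
    height_um: float


def list_preset_ages() -> list[int]:
    """Ages of the shipped presets, ascending."""
    root = resources.files("dermafiber").joinpath("data/presets")
    ages = []
    for entry in root.iterdir():
        name = entry.name
        if name.startswith("preset_") and name.endswith(".toml"):
            ages.append(int(name[len("preset_") : -len(".toml")]))
    return sorted(ages)


def load_preset(age: int) -> PresetSpec:
    path = resources.files("dermafiber").joinpath(f"data/presets/preset_{age}.toml")
    try:
        raw = path.read_bytes()
    except FileNotFoundError as exc:
        raise ValueError(f"no preset for age {age}; available: {list_preset_ages()}") from exc
    doc = tomllib.loads(raw.decode())
    t, g = doc["targets"], doc["generator"]
    return PresetSpec(
        age=int(t["age"]),
        fiber_count=int(t["fiber_count"]),
        mean_diameter_um=float(t["mean_diameter_um"]),
        volume_fraction_pct=float(t["volume_fraction_pct"]),
        n_clusters=int(t["n_clusters"]),
        vertical_proportion_pct=float(t["vertical_proportion_pct"]),
        seed=int(g["seed"]),
        length_mean_um=float(g["length_mean_um"]),
        length_sd_um=float(g["length_sd_um"]),
        diameter_sd_um=float(g["diameter_sd_um"]),
        waviness=float(g["waviness"]),
        break_gap_um=float(g["break_gap_um"]),
        height_um=float(g["height_um"]),
    )


def _fragment_to_cluster_count(
    net: FiberNetwork, n_breaks: int, gap: float, seed: int
) -> FiberNetwork:
    """Sever fibers one at a time, accepting only severings that raise the
    cluster count by exactly one (cuts inside graph cycles are retried)."""
    if n_breaks == 0:
        return net
    rng = np.random.default_rng(seed)
    fibers = list(net.fibers)
    current, _ = count_clusters(net)
    for _ in range(n_breaks):
        for _attempt in range(200):
            cand = _break_fiber(fibers, rng, gap)
            if cand is None:
                raise RuntimeError("no fiber long enough to sever")
            cnet = build_network(cand, net.merge_tolerance)
            k, _ = count_clusters(cnet)
            if k == current + 1:
                fibers = cand
                current = k
                net = cnet
                break
        else:
            raise RuntimeError(
                f"could not find a severing that adds a cluster (at {current} clusters)"
            )
    return net


def _match_mean_diameter(net: FiberNetwork, target: float) -> FiberNetwork:
    """Uniformly shift all radii so the mean of per-fiber mean diameters
    equals the target (geometry and diameter spread unchanged)."""
    current = diameter_stats(net)[0]
    shift_r = 0.5 * (target - current)
    fibers = []
    for f in net.fibers:
        radii = f.radii + shift_r
        if np.any(radii <= 0.05):
            raise RuntimeError("diameter shift would produce non-positive radii")
        fibers.append(FiberPolyline(f.points, radii, f.fiber_id))
    return build_network(fibers, net.merge_tolerance)


@dataclass
class PresetBuild:
    """A built preset network plus its domain and bookkeeping."""

    network: FiberNetwork
    domain: DomainSpec
    preset: PresetSpec
    scale: float
    info: dict = field(default_factory=dict)


def build_preset_network(
    preset: PresetSpec | int,
    scale: float = 1.0,
    seed: int | None = None,
    merge_tolerance: float = DEFAULT_MERGE_TOLERANCE,
    vf_rtol: float = 0.08,
    max_calibration: int = 8,
) -> PresetBuild:
    """Build the network for one donor-age preset.

    The mean fiber length is coarsely calibrated (damped, regenerating with
    the same seed) until the raw volume fraction is within ``vf_rtol`` of
    the target; the final affine diameter transform then matches mean
    diameter and volume fraction exactly.
    """
    if isinstance(preset, int):
        preset = load_preset(preset)
    if not (0.0 < scale <= 1.0):
        raise ValueError("scale must be in (0, 1]")
    std = DomainSpec.standard(height=preset.height_um)
    domain = DomainSpec(std.size_x * scale, std.size_y * scale, std.size_z * scale)
    n_target = max(2, int(round(preset.fiber_count * scale**3)))
    n_breaks = min(int(round((preset.n_clusters - 1) * scale**3)), n_target - 1)
    n_tree = n_target - n_breaks
    seed_eff = preset.seed if seed is None else seed

    # The volume-fraction response to length_mean is noisy at small fiber
    # counts (regeneration reshuffles clipping), so the calibration is damped
    # and keeps the best iterate seen.
    vf_target = preset.volume_fraction_pct
    length_mean = preset.length_mean_um
    sd_ratio = preset.length_sd_um / preset.length_mean_um
    best: tuple[float, FiberNetwork, float] | None = None
    iterations = 0
    for iterations in range(1, max_calibration + 1):
        params = NetworkGenParams(
            n_fibers=n_tree,
            diameter_mean=preset.mean_diameter_um,
            diameter_sd=preset.diameter_sd_um,
            length_mean=length_mean,
            length_sd=sd_ratio * length_mean,
            vertical_fraction_target=preset.vertical_proportion_pct / 100.0,
            waviness=preset.waviness,
            attach_fraction=1.0,
            seed=seed_eff,
        )
        net = generate_fiber_network(domain, params, merge_tolerance)
        net = _fragment_to_cluster_count(net, n_breaks, preset.break_gap_um, seed_eff + 1)
        net = _match_mean_diameter(net, preset.mean_diameter_um)
        vf = volume_fraction(net, domain)
        err = abs(vf - vf_target) / vf_target
        if best is None or err < best[0]:
            best = (err, net, length_mean)
        if err <= vf_rtol:
            break
        length_mean *= (vf_target / vf) ** 0.7  # damped update

    _, net, length_mean = best
    metrics = architecture_metrics(net, domain)
    info = {
        "targets": {
            "fiber_count": n_target,
            "n_clusters": n_breaks + 1,
            "mean_diameter_um": preset.mean_diameter_um,
            "volume_fraction_pct": preset.volume_fraction_pct,
            "vertical_proportion_pct": preset.vertical_proportion_pct,
        },
        "realized": metrics.as_dict(),
        "calibration_iterations": iterations,
        "calibrated_length_mean_um": length_mean,
        "seed": seed_eff,
    }
    return PresetBuild(network=net, domain=domain, preset=preset, scale=scale, info=info)
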