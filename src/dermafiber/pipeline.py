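"""End-to-end study orchestration.

``run_study`` takes all nine (or a subset of) donor-age presets through
generate -> voxelize -> segment -> quantify -> simulate -> correlate,
writing every stage artifact to disk so each stage is independently
re-runnable, plus a manifest with seeds, versions, and checksums. With the
imaging stages disabled, the quantification runs on the generated geometry
directly (faster; used for mechanics-focused studies).
"""

from __future__ import annotations

import hashlib
import logging
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .fibers import architecture_metrics, build_network
from .imaging import ImageProcConfig, segment_stack
from .io import (
    write_fiber_csv,
    write_mask_tiff,
    write_metrics_json,
    write_tiff_stack,
)
from .mechanics import (
    CompressionSetup,
    MaterialParams,
    build_box_mesh,
    embed_beams,
    solve_compression,
)
from .presets import PRESET_AGES, build_preset_network
from .stats import (
    AGE_COLUMN,
    FIRMNESS_COLUMN,
    cohort_analysis,
    normalize_firmness,
)
from .synthetic import VoxelizationParams, voxelize_network

logger = logging.getLogger("dermafiber")

ARCHITECTURE_COLUMNS = [
    "Mean Fiber Diameter (um)",
    "Fiber Count",
    "Elastin Volume Fraction (%)",
    "Number of Fiber Clusters",
    "Maximum Cluster Size",
    "Vertical Fiber Proportion (%)",
]


@dataclass
class PipelineConfig:
    """Study configuration (loadable from TOML)."""

    output_dir: str = "study_out"
    seed: int = 1234
    ages: list[int] = field(default_factory=lambda: list(PRESET_AGES))
    scale: float = 0.35
    use_imaging: bool = True
    run_simulation: bool = True
    write_vtk: bool = False
    log_level: str = "INFO"
    # voxelization
    voxel_spacing: float = 0.5
    noise_sd: float = 60.0
    blur_sigma: float = 0.6
    # segmentation
    median_kernel: int = 3
    threshold: str | float = "auto"
    # simulation
    target_edge: float = 5.0
    compression_ratio: float = 0.2
    n_increments: int = 5

    def __post_init__(self) -> None:
        if not self.ages:
            raise ValueError("study needs at least one sample (empty ages list)")
        if not (0 <= self.seed < 2**31):
            raise ValueError("seed must be in [0, 2**31)")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        doc = tomllib.loads(Path(path).read_text())
        flat: dict = {}
        for key, value in doc.items():
            if isinstance(value, dict):
                flat.update(value)
            else:
                flat[key] = value
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**flat)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _corr_to_dict(c) -> dict:
    return {"r": c.r, "p_value": c.p_value, "n": c.n}


def run_sample(
    age: int, cfg: PipelineConfig, sample_dir: Path
) -> dict:
    """Run one donor-age sample through the enabled stages; returns the row
    for the cohort table plus bookkeeping."""
    sample_dir.mkdir(parents=True, exist_ok=True)
    seed = (cfg.seed + 13 * age) % 2**31
    build = build_preset_network(age, scale=cfg.scale, seed=seed)
    net, domain = build.network, build.domain
    write_fiber_csv(sample_dir / "fibers_true.csv", net.fibers)
    write_metrics_json(
        sample_dir / "metrics_true.json",
        {"age": age, **architecture_metrics(net, domain).as_dict()},
    )
    logger.info("age %d: generated %d fibers (seed %d)", age, net.n_fibers, seed)

    measured_net = net
    if cfg.use_imaging:
        vp = VoxelizationParams(
            voxel_spacing=cfg.voxel_spacing,
            noise_sd=cfg.noise_sd,
            blur_sigma=cfg.blur_sigma,
            seed=seed + 1,
        )
        vol = voxelize_network(net, domain, vp)
        write_tiff_stack(sample_dir / "stack.tif", vol)
        ip = ImageProcConfig(median_kernel=cfg.median_kernel, threshold=cfg.threshold)
        mask, fibers = segment_stack(vol, ip)
        write_mask_tiff(sample_dir / "mask.tif", mask)
        write_fiber_csv(sample_dir / "fibers_segmented.csv", fibers)
        measured_net = build_network(fibers)
        logger.info("age %d: segmented %d fibers from the stack", age, len(fibers))

    metrics = architecture_metrics(measured_net, domain)
    write_metrics_json(
        sample_dir / "metrics.json", {"age": age, **metrics.as_dict()}
    )

    row: dict = {AGE_COLUMN: age, **metrics.as_dict()}
    if cfg.run_simulation:
        mesh = build_box_mesh(domain, cfg.target_edge)
        mesh = embed_beams(mesh, measured_net)
        setup = CompressionSetup(
            compression_ratio=cfg.compression_ratio, n_increments=cfg.n_increments
        )
        result = solve_compression(mesh, MaterialParams(), setup)
        low_frac = float(np.mean(result.element_equivalent_strain < 0.1))
        report = {
            "age": age,
            "reaction_force_top_uN": result.reaction_force_top,
            "nominal_top_traction_MPa": result.nominal_top_traction,
            "n_beams": mesh.n_beams,
            "n_tets": mesh.n_tets,
            "low_strain_fraction": low_frac,
            "converged": result.converged,
            "embedding": mesh.embedding_report,
            "newton_iterations": result.info["newton_iterations"],
        }
        write_metrics_json(sample_dir / "simulation.json", report)
        row["raw_force_uN"] = result.reaction_force_top
        if cfg.write_vtk:
            from .io import write_vtk_mesh

            write_vtk_mesh(
                sample_dir / "result.vtk",
                mesh,
                point_data={"displacement": result.displacements},
                cell_data={"equivalent_strain": result.element_equivalent_strain},
            )
        logger.info(
            "age %d: reaction force %.4f uN (%d beams)",
            age,
            result.reaction_force_top,
            mesh.n_beams,
        )
    return row


def run_study(config: PipelineConfig | str | Path) -> dict:
    """Run the full study; returns the report dict (also written to disk)."""
    cfg = (
        config
        if isinstance(config, PipelineConfig)
        else PipelineConfig.from_toml(config)
    )
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "study.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(getattr(logging, cfg.log_level.upper(), logging.INFO))
    try:
        rows = []
        for age in cfg.ages:
            try:
                rows.append(run_sample(age, cfg, out / f"sample_{age}"))
            except Exception as exc:
                raise RuntimeError(f"stage failure for sample age {age}: {exc}") from exc

        import pandas as pd

        table = pd.DataFrame(rows)
        report: dict = {"n_samples": len(rows), "config": asdict(cfg)}
        if cfg.run_simulation and len(rows) >= 3:
            forces = table["raw_force_uN"].to_numpy(dtype=float)
            table[FIRMNESS_COLUMN] = normalize_firmness(forces)
            cohort = table.drop(columns=["raw_force_uN"])
            cohort.to_csv(out / "cohort.csv", index=False)
            analysis = cohort_analysis(cohort)
            report["correlations"] = {
                col: _corr_to_dict(analysis["firmness_correlations"][col])
                for col in ARCHITECTURE_COLUMNS
            }
            report["age_correlation_firmness"] = _corr_to_dict(
                analysis["age_correlations"][FIRMNESS_COLUMN]
            )
        else:
            table.to_csv(out / "cohort.csv", index=False)

        write_metrics_json(out / "report.json", report)
        manifest = {
            "dermafiber_version": __version__,
            "numpy_version": np.__version__,
            "global_seed": cfg.seed,
            "per_sample_seeds": {a: (cfg.seed + 13 * a) % 2**31 for a in cfg.ages},
            "files": {
                str(p.relative_to(out)): _sha256(p)
                for p in sorted(out.rglob("*"))
                if p.is_file() and p.name != "manifest.json" and p.name != "study.log"
            },
        }
        write_metrics_json(out / "manifest.json", manifest)
        report["manifest"] = manifest
        return report
    finally:
        logger.removeHandler(handler)
        handler.close()
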