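# dermafiber

3D dermal elastin fiber architecture, embedded-beam finite-element
compression, and skin-firmness statistics.

Aged skin is measurably less firm. `dermafiber` implements, end to end, the
hypothesis that the **architecture** of the dermal elastin fiber network —
its fragmentation into clusters, the loss of vertically oriented fibers, and
fiber thinning — drives that mechanical change, not merely the amount of
elastin. The package provides:

- **Synthetic fiber networks** with controllable count, diameter, length,
  vertical-fiber fraction, waviness, connectivity, and enzymatic-style
  fragmentation, plus nine donor-age presets (ages 38–78) that reproduce a
  real cohort's architecture by construction (`dermafiber.synthetic`,
  `dermafiber.presets`).
- **Imaging emulation and processing**: rasterization to a confocal-like
  grayscale stack (blur + noise) and a full segmentation chain back to
  measured fibers — median filter, thresholding (Otsu or fixed), spherical
  morphology, surface smoothing, skeleton-based centerline tracing with
  junction-crossing continuation, and EDT-based local diameter estimation
  (`dermafiber.imaging`).
- **Architecture quantification**: mean fiber diameter, fiber count, elastin
  volume fraction, number of fiber clusters, maximum cluster size, and
  vertical fiber proportion, on a shared-node fiber graph
  (`dermafiber.fibers`).
- **Mechanics**: unconfined 20% compression of the fiber–matrix composite.
  The dermal matrix is a Saint Venant–Kirchhoff continuum (E = 80 kPa,
  nu = 0.48) on linear tetrahedra; fibers are geometrically nonlinear
  circular beams (E = 0.5 MPa) embedded by node sharing. The top-platen
  reaction force is the firmness surrogate (`dermafiber.mechanics`).
- **Statistics**: Pearson correlations with exact t-distribution p-values,
  Welch group comparisons, OLS regressions, and the packaged nine-donor
  cohort table (`dermafiber.stats`).
- **Orchestration**: a multi-sample study pipeline with per-stage artifacts,
  seeds, and a SHA-256 manifest, plus a CLI (`dermafiber.pipeline`,
  `dermafiber` console command).

Units are micrometre / micronewton / megapascal; **Y is the skin surface
normal and the compression axis**. See `docs/methods.md` for the model
details, numerical choices, and limitations.

## Worked example

Build the age-78 donor preset at 0.3 linear scale (fiber sizes stay
realistic; the box and counts shrink), voxelize it with noise and blur, and
write the fiber table and image stack:

```text
$ dermafiber generate --preset 78 --scale 0.3 --out fibers_78.csv \
    --tiff-out stack_78.tif --noise-sd 60 --blur-sigma 0.6
{
  "Mean Fiber Diameter (um)": 3.36,
  "Fiber Count": 29,
  "Elastin Volume Fraction (%)": 2.2055986166920944,
  "Number of Fiber Clusters": 2,
  "Maximum Cluster Size": 28,
  "Vertical Fiber Proportion (%)": 13.793103448275861
}
```

Segment the stack back into fibers and quantify the recovered architecture
(the domain is the scaled standard box, given as `XxZxH` in um):

```text
$ dermafiber segment --in stack_78.tif --out fibers_seg.csv --mask-out mask_78.tif
segmented 25 fibers

$ dermafiber quantify --fibers fibers_seg.csv --domain 103.071x29.925x45 \
    --out metrics_78.json
{
  "Mean Fiber Diameter (um)": 3.238601077410672,
  "Fiber Count": 25,
  "Elastin Volume Fraction (%)": 2.2667638461619326,
  "Number of Fiber Clusters": 5,
  "Maximum Cluster Size": 15,
  "Vertical Fiber Proportion (%)": 20.0
}
```

Run the 20% compression on the segmented network embedded in the matrix:

```text
$ dermafiber simulate --fibers fibers_seg.csv --domain 103.071x29.925x45 \
    --report sim_78.json
{
  "reaction_force_top_uN": 37.54280956708037,
  "nominal_top_traction_MPa": -0.012171836831450959,
  "n_beams": 89,
  "n_tets": 6804,
  "low_strain_fraction": 0.0007348618459729571,
  "converged": true,
  ...
}
```

(`n_dropped` in the embedding report counts sub-cell fiber segments whose
endpoints snap to the same mesh node; consecutive segments coarsen into the
kept beams, so fiber path length is preserved.)

Statistics on the packaged cohort:

```sh
dermafiber correlate --out stats.json
```

A full multi-sample study (generate → voxelize → segment → quantify →
simulate → correlate, with a checksummed manifest) runs from a TOML config:

```toml
# study.toml
[study]
output_dir = "study_out"
seed = 1234
ages = [38, 39, 43, 49, 58, 59, 67, 70, 78]
scale = 0.35
use_imaging = true
run_simulation = true
```

```sh
dermafiber run --config study.toml
```

The normalized reaction forces correlate positively with fiber count, volume
fraction, maximum cluster size, and vertical proportion, and negatively with
the number of fiber clusters — more fragmented, flatter networks are softer.

## Reproduction

- `python -m pytest -q tests/` runs the full suite, including one acceptance
  test per headline claim (cohort statistics, finite-element verification
  against closed-form and finite-difference oracles, clustering vs an
  independent union-find oracle, the imaging round trip, and the
  architecture–mechanics directional effects).
- `python scripts/acceptance.py --seed 1 --out results/acceptance.json`
  recomputes all headline quantities; every random draw derives from
  `--seed`, and reruns are bit-identical.
- Every study writes `manifest.json` with versions, per-sample seeds, and
  SHA-256 checksums of all artifacts; rerunning the same config reproduces
  every checksum.
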