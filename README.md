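# hullbsp

Convex-hull estimation of mammalian body segment parameters (BSPs) for
multibody dynamics analysis:

- **Exact mass properties** of watertight triangle meshes — mass, centre of
  mass, moments and products of inertia — via exact polyhedral
  face-projection integrals (`hullbsp.mass_properties`), with density
  rescaling.
- **Convex hulling** (Quickhull) of skeletal segment meshes and planar
  subdivision of elongate segments such as tails into equal-extent pieces
  (`hullbsp.hulling`).
- **A bundled calibration table** (130 published regression models: 13
  segments × 10 parameters, with 95% CIs) that converts naive hull BSPs
  into predicted soft-tissue BSPs, including left→right mirroring and
  optional axial zeroing (`hullbsp.segments_calibration`).
- **A fitting framework** to build new calibration tables from paired
  hull/soft observations: OLS and phylogenetic GLS under Brownian motion
  (λ = 1), AIC model selection, leave-one-out cross-validation RMSE
  (`hullbsp.calibration_fit`).
- **Synthetic data generators** — primitive paired skin/skeleton specimens,
  pure-birth trees, Brownian-correlated datasets, and a Monte-Carlo
  mass-property oracle (`hullbsp.synthetic_data`).

Units are SI throughout (meters, kilograms, kg m²). Axes follow the
anatomical convention: x craniocaudal, y mediolateral, z vertical.
Products of inertia are stored with the positive-integral convention
(Ixy = ρ∫xy dV); the assembled inertia tensor negates them. Mass and
moments of inertia are regressed on the log10 scale; all other parameters
linearly. The default density is 1000 kg m⁻³; use `rescale_density` for
other values (mass and inertia scale linearly, the CoM is unchanged).

## CLI

```bash
# exact BSPs of a mesh (OBJ / STL / PLY)
hullbsp compute segment.obj --density 1000 --format json

# convex hull of a skeletal segment
hullbsp hull skeleton.obj hull.obj

# split a tail into four equal-extent pieces along its principal axis
hullbsp split tail.obj parts/ -n 4 --axis auto

# naive hull BSPs + calibrated soft-tissue predictions (bundled table)
hullbsp predict skeleton.obj --segment left_thigh
hullbsp predict skull.obj --segment head --zero-axial

# fit a new calibration table from a paired dataset (optional phylogeny)
hullbsp calibrate pairs.csv table.csv --tree tree.nwk --report fits.csv

# generate a synthetic specimen set (meshes + manifest + tree)
hullbsp simulate out/ --n-species 8 --seed 42
```

Segment labels: `left_arm`, `right_forearm`, … for limbs; `head`, `neck`,
`torso`, `tail1`–`tail4` for axial segments. Exit codes: 0 success,
2 usage error, 3 data/validation error.

Paired-dataset CSV columns: `species, segment, side, parameter,
hull_value, soft_value` (one row per combination; right-side rows are
folded onto the left automatically before fitting).

## Layout

```
src/hullbsp/
  mesh_io.py               mesh container, OBJ/STL/PLY I/O, validation, generators
  mass_properties.py       exact polyhedral integrals, BSP vector, density rescale
  hulling.py               convex hull, hull BSPs, equal-extent splitting
  segments_calibration.py  segment taxonomy, bundled table, prediction, mirroring
  calibration_fit.py       OLS / PGLS-BM, AIC, LOOCV, table building
  synthetic_data.py        seeded generators + Monte-Carlo oracle
  cli.py                   click command group
  data/calibration_table.csv   the bundled 130-model table
tests/                     unit, property and acceptance suites (pytest)
scripts/acceptance.py      acceptance-target report
```
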