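# lumpsim

Finite-element simulation of breast cavity healing after breast-conserving
surgery (lumpectomy), coupling:

- **biochemical fields** — fibroblast density and cytokine concentration as
  reaction-diffusion equations with collagen-dependent (biphasic) cell
  migration;
- **microstructure** — local collagen deposition/degradation, plastic
  stretches along an evolving fiber frame, fiber reorientation toward the
  maximum principal stretch, and fiber dispersion dynamics;
- **mechanics** — quasi-static momentum balance with an anisotropic
  hyperelastic passive law (fiber dispersion, collagen-scaled stiffness),
  active (myo)fibroblast stress, logistic mechanosensing, and a
  multiplicative elastic/plastic split producing permanent contracture;

plus a Gaussian-process surrogate workflow (Latin-hypercube designs, RMSE
calibration with active refinement, sensitivity/CBVP/composition sweeps).

Two idealized geometries are built in: a human hemisphere breast
(radius 8.58 cm, spherical cavity radius 3.02 cm in the upper outer
quadrant, 2-cm chest wall) and a porcine half-ellipsoid breast
(a=b=2.32, c=2 cm; ellipsoidal cavity 1.5x1.5x0.6 cm at 1.15 cm depth)
embedded in a 15x15x2 cm connective-tissue slab. Meshing is a graded
structured tetrahedral grid with per-element region labels; no external
mesh generator is required.

## Command line

```bash
# coupled human run at desk scale, CSV scalars + manifest to out/
lumpsim simulate --geometry human --coarse --weeks 4 --out out/

# biochemical-only porcine submodel
lumpsim simulate --geometry porcine --bio-only --coarse --weeks 16 --out out/

# overrides: cavity size via CBVP, breast composition, VTU field output
lumpsim simulate --geometry human --coarse --cbvp 1.0 --fibro-fraction 0.15 \
    --weeks 4 --fields --out out/

# GP calibration stages (budget = initial LHS simulator runs)
lumpsim calibrate --stage bio --budget 16 --rounds 1 --seed 0 --out calib/
lumpsim calibrate --stage mechano --budget 16 --rounds 1 --seed 0 --out calib/

# sweep experiments (sensitivity contours, CBVP, breast composition)
lumpsim experiment --id sensitivity --out experiments/
lumpsim experiment --id cbvp_sweep --out experiments/

# labeled mesh export (ASCII VTU or Gmsh MSH 4.1)
lumpsim mesh --geometry human --out mesh.vtu
```

Runs are configurable through YAML files (`--config run.yaml`; see
`lumpsim.datasets.save_config` for the schema — geometry, biochemical,
microstructural, mechanical, and mechanobiological blocks plus solver
settings).

## Package layout

| module | contents |
| --- | --- |
| `lumpsim.fem` | P1 tetrahedral primitives, cached-sparsity assembly |
| `lumpsim.geometry` | geometry specs, graded tet meshing, region labels, VTU/MSH I/O |
| `lumpsim.constitutive` | kinematic split, passive/active stress, mechanosensing, rule of mixtures |
| `lumpsim.biochem` | fibroblast/cytokine sources, fluxes, implicit transport stepper |
| `lumpsim.microstructure` | collagen kinetics, plastic stretches, fiber frame, dispersion |
| `lumpsim.solver` | staggered coupled driver, Newton mechanics solve, summaries |
| `lumpsim.surrogate` | LHS designs, GP emulator, RMSE calibration, active refinement |
| `lumpsim.datasets` | packaged calibration tables, parameter defaults, YAML config I/O |
| `lumpsim.experiments` | figure-level experiment drivers |
| `lumpsim.cli` | `lumpsim` console entry point |

Units: lengths cm, time hours (outputs in weeks), stresses MPa, fibroblast
density cells/mm^3, cytokine and collagen normalized. Parameters whose
published source is a supplementary table are implemented as documented,
config-exposed stand-ins calibrated in-repo against the packaged datasets;
see the docstrings in `biochem.py`, `microstructure.py`, `constitutive.py`.
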