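# refplane

Reference-focal-plane calibration for brightfield microscopy using
control beads, and single-image prediction of defocus.

Image-based cell assays (for example trypan-blue viability counting)
are exquisitely sensitive to focus: the same cell can score live or dead
depending on the focal plane, and a stage's nominal Z readout is not
comparable across slides, days, or instruments.  `refplane` benchmarks
the Z axis with polystyrene control beads mixed into the sample:

1. **REFP estimation.** From a Z sweep of bead images it defines the
   *reference effective focal plane* (REFP) — the Z at which beads are
   most in focus.  Each detected bead is cropped to a 64 px tile, its
   continuous center found by minimizing the residuals of a cubic
   smoothing spline fit to intensity vs. distance-from-center, and two
   scale-free features extracted from the spline: the background-
   normalized steepest slope **SS** (most negative at focus) and center
   intensity **CI** (maximal at focus).  Median feature curves are pooled
   across exposures and fields of view by shift/scale alignment, and

   REFP = (REFP_SS + REFP_CI) / 2,

   where REFP_SS minimizes the fitted SS profile and REFP_CI maximizes
   the CI profile.
2. **ΔZ regression.** Bead tiles labeled ΔZ = z − REFP (µm; negative
   below the plane) train an ensemble of small convolutional regression
   networks.  A *single* new acquisition is then mapped to ΔZ_final by
   two-level robust averaging: per model, an IQR-trimmed mean over the
   bead predictions; then the mean over models.

Everything runs on synthetic bead fields with known ground truth
(`refplane.synth`), so the whole pipeline is testable end to end without
a microscope.  The CNN engine is a self-contained numpy implementation
(conv/batch-norm/residual blocks/Adam) — no deep-learning framework is
required.

## Worked example

```python
import numpy as np
from refplane import (OpticalModel, SweepSpec, simulate_sweep,
                      extract_sweep_features, estimate_refp, sweep_refp)

spec = SweepSpec(z_min=1462.5, z_max=1552.5, z_increment=7.5,
                 exposures=(6.0, 9.0, 12.0), n_fov=2, beads_per_fov=8,
                 true_refp=1507.5, seed=11)
images, manifest = simulate_sweep(spec, OpticalModel())
features, tiles = extract_sweep_features(images)
table, pooled = estimate_refp(features)
print(table[["exposure_ms", "fov", "refp_ss", "refp_ci", "refp_final"]].round(2))
print("sweep REFP:", sweep_refp(table))
```

prints one REFP per (exposure, FOV) curve and their median:

```
   exposure_ms  fov  refp_ss  refp_ci  refp_final
0          6.0    0  1508.03  1507.95     1507.99
1          6.0    1  1507.73  1507.95     1507.84
2          9.0    0  1507.95  1507.95     1507.95
3          9.0    1  1507.88  1508.03     1507.95
4         12.0    0  1507.88  1507.95     1507.91
5         12.0    1  1508.03  1507.95     1507.99
sweep REFP: 1507.95
```

The simulated focal plane was 1507.5 µm, so the pipeline recovers it to
0.45 µm — well inside the 7.5 µm repeatability of a typical stage
actuator — from noisy 8-bit images, with the six independent curves
agreeing to 0.15 µm.

The command line mirrors the pipeline (`refplane simulate | detect |
refp | train | predict | run`); `refplane run --config cfg.yaml --out
out/` chains all stages from a YAML file.

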