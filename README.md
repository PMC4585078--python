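# fourlink

Planar four-link hind-leg dynamics for analysing memory-guided obstacle
stepping: when a quadruped steps over a remembered barrier with a hind
leg, how much of the dependence of the toe's trajectory on its starting
position is pure limb mechanics, and how much is distance-specific neural
drive to the knee flexors?

`fourlink` implements the complete computational pipeline for that
question, for researchers in neuromechanics and motor control:

* a **four-link rigid-rod leg model** (thigh, shank, paw, toe; hip fixed).
  Per segment, three Newton–Euler equations
  (`f_x1 − f_x2 = mẍ`, `f_y1 − f_y2 − mg = mÿ`,
  `τ1 − τ2 + a sinθ (f_x1+f_x2) − a cosθ (f_y1+f_y2) = I θ̈`)
  plus two kinematic-chain equations give 20 linear equations in 20
  unknowns per time step, solved in **inverse** mode (torques from
  motion) or **forward** mode (motion from torques, fixed-step RK4);
* a **motion-capture pipeline**: knee triangulation, segment angles,
  zero-phase 10-Hz Butterworth filtering, 1-ms resampling, finite-
  difference derivatives, swing-onset detection, and the toe-trajectory
  slope (rise/run between 3 and 5 cm toe height);
* **EMG burst quantification** (rectify, 50-Hz low-pass, 150-ms
  integral from burst onset);
* the **fixed-command experiment**: drive every trial's initial geometry
  with one averaged long-distance torque profile and compare simulated
  with observed slopes;
* a **seeded synthetic-trial generator** that emulates the study —
  standing starts 5–25 cm behind the barrier, a shared motor command
  plus a knee flexion pulse growing linearly with proximity, EMG
  co-varying with the knee drive — so the whole pipeline is testable
  end-to-end with known ground truth.

## Worked example

```python
import numpy as np
from fourlink import (
    CohortSpec, make_default_cat_leg, generate_cohort, run_full_analysis,
)

geometry = make_default_cat_leg()          # 200/100/40/20 g, 10/11/5/2 cm
spec = CohortSpec(n_trials=30, seed=7)     # knee gain 0.08 N*m per m
trials, truths = generate_cohort(geometry, spec)
report = run_full_analysis(trials, geometry)

for name in ("actual_slope_vs_distance", "simulated_vs_actual_slope",
             "knee_tau0_vs_distance", "hip_tau0_vs_distance"):
    r = report.regressions[name]
    print(f"{name:28s} slope={r.slope:+.3f}  R^2={r.r_squared:.2f}  p={r.p_value:.1e}")
```

prints (seed 7):

```
actual_slope_vs_distance     slope=-21.096  R^2=0.38  p=2.6e-04
simulated_vs_actual_slope    slope=+0.186  R^2=0.66  p=6.0e-08
knee_tau0_vs_distance        slope=+0.087  R^2=0.26  p=4.0e-03
hip_tau0_vs_distance         slope=+0.101  R^2=0.10  p=8.7e-02
```

Reading: observed toe-trajectory slopes steepen sharply as the toe starts
closer to the barrier (negative slope on distance).  Fixed-command
simulations reproduce part of that steepening — mechanics alone bend the
trajectory the right way — but the regression of simulated on observed
slope sits well below the identity line (0.19 < 1), the signature of an
additional neural contribution.  Consistently, the initial knee flexion
torque grows significantly as distance shrinks (its fitted trend,
+0.087 N·m per metre, recovers the generator's commanded modulation gain
of 0.08), while the hip trend is not significant at the 5% level.

A command-line interface wraps the same steps:

```bash
fourlink synth --n-trials 30 --seed 7 --out cohort/
fourlink analyze --trials cohort/ --out results/ --plots
fourlink simulate --profile profile.csv --theta -1.2 -2.6 -1.5 -1.5 --out traj.csv
```

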