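# gpcrdimer

Quantification of G-protein-coupled receptor (GPCR) oligomers and their
effector coupling, built for studies that combine single-molecule
super-resolution imaging, rigid-body docking of receptor complexes, and
BRET (bioluminescence resonance energy transfer) assays — the workflow used
to characterize dopamine D2 receptor homodimers and their β-arrestin-2
bias.

The package covers three analysis stages, each testable against a
ground-truth simulator:

1. **Localization census** (`gpcrdimer.palm`).  PALM imaging of labelled
   cell-surface receptors yields (x, y) coordinates per detected emitter in
   a 7 × 7 µm region of interest.  The census discounts photoblinking
   duplicates (localizations within 20 nm of each other), groups the
   remaining receptors by fixed-radius neighborhood analysis (50 nm search
   radius, Getis–Franklin style, with each receptor discounted from further
   searches once assigned so nothing is double-counted), and tallies
   monomers / dimers / oligomers as a percentage of total receptors.  ROIs
   are stratified into high (>100 receptors/µm²) and low expression classes.
2. **Docking-pose post-processing** (`gpcrdimer.poses`).  Rigid-body docking
   poses of a probe protomer against a membrane-framed target are screened
   by the membrane-topology filter — tilt from the membrane normal ≤ 0.4 rad
   and |z-offset| of the geometric center ≤ 6.0 Å, applied to the best 4000
   poses by score — then leader-clustered at a 3 Å Cα RMSD cutoff (no
   re-superposition; the target fixes the frame).  Also included: interface
   residue contacts, the receptor–arrestin anchor filter (DRY arginine R132
   to finger-loop residue 71 Cα–Cα distance), arrestin Tilt/Rot indices, and
   heavy-atom steric-clash counting for stoichiometry checks.
3. **BRET quantification** (`gpcrdimer.bret`).  Net BRET (535/475 ratio
   minus donor-only control), one-site saturation fits
   `y = BRETmax·x/(BRET50 + x)`, one-phase association kinetics
   `y = plateau·(1 − e^(−kt))` with halftime `ln 2/k` and initial rate
   `k·span`, dose-response fits reported as −log₁₀ EC50, and the
   Emax/EC50 bias factor across signaling pathways.

`gpcrdimer.simulate` generates labelled synthetic inputs for all three
stages; `gpcrdimer.pipeline` and the `gpcrdimer` CLI tie them into
reproducible seeded runs.  Curve fits and clusterers follow scikit-learn
estimator conventions (`fit`, `predict`, trailing-underscore attributes),
so they compose with sklearn tooling; module-level functions wrap them for
one-call use.

## Worked example

```python
import numpy as np
from gpcrdimer import (
    PalmSimConfig, simulate_localizations, run_census,
    BretSimConfig, simulate_bret, fit_kinetics,
)

# a 7x7 um ROI with 50 monomers, 30 dimers, 15 trimers, 5 pentamers
cfg = PalmSimConfig(
    counts_per_size={1: 50, 2: 30, 3: 15, 5: 5},
    min_center_sep_nm=300.0, cluster_radius_nm=10.0,
    loc_error_sd_nm=5.0, blink_rate=0.0, seed=7,
)
loc_map, truth = simulate_localizations(cfg)
result, assignment, _ = run_census(loc_map, dedup=False)
print(f"{result.total_receptors} receptors at "
      f"{result.density_per_um2:.2f}/um2 ({result.density_class} density)")
print(f"monomers: {result.pct_monomer:.2f}%  associated: {result.pct_associated:.2f}%")
print("complexes by size:", result.count_by_size)

# a noisy beta-arrestin recruitment trace and its kinetic fit
data = simulate_bret(BretSimConfig(
    mode="kinetics", grid=tuple(np.arange(3.0, 303.0, 3.0)),
    k_per_s=0.02, plateau=0.05, noise_sd=0.002, seed=7,
))
fit = fit_kinetics(data["x"].to_numpy(), data["y"].to_numpy())
print(f"k = {fit.k_per_s:.4f} /s, plateau = {fit.plateau:.4f}, "
      f"halftime = {fit.halftime_s:.2f} s, initial rate = {fit.initial_rate:.3e}")
```

prints

```
180 receptors at 3.67/um2 (low density)
monomers: 27.78%  associated: 72.22%
complexes by size: {1: 50, 2: 30, 3: 15, 5: 5}
k = 0.0190 /s, plateau = 0.0501, halftime = 36.49 s, initial rate = 9.516e-04
```

The census recovers the configured composition exactly (180 receptors =
50 + 60 + 45 + 25; 50/180 = 27.78% monomeric), and the kinetic fit on a
single noisy trace lands near the simulated truth (k = 0.02 s⁻¹, plateau
0.05; halftime ln 2/k = 34.66 s) with the derived fields computed exactly
from the fitted parameters.

A full demo run of all three stages:

```sh
gpcrdimer pipeline run --config examples/demo_run.json --out runs/demo --seed 7
```

## Layout

```
src/gpcrdimer/
  simulate.py    ground-truth-labelled synthetic data for all stages
  palm.py        localization census (dedup, assignment, tallies, strata)
  poses.py       pose topology, RMSD clustering, contacts, clashes
  bret.py        net BRET, curve fits, bias factors
  structures.py  membrane-framed structure container (biotite-backed)
  pipeline.py    seeded end-to-end runs with a JSON report
  cli.py         the `gpcrdimer` command-line interface
docs/methods.md  models, conventions, defaults and their rationale
```
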