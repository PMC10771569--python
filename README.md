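# ireplan

Treatment planning and field-threshold inversion for multi-electrode
**irreversible electroporation (IRE)** in liver-tumor-mimicking hydrogel
phantoms.

IRE ablates tissue non-thermally: short high-voltage pulses permanently
permeabilize cell membranes wherever the local electric-field magnitude
exceeds a tissue-specific threshold `E_th`. Bench studies deliver pulse
trains through needle electrodes into cell-laden hydrogel discs, image the
live/dead outcome, and need two computations that this package provides:

1. **Forward planning** — given a geometry, electrode layout and an
   activation plan, predict the field distribution, the ablated
   area/volume as a function of the candidate threshold, and the fraction
   of a target (well or tumor) covered above `E_th`.
2. **Threshold inversion** — given measured ablation areas from imaging,
   find the field iso-level that encloses exactly the measured area, and
   pool replicates into an `E_th` estimate (mean ± SD). For Hep-G2
   hydrogels this procedure yields 544 ± 61 V/cm, versus the 800 V/cm
   reported in vivo for healthy liver.

## Model

Each pulse is treated quasi-statically: the potential obeys

```
∇ · (σ(|E|) ∇φ) = 0,   E = −∇φ
```

with Dirichlet data on the active needle pair (amplitude `V` on one,
ground on the other), zero normal current through the insulating well
wall, and conductivity that is either constant per region (calibrated
from an inter-electrode resistance readout, `σ = σ_ref · R(σ_ref)/R_meas`)
or a sigmoid of the local field, rising from σ₀ = 0.4 S/m to σ_f = 1.6 S/m
as electroporation progresses. The discretization is cell-centered finite
volumes on a regular grid with harmonic-mean face conductivities; the
nonlinear σ–E coupling is resolved by damped Picard iteration.

Multi-needle plans energize pairs **sequentially**; the cumulative
exposure at a point is the pointwise maximum field magnitude over the
activations. The ablation sweep counts cells at or above each candidate
threshold (area in 2D sections, volume in 3D tumor grids); reading the
sweep backwards converts a measured area into a per-sample threshold.

A synthetic-data module replaces the wet lab: noisy measured areas drawn
around the forward model under a known ground-truth threshold, bumpy
spherical-harmonic tumor masks standing in for CT segmentations,
resistance readouts, and binary live/dead z-stacks with a pixel-counting
measurement.

## Worked example

Two needles 0.8 cm apart in a 24-well hydrogel disc (190 mm², calibrated
conductivity 0.027 S/m), one 1100 V activation of 100 pulses at 1 Hz:

```python
import numpy as np
import ireplan as ip

geometry = ip.make_well_geometry(24, grid_spacing_cm=0.01,
                                 conductivity=ip.ConductivityModel.constant(0.027))
electrodes = ip.place_electrodes(geometry, "pair", 0.8)
plan = ip.ActivationPlan.uniform([("E1", "E2")], amplitude_V=1100.0, n_pulses=100)

cum = ip.run_plan(geometry, electrodes, plan)
sweep = ip.ablation_sweep(cum, 200.0, 1200.0, 1.0)
print(f"well area            : {geometry.region_measure_mm():.1f} mm^2")
print(f"treatment time       : {ip.treatment_time(plan):.0f} s")
print(f"ablated at 544 V/cm  : "
      f"{np.interp(544.0, sweep.thresholds_V_per_cm, sweep.ablated_measure):.1f} mm^2")
print(f"coverage at 544 V/cm : {ip.coverage_fraction(cum, 544.0):.3f}")
print(f"coverage at 800 V/cm : {ip.coverage_fraction(cum, 800.0):.3f}")

est = ip.threshold_recovery_experiment(
    geometry, electrodes, plan,
    true_threshold_V_per_cm=544.0, noise_cv=0.05, n_samples=9, seed=42)
print(f"recovered threshold  : {est.mean_V_per_cm:.1f} +/- {est.sd_V_per_cm:.1f} V/cm (n={est.n})")
```

prints

```
well area            : 189.7 mm^2
treatment time       : 100 s
ablated at 544 V/cm  : 83.1 mm^2
coverage at 544 V/cm : 0.441
coverage at 800 V/cm : 0.241
recovered threshold  : 549.8 +/- 18.8 V/cm (n=9)
```

The first block is the forward plan: 44% of the hydrogel sits above the
experimental Hep-G2 threshold and 24% above the in-vivo liver threshold.
The last line is the inverse problem run end-to-end on synthetic data:
nine noisy "measured" areas (5% CV) generated at a known 544 V/cm truth
are inverted back through the sweep, recovering the truth well within the
experimental 61 V/cm spread.

The same workflow is available from a shell via the `ireplan` CLI
(`plan`, `sweep`, `invert`, `simulate`, `recover`), configured by a TOML
file with unit-suffixed keys; every run writes a manifest with the config
hash and seed.

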