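# atrophysim

EEG forward modelling of cortical atrophy: how much scalp EEG power is lost
purely because an aging, shrinking brain sits farther from the electrodes
behind an expanding layer of cerebrospinal fluid (CSF)?

Large age-related EEG power reductions (up to 10-20 dB in the alpha band)
are usually read as evidence of weakened cortical currents. But cortical
atrophy also changes the volume conductor itself: the brain contracts, CSF —
the most conductive tissue in the head — fills the vacated space, and the
current dipoles move away from the scalp. `atrophysim` quantifies the purely
geometric/conductive part of the power loss so that the remainder can be
attributed to neural change. It is written for EEG methodologists and
computational neurophysiologists who work with forward models.

## Model

Cortical activity is represented as current dipoles normal to the cortical
surface inside a four-compartment piecewise-homogeneous volume conductor
(scalp, skull, CSF, brain; conductivities σ = 0.3, 0.006, 1.5, 0.3 S/m).
Two forward solvers map dipoles to scalp potentials:

* **Exact multilayer-sphere series** (`sphere_forward`). For a dipole at
  eccentricity x = b/R_brain the scalp potential is

  V = 1/(4π σ_brain R²_brain) Σₙ Gₙ xⁿ⁻¹ [ n m_r Pₙ(cos γ) + m_t P′ₙ(cos γ) ],

  where the per-degree transfer factors Gₙ propagate the interface
  conditions (continuity of V and of σ ∂V/∂r) through the shells; with one
  shell Gₙ = (2n+1)/n, the classical homogeneous-sphere result.

* **Linear-collocation BEM with the isolated source approach**
  (`bem_forward`) for realistic (non-spherical) heads, discretizing the
  Geselowitz double-layer equation on triangulated tissue boundaries with
  analytic element integrals, deflation, and the inner skull as isolation
  boundary. Validated against the series on meshed concentric spheres with
  the standard RDM/MAG error metrics.

Atrophy ("brain shrinkage") contracts the dipole cloud — and the brain/CSF
boundary — toward the median centroid of the sources by a fraction s, while
skull and scalp keep their dimensions. For an active patch of 20
equal-amplitude dipoles the attenuation at an electrode neighbourhood E is

  dB(s) = 10 log₁₀ ( mean_{e∈E} |Σ_{i∈patch} G⁰[e,i]|² / mean_{e∈E} |Σ_{i∈patch} Gˢ[e,i]|² ),

independent of the dipole amplitude. A conductivity-sensitivity sweep
recomputes dB(0.10) over the published CSF (1.2-1.8 S/m) and skull
(0.003-0.015 S/m) ranges on a 100×100 grid.

Because no MRI is shipped, a seeded synthetic head generator
(`make_synthetic_head`) stands in for segmentation: four nested surfaces
with a shared smooth spherical-harmonic shape perturbation, ~2500 cortical
dipoles normal to a source surface just beneath the pial boundary, and a
128-electrode equidistant montage with 4-7 neighbours per electrode.

## Worked example

```python
import numpy as np
from atrophysim import run_spherical_experiment, conductivity_grid

res = run_spherical_experiment()          # 0-30% shrinkage in 5% steps
for s, db in zip(res.shrink_levels, res.mean_db):
    print(f"shrink {100*s:4.0f}%  attenuation {db:5.2f} dB")

grid = conductivity_grid()                # 100x100 sigma grid at 10% shrink
print(f"conductivity can alter the 10% attenuation by "
      f"{grid.max_deviation:.2f} dB (grid spread {grid.spread:.2f} dB)")
```

prints

```
shrink    0%  attenuation  0.00 dB
shrink    5%  attenuation  2.58 dB
shrink   10%  attenuation  4.52 dB
shrink   15%  attenuation  6.08 dB
shrink   20%  attenuation  7.41 dB
shrink   25%  attenuation  8.57 dB
shrink   30%  attenuation  9.59 dB
conductivity can alter the 10% attenuation by 0.53 dB (grid spread 1.04 dB)
```

Even an implausibly severe 30% global shrinkage attenuates the overlying
electrode by less than 10 dB — far below the empirical age-related power
reductions — and the result is nearly insensitive to tissue-conductivity
uncertainty. The same experiment on the synthetic realistic head
(`run_realistic_experiment`, seed 1, BEM at icosphere subdivision 3) gives
2.0 dB at 5% and 3.5 dB at 10% shrinkage while the mean CSF thickness grows
from 5.0 mm to 8.9 and 12.8 mm.

A CLI mirrors the library: `atrophysim shrink --config run.yaml`,
`atrophysim sensitivity --config run.yaml`, `atrophysim make-head`,
`atrophysim validate-bem` (sphere-oracle RDM/MAG table).

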