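# vascmrf

MR vascular fingerprinting in Python: estimate sub-voxel microvascular
properties — blood volume fraction (BVf, %), mean vessel radius (R, µm),
blood oxygen saturation (SO₂, %) and T₂ (ms) — from pre/post-contrast
GESFIDSE signal evolutions, by simulating fingerprint dictionaries over
explicit vascular geometries and inverting acquisitions against them.

It is aimed at MR physicists and methods researchers who want a
self-contained, deterministic simulation/reconstruction chain for
vascular-fingerprinting experiments: voxel-scale geometry generators (2D
disks, 3D isotropic cylinders, stochastic vascular networks), a Fourier
dipole-kernel field solver, an isochromat Bloch simulator with diffusion, a
dictionary builder with Sobol parameter sampling, and two reconstruction
back-ends.

## The model in brief

A voxel's vessels carry a susceptibility offset

    Δχ = Δχ_deoxy · Hct · (1 − SO₂/100) + Δχ_CA ,

which induces a field offset via the dipole kernel in Fourier space,
`δω(k) = γB₀ (1/3 − k_z²/|k|²) χ(k)` (periodic, k = 0 dropped). The GESFIDSE
response (32 gradient echoes, ΔTE 3.3 ms, spin echo at 60 ms, B₀ 4.7 T) is
simulated by stepping the magnetization grid: phase accrual `exp(iδω dt)`,
T₂ decay, and a Gaussian diffusion kernel of width √(2·ADC·dt) convolved
with the magnetization each step; an ideal 180° pulse conjugates the phase
at 30 ms. Pre- and post-contrast signals are concatenated and L2-normalized
into one fingerprint per voxel.

Reconstruction is either **DBM** (dot-product matching: the best dictionary
entry's parameters win) or **DBL** (Gaussian locally-linear mapping: a joint
Gaussian-mixture inverse regression fit to the dictionary by EM, predicting
posterior means — it interpolates between simulated parameter values where
DBM snaps to the grid). Estimates are clipped to physical ranges (BVf, SO₂
to [0, 100] %; R to [0, 250] µm; T₂ to ≥ 0).

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
import numpy as np
from vascmrf import (make_cylinder_voxel, characterize_voxel,
                     SusceptibilityState, vessel_field, SimPhysics,
                     SequenceSpec, simulate_gesfidse)
from vascmrf.geometry import fixed_radius
from vascmrf.dictionary import default_dictionary_grid

grid = default_dictionary_grid("cylinder3d")   # 48x48x72 @ 3.875 µm
voxel = make_cylinder_voxel(grid, fixed_radius(5.0), target_bvf=3.0, seed=1)
characterize_voxel(voxel)
print(f"BVf {voxel.bvf:.2f}%  R {voxel.mean_radius:.2f} µm")

state = SusceptibilityState(so2=70.0, dchi_ca=0.5)   # post-contrast
fmap = vessel_field(voxel, state)
seq = SequenceSpec(dt_sim_ms=None)
sig = simulate_gesfidse(fmap, SimPhysics(t2_ms=70.0), seq)
print(f"first echo {sig[0]:.4f}   spin-echo region {sig[17]:.4f}   "
      f"last echo {sig[31]:.4f}")
```

prints

```
BVf 2.96%  R 5.33 µm
first echo 0.9419   spin-echo region 0.3264   last echo 0.1184
```

i.e. the generator hit the 3 % blood-volume target within its tolerance
band (the measured min-Feret radius of a rasterized 5 µm cylinder
population reads slightly high), and the signal shows susceptibility
dephasing on top of T₂ decay with partial spin-echo recovery near 60 ms
(0.3264 vs. a pure-T₂ value of 0.428 at 59.4 ms — the shortfall is the
diffusion-mediated, non-refocusable part of the vascular dephasing).

A full demo pipeline (dictionary → phantom units → DBM/DBL maps → ROI
t-tests) runs from one config:

```bash
vascmrf run --out demo_run --seed 0
```

writing `dictionary.h5`, per-unit map NIfTIs, `roi_means.csv` and
`roi_stats.csv` (tumor-vs-contralateral two-sample t-tests on per-unit ROI
means). The `geom`, `dict`, `recon`, `phantom` and `stats` subcommands
expose the individual stages.

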