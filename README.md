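# softcells

Agent-based simulation and analysis of a dense, **non-confluent 2D
tissue**: N polydisperse soft deformable disks with Hertzian repulsion
and active noise in a periodic box. The package exists to study a
striking rheological behaviour of such tissues: the effective shear
viscosity η̄ grows super-exponentially with packing fraction ϕ
(Vogel–Fulcher–Tammann-like, as in glass-forming liquids) — and then
**saturates** above a critical packing fraction ϕ_S ≈ 0.90 instead of
diverging. The explanation is geometric: because soft cells of very
different sizes can interpenetrate, the *available free area* per cell
stops shrinking at high ϕ, and the dynamics stops slowing down.

It is aimed at computational biophysicists who want to reproduce,
probe, or extend that mechanism: every piece — the simulator, g(r),
the self-intermediate scattering function and relaxation times, the
Green–Kubo viscosity with its spline + stretched-exponential splicing,
the periodic-Voronoi free-area analysis, and the VFT / KWW / Gaussian
master-curve fits — is an importable, tested component with a thin CLI
on top.

## Model in brief

Cell i is a disk of fixed radius R_i. Overlapping cells (overlap
h_ij = max(0, R_i + R_j − r_ij) > 0) repel with the Hertzian force

    F_ij = h_ij^{3/2} / [ (3/2)((1−ν²)/E) √(1/R_i + 1/R_j) ] ,

and each cell moves by overdamped, athermal dynamics

    ṙ_i = F_i/(γ0 R_i) + µ W_i(t) ,

with delta-correlated active noise W. Defaults (Δt = 10 s, µ = 0.045,
γ0 = 0.1 kg/(µm·s), E = 10⁻³ MPa, ν = 0.5, N = 500, radii spanning a
factor ~8 with mean 8.5 µm) are the reference tissue conditions; see
`docs/methods.md` for units, the radius-distribution calibration, and
every numerical choice.

Key observables:

- **g(r)** — liquid-like structure; its first peak r_max ≈ mean cell
  diameter sets the probing wavevector q = 2π/r_max.
- **Fs(q,t)** and **τα** — structural relaxation; Fs(q,τα) = 1/e.
- **η̄ = ∫ dt Σ⟨P_µν(t)P_µν(0)⟩** — Green–Kubo effective viscosity
  from the off-diagonal virial stress (reduced units).
- **ϕ_free** — frame-averaged positive part of A_i − πR_i² over the
  box area, from a periodic Voronoi tessellation: the free-area
  fraction whose saturation explains the viscosity plateau.

## Worked example

```python
import numpy as np
import softcells as sc

params = sc.SimParams(n_cells=500, target_phi=0.93, rng_seed=7,
                      n_steps_grow=5_000, n_steps_equil=100_000,
                      n_steps_prod=30_000, save_every=1_000)
traj = sc.run_simulation(params)          # ~40 s with the jitted kernels

g = sc.pair_correlation(traj, bin_width=0.5)
print(f"g(r) first peak: {sc.first_peak_position(g):.2f} um")

frames = sc.voronoi_frames(traj)
print(f"phi_free: {sc.free_area_fraction(frames):.3f}")

q = 2 * np.pi / sc.first_peak_position(g)
fs = sc.self_intermediate_scattering(traj, q)
tau = sc.relaxation_time(fs)
print("tau_alpha:", "unrelaxed" if tau is None else f"{tau:.3g} s")
```

Output from this exact script (seed 7):

```
g(r) first peak: 13.87 um
phi_free: 0.221
tau_alpha: unrelaxed
```

Read: at ϕ = 0.93 the packing is liquid-like in structure — g(r) has a
single broad, flat-topped hump spanning roughly 13–17 µm (the range of
typical cell-contact diameters; for a single run the reported first
peak can land anywhere on that top, and replicate averaging centres
it). About 22% of the box is still available as positive free area
despite only 7% being uncovered — soft-disk overlap creates the
difference. And the system is deep in the glassy regime: within this
3·10⁵ s production window Fs(q,t) never falls below 1/e, so τα is
censored as "unrelaxed" rather than reported as a number.

The same analyses are available from the shell:

```bash
softcells simulate --phi 0.93 --seed 7 --out run93.h5
softcells gr --traj run93.h5 --out gr.csv
softcells freearea --traj run93.h5 --out afree.csv
softcells viscosity --traj run93.h5 --out acf.csv
softcells sweep --phis 0.75,0.80,0.85 --replicates 3 --seed 0 --out-prefix sweep
```

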