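# raftdyn

Simulation and quantification of membrane nanodomain dynamics: spot-variation
fluorescence correlation spectroscopy (svFCS) diffusion laws and fluorescence
recovery after photobleaching (FRAP), driven by a particle-level Monte Carlo
model of probe diffusion in a raft-containing plasma membrane.

## The problem

Raft nanodomains are small (< 100 nm), short-lived sterol/sphingolipid
assemblies in the plasma membrane that transiently trap partitioning
molecules (sphingomyelin, GPI-anchored proteins such as Thy-1, flotillin
scaffolds). They are far below the diffraction limit, so their effect is
measured indirectly through the *dynamics* of fluorescent probes:

* **svFCS** measures the mean dwell time τ_d of a probe in a Gaussian
  confocal spot at several spot sizes (waist ω). For free Brownian motion
  τ_d = ω²/(4D), a line through the origin. Transient trapping adds a
  size-independent offset, giving the *diffusion law*

      τ_d(ω²) = t₀ + ω² / (4·D_eff)

  with intercept t₀ > 0 for nanodomain trapping, t₀ < 0 for
  meshwork/cytoskeleton hindrance and t₀ ≈ 0 for free diffusion, and an
  effective diffusion coefficient D_eff = 1/(4·slope).

* **FRAP** bleaches a circular region (here 2.5 µm diameter) and fits the
  normalized recovery with the uniform-disk 2D-diffusion (Soumpasis) form
  F(t) = M·e^(−2τ_D/t)[I₀(2τ_D/t) + I₁(2τ_D/t)], yielding the half-time
  t₁/₂ ≈ 0.8946·τ_D and the mobile fraction M.

`raftdyn` implements the full chain as tested, reproducible code: a Monte
Carlo simulator of diffusion with transient trapping in circular
nanodomains, a virtual confocal detector and multi-tau correlator, the 2D
ACF model fit, the diffusion-law regression with regime classification, a
FRAP generator/fitter, and per-condition presets emulating erythroid-cell
experimental groups (control, MPP1 knockdown, rescue, sterol/sphingolipid
depletion) for both raft-partitioning and non-raft probes. Measured curves
can be analyzed from plain CSV files.

## Worked example

```bash
python examples/diffusion_law_roundtrip.py
```

```
SM_control    t0 =  9.34 ± 0.88 ms   D_eff = 1.16 ± 0.08 µm²/s   regime = trapped
SM_KnD        t0 =  3.10 ± 0.97 ms   D_eff = 0.68 ± 0.03 µm²/s   regime = trapped

control / knockdown confinement ratio: 3.01
```

Per-cell diffusion times are drawn from each condition's ground-truth
diffusion law (4 waists of 0.20–0.35 µm, 15 cells, 15 % cell-to-cell
variability), the law is refitted, and the intercepts are compared: the
sphingomyelin probe loses roughly two-thirds of its confinement when the
raft-organizing scaffold protein is depleted. `examples/` also contains
`particle_simulation_acf.py` (the microscopic chain: trajectories → photon
trace → multi-tau ACF → τ_d, which matches ω²/4D within a few percent) and
`frap_quantification.py` (a photobleaching cohort with half-times and
mobile fractions).

A thin CLI wraps the same functions for shell use:

```bash
raftdyn svfcs run --condition SM_control --seed 1
raftdyn svfcs law-fit my_taus.csv        # waist_um, tau_d_ms[, tau_d_sem_ms]
raftdyn fcs fit-acf my_acf.csv           # lag_s, g[, g_err]
raftdyn frap fit my_recovery.csv         # time_s, intensity (bleach at t=0)
raftdyn report compare --conditions SM_control,SM_KnD
```

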