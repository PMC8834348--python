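# Experimental-condition presets.
#
# law:  ground-truth diffusion-law parameters (intercept t0 in ms, effective
#       diffusion coefficient in um^2/s) with their reported uncertainties,
#       used by the law-level generator for fast round-trip experiments.
# frap: ground-truth FRAP recovery parameters (half-time in s, mobile
#       fraction in percent) for the photobleaching conditions.
# sim:  microscopic Monte Carlo parameters (tuned once; see docs/methods.md).
#       Lengths um, times s, diffusion um^2/s.  Trapping strength is ordered
#       Thy1_control > SM_control > SM_rescue > SM_ZA_Myr >~ SM_KnD, and the
#       PC (non-raft lipid) presets have no effective trapping.

version: 1

defaults:
  box_um: 3.0
  n_particles: 40
  radius_um: 0.04
  burn_in_s: 0.5

conditions:
  SM_control:
    law: {t0_ms: 10.25, t0_sem_ms: 1.43, d_eff: 1.18, d_eff_sem: 0.09}
    sim: {d_out: 1.7, d_in: 0.2, p_enter: 0.024, p_escape: 0.02,
          area_fraction: 0.20, dt_s: 3.0e-5}
  SM_KnD:
    law: {t0_ms: 3.71, t0_sem_ms: 2.44, d_eff: 0.68, d_eff_sem: 0.06}
    sim: {d_out: 1.1, d_in: 0.3, p_enter: 0.018, p_escape: 0.08,
          area_fraction: 0.07, dt_s: 4.5e-5}
  SM_ZA_Myr:
    law: {t0_ms: 4.77, t0_sem_ms: 1.08, d_eff: 0.81, d_eff_sem: 0.04}
    sim: {d_out: 1.2, d_in: 0.25, p_enter: 0.02, p_escape: 0.05,
          area_fraction: 0.10, dt_s: 4.0e-5}
  SM_rescue:
    law: {t0_ms: 8.28, t0_sem_ms: 1.46, d_eff: 1.01, d_eff_sem: 0.07}
    sim: {d_out: 1.55, d_in: 0.2, p_enter: 0.022, p_escape: 0.024,
          area_fraction: 0.17, dt_s: 3.2e-5}
  PC_control:
    law: {t0_ms: 1.04, t0_sem_ms: 2.49, d_eff: 1.09, d_eff_sem: 0.12}
    sim: {d_out: 1.09, d_in: 1.09, p_enter: 0.0, p_escape: 1.0,
          area_fraction: 0.0, dt_s: 5.0e-5, burn_in_s: 0.1, box_um: 6.0,
          n_particles: 60}
  PC_KnD:
    law: {t0_ms: 2.18, t0_sem_ms: 2.04, d_eff: 1.15, d_eff_sem: 0.15}
    sim: {d_out: 1.15, d_in: 1.15, p_enter: 0.0, p_escape: 1.0,
          area_fraction: 0.0, dt_s: 5.0e-5, burn_in_s: 0.1, box_um: 6.0,
          n_particles: 60}
  Thy1_control:
    law: {t0_ms: 22.26, t0_sem_ms: 2.37, d_eff: 1.42, d_eff_sem: 0.26}
    sim: {d_out: 1.8, d_in: 0.18, p_enter: 0.028, p_escape: 0.015,
          area_fraction: 0.22, dt_s: 2.7e-5}
  Thy1_KnD:
    law: {t0_ms: 13.21, t0_sem_ms: 1.85, d_eff: 0.79, d_eff_sem: 0.06}
    sim: {d_out: 1.2, d_in: 0.2, p_enter: 0.022, p_escape: 0.03,
          area_fraction: 0.15, dt_s: 4.0e-5}
  Flot2_control:
    frap: {t_half_s: 13.7, t_half_sd_s: 4.51, mobile_fraction_pct: 42.13,
           mobile_fraction_sd: 4.01}
    sim: {d_out: 0.40, d_in: 0.08, p_enter: 0.024, p_escape: 0.02,
          area_fraction: 0.20, dt_s: 1.0e-4}
  Flot2_KnD:
    frap: {t_half_s: 11.26, t_half_sd_s: 3.55, mobile_fraction_pct: 41.74,
           mobile_fraction_sd: 4.15}
    sim: {d_out: 0.45, d_in: 0.15, p_enter: 0.02, p_escape: 0.07,
          area_fraction: 0.08, dt_s: 1.0e-4}
  Flot2_MbCD:
    frap: {t_half_s: 10.9, t_half_sd_s: 3.49, mobile_fraction_pct: 42.0,
           mobile_fraction_sd: 3.97}
    sim: {d_out: 0.46, d_in: 0.2, p_enter: 0.018, p_escape: 0.10,
          area_fraction: 0.05, dt_s: 1.0e-4}
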