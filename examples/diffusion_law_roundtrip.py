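"""Law-level svFCS round trip: control vs MPP1-knockdown sphingomyelin.

Draws per-cell diffusion times from each condition's ground-truth diffusion
law (4 spot waists, 15 cells, 15 % cell-to-cell noise), refits the law, and
compares the recovered confinement intercepts.  A positive t0 means the
probe is transiently trapped in raft nanodomains; the knockdown condition
should show a roughly three-fold smaller t0.
"""

from raftdyn import ExperimentSpec, compare_conditions, run_svfcs_experiment

reports = []
for condition in ("SM_control", "SM_KnD"):
    report = run_svfcs_experiment(ExperimentSpec(condition=condition, seed=7))
    law = report.law
    print(f"{condition:12s}  t0 = {law.t0:5.2f} ± {law.t0_sem:4.2f} ms   "
          f"D_eff = {law.d_eff:4.2f} ± {law.d_eff_sem:4.2f} µm²/s   "
          f"regime = {law.regime}")
    reports.append(report)

table = compare_conditions(reports)
ratio = table.loc[1, "t0_ratio_vs_first"]
print(f"\ncontrol / knockdown confinement ratio: {ratio:.2f}")
print("(values fluctuate around the generating parameters 10.25 and "
      "3.71 ms; the ratio sits near 2.8, the loss of confinement on "
      "MPP1 depletion)")
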