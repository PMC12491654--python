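"""Entropy production and regime classification on synthetic cohorts.

Simulates both cohorts at the default calibration, runs the full
pipeline, and prints each group's thermodynamic verdict: flow, force,
entropy production rate (EPR), excess entropy production (EEP) and the
near- vs far-from-equilibrium classification.
"""
import myothermo as mt

cfg = mt.RunConfig(seed=7)
samples, points, truths = mt.simulate_cohorts(cfg)
res = mt.analyze(samples, points, cfg)

for group, rec in res["groups"].items():
    s = rec["summaries"]
    print(f"--- {group} (n = {rec['n']}) ---")
    print(f"  thermodynamic flow  v0:   {s['flow'].mean:8.3f} +- {s['flow'].sd:.3f} 1/s")
    print(f"  thermodynamic force Eo/T: {s['force'].mean:8.4f} +- {s['force'].sd:.4f} Lo mN/K")
    print(f"  EPR  y  = force*flow:     {s['epr'].mean:8.4f} +- {s['epr'].sd:.4f}")
    print(f"  EEP  y' = d(EPR)/d(ts):   {s['eep'].mean:8.3f} (mean of trend derivative)")
    print(f"  regime: {rec['regime'].regime.value} "
          f"(lack-of-fit p = {rec['regime'].lack_of_fit_p:.3f})")
    print()

cae = res["groups"]["caesarean"]
hys = res["groups"]["hysterectomy"]
print("Interpretation:")
print(f"  EPR is {hys['mean_epr'] / cae['mean_epr']:.1f}x higher outside "
      "pregnancy: the non-pregnant muscle dissipates far more.")
print(f"  EEP sign: caesarean {cae['mean_eep_fit']:+.3f} (stable, near "
      f"equilibrium), hysterectomy {hys['mean_eep_fit']:+.3f} (negative -")
print("  the prerequisite for self-organization into a dissipative structure).")
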