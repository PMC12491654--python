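"""From macroscopic mechanics to molecular crossbridge kinetics.

Runs the two-state sliding-filament model forward at the two cohorts'
mean rate constants, then demonstrates the inversion: a force-velocity
curve sampled like the experiment is turned back into attachment and
detachment rates, turnover, unitary force and peak efficiency.
"""
import numpy as np

import myothermo as mt
import myothermo.huxley as hx

cfg = mt.RunConfig(seed=0)

for label, rates, MC in [
    ("term caesarean", mt.HuxleyRates(2.3, 1.0, 6.9), 2.2),
    ("non-pregnant hysterectomy", mt.HuxleyRates(2.6, 3.9, 2.6), 2.7),
]:
    # forward: normalized force-velocity curve of the model
    v, p, v_cb_max = mt.force_velocity(rates)

    # emulate the protocol (zero-load clamp, afterloads, isometric), refit
    TT = 25.0
    rel = np.array(hx.PROTOCOL_REL_LOADS)
    umax = hx._u_max(rates.r)
    vel = np.array([hx._u_at_load(rates.r, q, umax) for q in rel]) \
        * rates.phi / cfg.L_ref
    fit = mt.fit_hill(rel * TT, vel, TT=TT)
    rec = mt.fit_rates(rel * TT, vel, TT, cfg, partition=rates.F1)
    kin = mt.molecular_outputs(rec, fit, cfg, MC_input=MC)

    print(f"--- {label} mean kinetics ---")
    print(f"  input rates f1={rates.f1}, g1={rates.g1}, g2={rates.g2} 1/s")
    print(f"  recovered   f1={rec.f1:.3f}, g1={rec.g1:.3f}, g2={rec.g2:.3f} 1/s"
          "   (round trip through the measured curve)")
    print(f"  unloaded sliding velocity: {v_cb_max:8.2f} nm/s")
    print(f"  fitted macroscopic curvature G: {fit.G:.3f}")
    print(f"  time stroke ts = h/v_cb_max: {kin.ts:.3f} s")
    print(f"  kcat = {kin.kcat:.4f} 1/s, ATPase = kcat*MC = {kin.atpase:.4f} nmol/g/s")
    print(f"  unitary crossbridge force po = {kin.po:.2f} pN")
    print(f"  peak mechanical efficiency = {kin.eff_max:.1f} %")
    print()

print("The slow, high-curvature term kinetics are the more efficient and")
print("more economical motor; the fast non-pregnant kinetics cycle and")
print("hydrolyse ATP several times faster for less mechanical output.")
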