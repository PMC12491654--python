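"""Fit the Hill force-velocity hyperbola to one muscle strip.

Builds nine noise-free afterloaded points on a hyperbola with the
term-pregnant cohort's mean parameters (Vmax = 0.034 Lo/s, curvature
G = 2.14, isometric tension TT = 28.3 mN/mm^2), refits with TT fixed,
and prints the recovered parameters.
"""
import numpy as np

import myothermo as mt

load, vel = mt.hyperbola_points(Vmax=0.034, G=2.14, TT=28.3,
                                rel_loads=[0, .1, .2, .3, .4, .5, .6, .7, 1.0])
fit = mt.fit_hill(load, vel, TT=28.3)

print("Hill fit of a term-cohort mean force-velocity curve")
print(f"  a  = {fit.a:.4f} mN/mm^2   (load asymptote; TT/a = curvature)")
print(f"  b  = {fit.b:.6f} Lo/s     (velocity asymptote)")
print(f"  Vmax = {fit.Vmax:.4f} Lo/s  (zero-load clamp velocity)")
print(f"  G  = {fit.G:.4f}           (dimensionless curvature)")
print(f"  rss = {fit.rss:.2e}        (exact fit on noise-free data)")
print(f"  velocity at half the isometric load: "
      f"{mt.hill_velocity(fit, 14.15):.6f} Lo/s")
print()
print("G = Vmax/b = TT/a summarizes how curved, and hence how economical,")
print("the force-velocity relation is: higher G means slower, thriftier myosin.")
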