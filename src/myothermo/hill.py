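"""Hill hyperbola fitting for afterloaded force-velocity data.

The empirical force-velocity relation of a fully activated muscle is the
rectangular hyperbola ``(V + b)(iT + a) = b(TT + a)``, where ``iT`` is
the afterload (isotonic tension), ``V`` the steady shortening velocity,
``TT`` the isometric tension and ``-a``, ``-b`` the asymptotes.  The
dimensionless curvature ``G = Vmax/b = TT/a`` summarizes the shape:
higher G means a more curved, more economical muscle.

``TT`` is measured independently (fully isometric contraction) and is
held fixed during fitting; residuals are taken in velocity because the
afterload is the experimentally controlled variable.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares


class HillFitError(RuntimeError):
    """Degenerate data or non-convergence during Hill fitting."""


@dataclass(frozen=True)
class HillFit:
    """Fitted Hill hyperbola for one muscle sample.

    ``G = Vmax/b = TT/a`` holds by construction (Vmax is computed as the
    zero-load velocity ``b*TT/a``).
    """

    a: float           # mN/mm^2
    b: float           # Lo/s
    Vmax: float        # Lo/s, velocity extrapolated to zero load
    TT: float          # mN/mm^2, measured isometric tension (fixed)
    G: float           # dimensionless curvature
    rss: float         # sum of squared velocity residuals, (Lo/s)^2
    n_points: int

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("Hill asymptotes a, b must be positive")


def hill_velocity(fit: HillFit, load) -> np.ndarray | float:
    """Velocity predicted by the hyperbola at the given afterload(s).

    ``V = b (TT - load) / (load + a)``; V(0) = Vmax, V(TT) = 0.
    """
    load_arr = np.asarray(load, dtype=float)
    if np.any(load_arr < -1e-12) or np.any(load_arr > fit.TT * (1 + 1e-9)):
        raise ValueError("load outside [0, TT]")
    v = fit.b * (fit.TT - load_arr) / (load_arr + fit.a)
    return float(v) if np.isscalar(load) else v


def _linearized_start(load: np.ndarray, vel: np.ndarray, TT: float):
    """Starting values from the linearized transform.

    (TT - iT)/V = (iT + a)/b is linear in iT with slope 1/b and
    intercept a/b.  Zero-velocity points carry no information here and
    are dropped from the transform only.
    """
    m = vel > 0
    if m.sum() >= 2:
        yy = (TT - load[m]) / vel[m]
        slope, intercept = np.polyfit(load[m], yy, 1)
        if slope > 0 and intercept > 0:
            b0 = 1.0 / slope
            a0 = intercept * b0
            return a0, b0
    # fallback: moderate curvature G = 4
    return TT / 4.0, float(np.max(vel, initial=0.0)) / 4.0 or 1.0


def fit_hill(load, velocity, TT: float) -> HillFit:
    """Least-squares Hill fit with TT fixed.

    Parameters
    ----------
    load, velocity:
        Afterload (mN/mm^2) and steady shortening velocity (Lo/s) of the
        afterloaded contractions, including the zero-load clamp point.
    TT:
        Measured isometric tension; must dominate every afterload.

    Returns
    -------
    HillFit
        Estimates of (a, b) minimizing squared velocity residuals,
        with ``Vmax = b*TT/a`` and ``G = Vmax/b = TT/a``.
    """
    load = np.asarray(load, dtype=float)
    vel = np.asarray(velocity, dtype=float)
    if load.shape != vel.shape or load.ndim != 1:
        raise ValueError("load and velocity must be 1-D and equally long")
    if load.size < 4:
        raise HillFitError(f"need >= 4 force-velocity points, got {load.size}")
    if TT <= 0:
        raise ValueError("TT must be positive")
    if np.max(load) > TT * (1 + 1e-6):
        raise ValueError("afterload exceeds isometric tension TT")
    if np.all(vel <= 0):
        raise HillFitError("all velocities zero: degenerate force-velocity data")

    a0, b0 = _linearized_start(load, vel, TT)

    def resid(theta):
        la, lb = theta
        a, b = np.exp(la), np.exp(lb)
        return b * (TT - load) / (load + a) - vel

    sol = least_squares(
        resid,
        x0=[np.log(a0), np.log(b0)],
        method="lm",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
        max_nfev=2000,
    )
    if not sol.success:
        raise HillFitError(f"Hill fit did not converge: {sol.message}")
    a, b = np.exp(sol.x)
    rss = float(np.sum(sol.fun ** 2))
    vmax = b * TT / a
    return HillFit(
        a=float(a),
        b=float(b),
        Vmax=float(vmax),
        TT=float(TT),
        G=float(TT / a),
        rss=rss,
        n_points=int(load.size),
    )


def hyperbola_points(Vmax: float, G: float, TT: float, rel_loads) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free (load, velocity) points on a stated Hill hyperbola.

    Convenience for simulation and round-trip tests: builds the
    hyperbola with ``b = Vmax/G`` and ``a = TT/G`` and evaluates it at
    ``rel_loads * TT``.
    """
    if Vmax <= 0 or G <= 0 or TT <= 0:
        raise ValueError("Vmax, G, TT must be positive")
    rel = np.asarray(rel_loads, dtype=float)
    a = TT / G
    b = Vmax / G
    load = rel * TT
    vel = b * (TT - load) / (load + a)
    return load, vel
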