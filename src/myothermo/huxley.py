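"""Two-state sliding-filament crossbridge model (Huxley 1957 kinetics).

A crossbridge at strain ``x`` (distance of its actin site from the
zero-strain position, nm) attaches with rate ``f(x) = f1*x/h`` and
detaches with rate ``g(x) = g1*x/h`` on the working range ``0 <= x <= h``;
beyond ``h`` no attachment occurs, and for ``x < 0`` (drag region) the
detachment rate is the constant ``g2``.  During steady shortening at
filament velocity ``v`` (nm/s) the attached fraction ``n(x)`` obeys

    -v dn/dx = f(x) (1 - n) - g(x) n,

which integrates in closed form.  Everything macroscopic follows from
``n``: force is the spring moment ``integral n(x) * k x dx``, the ATP
turnover is the attachment flux (one ATP per cycle), and mechanical
efficiency is their ratio.

The normalized force-velocity curve depends on the rate constants only
through the single shape ratio ``r = (f1 + g1) / g2`` and on velocity
through ``u = v / phi`` with ``phi = (f1 + g1) h / 2``; this is what
makes the macroscopic Hill curvature invertible to molecular kinetics.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .config import RunConfig
from .hill import HillFit, fit_hill

__all__ = [
    "HuxleyRates",
    "CrossbridgeKinetics",
    "InversionError",
    "attached_fraction",
    "force_ratio",
    "force_velocity",
    "model_curvature",
    "invert_from_hill",
    "fit_rates",
    "molecular_outputs",
    "efficiency_curve",
]

#: relative-afterload grid used both by the emulated experimental
#: protocol and by the model-curve curvature fit; keeping them identical
#: makes the rate inversion bias-free for protocol-generated data.
PROTOCOL_REL_LOADS = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 1.0)


class InversionError(RuntimeError):
    """Macroscopic curvature outside the invertible range of the model."""


@dataclass(frozen=True)
class HuxleyRates:
    """Attachment/detachment rate constants (s^-1) and geometry (nm)."""

    f1: float
    g1: float
    g2: float
    h: float = 11.0
    ell: float = 36.0

    def __post_init__(self):
        if min(self.f1, self.g1, self.g2) <= 0:
            raise ValueError("all rate constants must be positive")
        if not 0 < self.h <= self.ell:
            raise ValueError("need 0 < h <= ell")

    @property
    def F1(self) -> float:
        """Isometric attached fraction f1/(f1+g1)."""
        return self.f1 / (self.f1 + self.g1)

    @property
    def phi(self) -> float:
        """Velocity scale (f1+g1)*h/2 in nm/s."""
        return (self.f1 + self.g1) * self.h / 2.0

    @property
    def r(self) -> float:
        """Dimensionless shape ratio (f1+g1)/g2."""
        return (self.f1 + self.g1) / self.g2


@dataclass(frozen=True)
class CrossbridgeKinetics:
    """Molecular quantities derived for one sample."""

    rates: HuxleyRates
    po: float          # pN, unitary crossbridge force
    ts: float          # s, time stroke h / v_cb_max
    kcat: float        # s^-1, isometric ATP turnover per crossbridge
    MC: float          # nmol/g, myosin content
    atpase: float      # nmol/g/s, kcat * MC
    eff_max: float     # %, peak mechanical efficiency
    v_cb_max: float    # nm/s, unloaded crossbridge sliding velocity


# ---------------------------------------------------------------------------
# attached fraction and closed-form force
# ---------------------------------------------------------------------------

def attached_fraction(rates: HuxleyRates, v: float, x=None):
    """Steady-state attached fraction ``n(x)`` at sliding velocity ``v``.

    Closed form: on ``0 <= x <= h``,
    ``n = F1 (1 - exp((f1+g1)(x^2 - h^2) / (2 h v)))``; for ``x < 0``,
    ``n = n(0) exp(g2 x / v)``; zero beyond ``h``.  At ``v = 0`` the
    kinetic fixed point gives ``n = F1`` on ``(0, h]``.

    Returns ``(x, n)`` arrays; default grid spans ``[-2h, h]``.
    """
    if v < 0:
        raise ValueError("sliding velocity must be >= 0")
    h = rates.h
    if x is None:
        x = np.linspace(-2 * h, h, 601)
    x = np.asarray(x, dtype=float)
    n = np.zeros_like(x)
    F1 = rates.F1
    if v == 0:
        n[(x > 0) & (x <= h)] = F1
        return x, n
    fg = rates.f1 + rates.g1
    mid = (x >= 0) & (x <= h)
    n[mid] = F1 * -np.expm1(fg * (x[mid] ** 2 - h ** 2) / (2 * h * v))
    n0 = F1 * -np.expm1(-fg * h / (2 * v))
    neg = x < 0
    n[neg] = n0 * np.exp(rates.g2 * x[neg] / v)
    return x, n


def force_ratio(r: float, u) -> np.ndarray | float:
    """Normalized crossbridge force ``P(v)/P0`` at reduced velocity ``u = v/phi``.

    ``P/P0 = 1 - u (1 - e^{-1/u}) (1 + r^2 u / 2)``; the drag term
    ``r^2 u / 2`` is the negative-strain contribution controlled by g2.
    """
    if isinstance(u, (int, float)):  # fast scalar path for root finding
        if u < 0:
            raise ValueError("reduced velocity must be >= 0")
        if u == 0:
            return 1.0
        w = u * -math.expm1(-1.0 / u)
        return 1.0 - w * (1.0 + r ** 2 * u / 2.0)
    u_arr = np.asarray(u, dtype=float)
    if np.any(u_arr < 0):
        raise ValueError("reduced velocity must be >= 0")
    out = np.ones_like(u_arr)
    pos = u_arr > 0
    up = u_arr[pos]
    w = up * -np.expm1(-1.0 / up)
    out[pos] = 1.0 - w * (1.0 + r ** 2 * up / 2.0)
    return out


def _u_max(r: float) -> float:
    """Root of the normalized force: reduced unloaded velocity."""
    hi = 1.0
    while force_ratio(r, hi) > 0:
        hi *= 2.0
        if hi > 1e9:  # pragma: no cover
            raise RuntimeError("unloaded-velocity bracket failed")
    return brentq(lambda u: force_ratio(r, u), hi / 2.0 if force_ratio(r, hi / 2.0) > 0 else 1e-12, hi,
                  xtol=1e-15, rtol=1e-12)


def _u_at_load(r: float, p: float, umax: float) -> float:
    """Reduced velocity at relative load ``p`` (P/P0 = p)."""
    if p >= 1.0:
        return 0.0
    if p <= 0.0:
        return umax
    return brentq(lambda u: force_ratio(r, u) - p, 1e-15, umax, xtol=1e-15, rtol=1e-12)


def force_velocity(rates: HuxleyRates, n_points: int = 200):
    """Normalized force-velocity curve and unloaded sliding velocity.

    Returns ``(v, p, v_cb_max)``: velocities in nm/s, ``p = P(v)/P0``,
    and the unique root of ``P(v) = 0`` in nm/s.
    """
    umax = _u_max(rates.r)
    u = np.linspace(0.0, umax, n_points)
    p = force_ratio(rates.r, u)
    return u * rates.phi, p, umax * rates.phi


# ---------------------------------------------------------------------------
# curvature of the model curve and inversion from the Hill fit
# ---------------------------------------------------------------------------

def model_curvature(r: float, rel_loads=PROTOCOL_REL_LOADS) -> float:
    """Hill curvature G of the model's normalized force-velocity curve.

    The model curve is evaluated at the protocol's relative afterloads
    and fitted with the Hill hyperbola (TT = 1 fixed); G of that fit is
    the macroscopic curvature the model predicts for shape ratio ``r``.
    """
    umax = _u_max(r)
    loads = np.asarray(rel_loads, dtype=float)
    vels = np.array([_u_at_load(r, p, umax) for p in loads])
    return fit_hill(loads, vels, TT=1.0).G


@lru_cache(maxsize=8)
def _curvature_table(rel_loads=PROTOCOL_REL_LOADS, n: int = 241):
    """Monotone table of G(r) over log10 r in [-3, 3] for fast bracketing."""
    log_r = np.linspace(-3.0, 3.0, n)
    G = np.array([model_curvature(10.0 ** lr, rel_loads) for lr in log_r])
    return log_r, G


def _solve_shape_ratio(G_target: float, rel_loads=PROTOCOL_REL_LOADS) -> float:
    log_r, G = _curvature_table(tuple(rel_loads))
    # G(r) is strictly decreasing in r
    if not (G.min() < G_target < G.max()):
        raise InversionError(
            f"curvature G={G_target:.4g} outside invertible range "
            f"[{G.min():.4g}, {G.max():.4g}] for r in [1e-3, 1e3]"
        )
    idx = int(np.searchsorted(-G, -G_target))
    lo, hi = 10.0 ** log_r[max(idx - 1, 0)], 10.0 ** log_r[min(idx, len(log_r) - 1)]
    if lo == hi:
        return lo
    try:
        return brentq(lambda r: model_curvature(r, rel_loads) - G_target, lo, hi,
                      xtol=1e-12, rtol=1e-10)
    except ValueError as exc:  # bracket lost in the flat (non-Hill-like) regime
        raise InversionError(
            f"curvature G={G_target:.4g} falls in the degenerate flat region "
            f"of the model curve (bracket [{lo:.4g}, {hi:.4g}]): {exc}"
        ) from exc


def invert_from_hill(fit: HillFit, cfg: RunConfig,
                     partition: Optional[float] = None) -> HuxleyRates:
    """Molecular rate constants reproducing a sample's Hill fit.

    Three constraints identify the rates:

    1. *shape*: ``r = (f1+g1)/g2`` solves ``G_model(r) = G_sample``;
    2. *scale*: ``phi = (f1+g1) h / 2`` makes the model's unloaded
       velocity equal ``Vmax * L_ref`` (nm/s);
    3. *partition*: ``f1/(f1+g1)`` is not constrained by the normalized
       curve and is supplied by ``partition`` (default from config).

    Deterministic given (fit, cfg, partition).
    """
    if fit.G <= 0 or fit.Vmax <= 0:
        raise ValueError("need G > 0 and Vmax > 0 to invert")
    part = cfg.partition if partition is None else partition
    if not 0 < part < 1:
        raise ValueError("partition must be in (0, 1)")
    r = _solve_shape_ratio(fit.G)
    umax = _u_max(r)
    v_cb_max = fit.Vmax * cfg.L_ref
    phi = v_cb_max / umax
    fg = 2.0 * phi / cfg.h
    return HuxleyRates(f1=part * fg, g1=(1.0 - part) * fg, g2=fg / r,
                       h=cfg.h, ell=cfg.ell)


def fit_rates(load, velocity, TT: float, cfg: RunConfig,
              partition: Optional[float] = None) -> HuxleyRates:
    """Molecular rates by least-squares matching of the full curve.

    The curvature-match inversion (:func:`invert_from_hill`) is only
    well-posed while the model curve is Hill-like (shape ratio
    ``r = (f1+g1)/g2`` below ~1.3); beyond that the fitted Hill
    curvature saturates near zero and carries no information about
    ``r``.  This fitter instead matches the model's force-velocity
    curve to the measured points directly: for each candidate ``r`` the
    model velocities at the measured relative loads are computed, the
    optimal velocity scale ``phi`` follows in closed form, and ``r``
    minimizes the squared velocity residuals.  Well-posed for every
    ``r`` in [1e-3, 1e3]; reduces to the curvature match on Hill-like
    data.
    """
    loads = np.asarray(load, dtype=float)
    vel = np.asarray(velocity, dtype=float)
    if loads.size < 4:
        raise InversionError("need >= 4 points to fit molecular rates")
    if TT <= 0 or np.max(loads) > TT * (1 + 1e-6):
        raise ValueError("need 0 < loads <= TT")
    if np.all(vel <= 0):
        raise InversionError("all velocities zero: no kinetics to fit")
    part = cfg.partition if partition is None else partition
    if not 0 < part < 1:
        raise ValueError("partition must be in (0, 1)")
    rel = np.clip(loads / TT, 0.0, 1.0)

    def rss_and_scale(log_r: float):
        r = 10.0 ** log_r
        umax = _u_max(r)
        u = np.array([_u_at_load(r, p, umax) for p in rel])
        denom = float(u @ u)
        phi = float(u @ vel) / denom if denom > 0 else 0.0
        if phi <= 0:
            return float(vel @ vel), 0.0
        resid = phi * u - vel
        return float(resid @ resid), phi

    grid = np.linspace(-3.0, 3.0, 25)
    rss = [rss_and_scale(lr)[0] for lr in grid]
    k = int(np.argmin(rss))
    lo, hi = grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]
    res = minimize_scalar(lambda lr: rss_and_scale(lr)[0], bounds=(lo, hi),
                          method="bounded", options={"xatol": 1e-10})
    log_r = float(res.x)
    _, phi = rss_and_scale(log_r)
    if phi <= 0:
        raise InversionError("force-velocity points admit no positive velocity scale")
    r = 10.0 ** log_r
    fg = 2.0 * phi * cfg.L_ref / cfg.h  # phi was in Lo/s; convert to nm/s
    return HuxleyRates(f1=part * fg, g1=(1.0 - part) * fg, g2=fg / r,
                       h=cfg.h, ell=cfg.ell)


# ---------------------------------------------------------------------------
# energetics
# ---------------------------------------------------------------------------

def _cycling_factor(F1: float, u) -> np.ndarray:
    """Attachment flux relative to f1*h/(2*ell): (1-F1) + F1*w(u)."""
    u_arr = np.asarray(u, dtype=float)
    w = np.zeros_like(u_arr)
    pos = u_arr > 0
    w[pos] = u_arr[pos] * -np.expm1(-1.0 / u_arr[pos])
    return (1.0 - F1) + F1 * w


def cycling_rate(rates: HuxleyRates, v: float) -> float:
    """ATP turnover per crossbridge site (s^-1) at sliding velocity v (nm/s).

    One ATP per attachment event: ``(1/ell) * integral f(x) (1 - n) dx``.
    At v = 0 this is the catalytic constant kcat.
    """
    u = v / rates.phi
    return float(rates.f1 * rates.h / (2.0 * rates.ell) * _cycling_factor(rates.F1, u))


def _efficiency_of_u(rates: HuxleyRates, cfg: RunConfig, u) -> np.ndarray:
    """Mechanical efficiency (fraction) at reduced velocity u.

    power out = force * v with force the crossbridge spring moment;
    power in = e_atp * attachment flux.  Both per actin site, so the
    site spacing cancels.
    """
    e_pn_nm = cfg.e_atp * 1e21  # J -> pN nm
    u_arr = np.asarray(u, dtype=float)
    ratio = force_ratio(rates.r, u_arr)
    num = cfg.k_cb * rates.h ** 2 / (2.0 * e_pn_nm) * u_arr * ratio
    return num / _cycling_factor(rates.F1, u_arr)


def efficiency_curve(rates: HuxleyRates, cfg: RunConfig, n_points: int = 200):
    """Efficiency vs velocity; returns ``(v, eff_percent, eff_max_percent)``.

    Efficiency vanishes at both ends (no power at v = 0, no force at
    v_cb_max) and peaks at an interior velocity.
    """
    umax = _u_max(rates.r)
    u = np.linspace(0.0, umax, n_points)
    eff = _efficiency_of_u(rates, cfg, u)
    guess = u[int(np.argmax(eff))]
    lo = max(guess - 2 * umax / n_points, 1e-12)
    hi = min(guess + 2 * umax / n_points, umax)
    res = minimize_scalar(lambda uu: -_efficiency_of_u(rates, cfg, uu),
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-12})
    eff_max = float(-res.fun)
    return u * rates.phi, eff * 100.0, eff_max * 100.0


def molecular_outputs(rates: HuxleyRates, fit: HillFit, cfg: RunConfig,
                      MC_input: Optional[float] = None) -> CrossbridgeKinetics:
    """All per-sample molecular quantities.

    * ``kcat = [f1 g1 / (2 (f1+g1))] * (h/ell)`` — isometric cycling rate
      per crossbridge scaled by actin site spacing;
    * ``po = F1 * k_cb * h/2`` — mean spring force of the attached
      isometric population (mean extension h/2, attached fraction F1);
    * ``ts = h / v_cb_max`` — duration of one stroke at unloaded speed;
    * ``MC`` — assayed content when given, else derived from isometric
      tension via the configured geometric factor;
    * ``atpase = kcat * MC`` exactly.
    """
    umax = _u_max(rates.r)
    v_cb_max = umax * rates.phi
    ts = rates.h / v_cb_max
    kcat = rates.f1 * rates.g1 / (2.0 * (rates.f1 + rates.g1)) * (rates.h / rates.ell)
    po = rates.F1 * cfg.k_cb * rates.h / 2.0
    if MC_input is not None:
        if MC_input < 0:
            raise ValueError("myosin content must be >= 0")
        MC = float(MC_input)
    else:
        if cfg.kappa_geom is None:
            raise ValueError(
                "myosin content absent and kappa_geom unset: cannot derive MC"
            )
        MC = fit.TT * cfg.kappa_geom / po
    _, _, eff_max = efficiency_curve(rates, cfg)
    return CrossbridgeKinetics(
        rates=rates, po=po, ts=ts, kcat=kcat, MC=MC,
        atpase=kcat * MC, eff_max=eff_max, v_cb_max=v_cb_max,
    )
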