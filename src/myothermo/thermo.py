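"""Entropy-production statistics for muscle cohorts.

A contracting muscle is an open thermodynamic system.  Its generalized
*flow* is the crossbridge cycling/sliding rate ``v0`` and its
generalized *force* is ``Eo/T`` with ``Eo = 4.24 * MC^2`` a quadratic
function of myosin content.  Their product is the entropy production
rate ``y = EPR = (1/T) Eo v0``; the time derivative of ``y`` along the
stroke-duration axis is the excess entropy production ``y' = EEP``.
Positive EEP means the stationary state is thermodynamically stable;
negative EEP is the prerequisite for self-organization into a
dissipative structure.

A cohort is *near equilibrium* when flow varies linearly with force and
*far from equilibrium* when that linearity breaks down.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .huxley import CrossbridgeKinetics

__all__ = [
    "EO_COEFF",
    "Regime",
    "ThermoState",
    "RegimeVerdict",
    "thermo_force",
    "thermo_flow",
    "epr",
    "classify_regime",
    "eep_from_trend",
    "eep_deviation",
]

#: coefficient of the quadratic force law Eo = 4.24 * MC^2 (Lo mN per (nmol/g)^2)
EO_COEFF = 4.24


class Regime(str, Enum):
    NEAR = "near_equilibrium"
    FAR = "far_from_equilibrium"


@dataclass(frozen=True)
class ThermoState:
    """Per-sample thermodynamic state."""

    v0: float                    # s^-1, thermodynamic flow
    Eo: float                    # Lo mN
    force: float                 # Lo mN / K, Eo/T
    epr: float                   # Lo mN / (K s), y = force * v0
    T: float                     # K
    eep_fit: Optional[float] = None   # y' from the cohort trend derivative
    eep_dev: Optional[float] = None   # (1/T) dEo dv0 deviation product
    stable: Optional[bool] = None     # eep_fit > 0


@dataclass(frozen=True)
class RegimeVerdict:
    """Linearity verdict for one cohort's force-flow relation."""

    group: str
    regime: Regime
    slope: float
    intercept: float
    rss: float
    lack_of_fit_p: float
    alpha: float


def thermo_force(MC: float, T: float) -> tuple[float, float]:
    """Generalized force from myosin content: ``Eo = 4.24 MC^2``, force = Eo/T."""
    if T <= 0:
        raise ValueError("absolute temperature must be positive")
    if MC < 0:
        raise ValueError("myosin content must be >= 0")
    Eo = EO_COEFF * MC ** 2
    return Eo, Eo / T


def thermo_flow(kin: CrossbridgeKinetics) -> float:
    """Thermodynamic flow ``v0``.

    Identified with the slow detachment rate constant g1 (s^-1): the
    cohort "flow" statistics coincide numerically with g1 in both
    groups, making g1 the detachment-limited cycling rate that plays
    the role of the crossbridge sliding flow.
    """
    return kin.rates.g1


def epr(force: float, v0: float) -> float:
    """Entropy production rate ``y = force * v0``."""
    return force * v0


def classify_regime(force: Sequence[float], v0: Sequence[float],
                    alpha: float = 0.05, group: str = "") -> RegimeVerdict:
    """Linear-vs-power lack-of-fit test on a cohort's force-flow relation.

    Fits ordinary least squares ``v0 = slope*force + intercept`` and the
    two-parameter power law ``v0 = A * force^b`` (log-log OLS), then
    compares their residual variances on the log scale with an F-type
    ratio.  A systematically curved relation leaves the straight line
    with inflated log residuals and a small p; the cohort is then far
    from equilibrium.
    """
    f = np.asarray(force, dtype=float)
    v = np.asarray(v0, dtype=float)
    if f.size != v.size or f.ndim != 1:
        raise ValueError("force and v0 must be 1-D and equally long")
    n = f.size
    if n < 5:
        raise ValueError(f"regime classification needs >= 5 samples, got {n}")
    if np.any(f <= 0) or np.any(v <= 0):
        raise ValueError("force and flow must be positive for the log-scale test")

    slope, intercept = np.polyfit(f, v, 1)
    pred_lin = slope * f + intercept
    rss_raw = float(np.sum((v - pred_lin) ** 2))
    # log-scale residuals; non-positive linear predictions are clamped and
    # penalize the linear model, as they should
    tiny = 1e-12 * float(np.max(v))
    rss_lin = float(np.sum((np.log(v) - np.log(np.clip(pred_lin, tiny, None))) ** 2))

    bpow, loga = np.polyfit(np.log(f), np.log(v), 1)
    rss_pow = float(np.sum((np.log(v) - (loga + bpow * np.log(f))) ** 2))

    dof = n - 2
    if rss_pow <= 0:
        p = 0.0 if rss_lin > 0 else 1.0
    else:
        F = (rss_lin / dof) / (rss_pow / dof)
        p = float(sps.f.sf(F, dof, dof))
    regime = Regime.NEAR if p >= alpha else Regime.FAR
    return RegimeVerdict(group=group, regime=regime, slope=float(slope),
                         intercept=float(intercept), rss=rss_raw,
                         lack_of_fit_p=p, alpha=alpha)


def eep_from_trend(ts: Sequence[float], y: Sequence[float], regime: Regime,
                   degree: int = 2) -> np.ndarray:
    """Per-sample EEP as the derivative of the cohort EPR(ts) trend.

    Far-from-equilibrium cohorts follow a power law ``y = A ts^beta``
    (log-log least squares); near-equilibrium cohorts are fitted with a
    polynomial of the given degree (default quadratic, so the derivative
    can itself rise linearly with ts).  Returns ``dy/dts`` evaluated at
    each sample's ts.
    """
    t = np.asarray(ts, dtype=float)
    yy = np.asarray(y, dtype=float)
    if t.size != yy.size or t.size < 4:
        raise ValueError("need >= 4 (ts, y) samples")
    if regime == Regime.FAR:
        if np.any(t <= 0) or np.any(yy <= 0):
            raise ValueError("power-law trend requires positive ts and y")
        beta, logA = np.polyfit(np.log(t), np.log(yy), 1)
        A = np.exp(logA)
        return A * beta * t ** (beta - 1.0)
    if degree not in (1, 2):
        raise ValueError("trend degree must be 1 or 2")
    coeffs = np.polyfit(t, yy, degree)
    return np.polyval(np.polyder(coeffs), t)


def eep_deviation(Eo: float, v0: float, Eo_star: float, v0_star: float,
                  T: float) -> float:
    """Deviation-product EEP: ``(1/T) (Eo - Eo*) (v0 - v0*)``.

    Positive when force and flow deviate from the stationary state on
    the same side (stable); negative deviations of opposite sign mark
    the unstable, self-organizing side.
    """
    if T <= 0:
        raise ValueError("absolute temperature must be positive")
    return (Eo - Eo_star) * (v0 - v0_star) / T
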