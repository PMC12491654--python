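"""One-parameter phase equation and bifurcation analysis of the EPR.

From cohort (y, y') pairs — entropy production rate and its excess —
a quadratic regression of y on y' rearranges into the one-dimensional
autonomous equation

    y' = a_lin (y_inf - y) - b_quad y'^2 .

Substituting the empirical power law ``y'^2 = A_pow G^beta`` (with G the
Hill curvature) yields the one-parameter form

    y' = a_lin (y_inf - y) - k_comb G^beta ,   k_comb = b_quad A_pow ,

whose steady state ``y*(G) = y_inf - (k_comb/a_lin) G^beta`` traces the
bifurcation diagram: a near-flat plateau at high curvature (economical,
near-equilibrium regime) turning sharply as G drops through ~1 into the
steep far-from-equilibrium branch.

The phase diagram itself is the parabola ``b_quad y'^2 + y' =
a_lin (y_inf - y)``; its two branches merge at a vertex where the fixed
point is half-stable (attracting on one side, repelling on the other).
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "PhaseModel",
    "FixedPointReport",
    "Branch",
    "Stability",
    "fit_phase_equation",
    "fit_eep_power_law",
    "combine",
    "steady_state_branch",
    "phase_curve",
    "phase_vertex",
    "classify_fixed_point",
    "bifurcation_diagram",
]


class Branch(str, Enum):
    UPPER = "upper"
    LOWER = "lower"
    VERTEX = "vertex"


class Stability(str, Enum):
    ATTRACTING = "attracting"
    REPELLING = "repelling"
    HALF_STABLE = "half_stable"


@dataclass(frozen=True)
class PhaseModel:
    """Coefficients of the reconstructed phase equation."""

    a_lin: float                  # s^-1 linear relaxation coefficient
    y_inf: float                  # EPR asymptote
    b_quad: float                 # inverse-EEP quadratic coefficient
    A_pow: float = float("nan")   # EEP^2 power-law amplitude
    beta: float = float("nan")    # EEP^2 power-law exponent (negative)
    k_comb: float = float("nan")  # b_quad * A_pow

    @property
    def has_parameter(self) -> bool:
        return np.isfinite(self.k_comb)


@dataclass(frozen=True)
class FixedPointReport:
    y_star: float
    lam: float                    # slope of the phase map at y_star
    classification: Stability
    branch: Branch


def fit_phase_equation(y: Sequence[float], yprime: Sequence[float]) -> PhaseModel:
    """Quadratic regression of y on y', rearranged to the phase equation.

    Least squares ``y = c0 + c1 y' + c2 y'^2`` gives
    ``a_lin = -1/c1``, ``y_inf = c0``, ``b_quad = c2/c1``.
    """
    yy = np.asarray(y, dtype=float)
    yp = np.asarray(yprime, dtype=float)
    if yy.size != yp.size or yy.size < 6:
        raise ValueError("need >= 6 (y, y') pairs")
    if np.unique(yp).size < 4:
        raise ValueError("rank-deficient regression: need >= 4 distinct y' values")
    c2, c1, c0 = np.polyfit(yp, yy, 2)
    if c1 == 0:
        raise ValueError("vertical parabola (c1 = 0): cannot rearrange to y' = f(y)")
    return PhaseModel(a_lin=-1.0 / c1, y_inf=float(c0), b_quad=float(c2 / c1))


def fit_eep_power_law(G: Sequence[float], yprime_sq: Sequence[float]) -> tuple[float, float]:
    """Log-log least squares of ``y'^2 = A G^beta``; returns (A, beta)."""
    g = np.asarray(G, dtype=float)
    q = np.asarray(yprime_sq, dtype=float)
    if g.size != q.size or g.size < 2:
        raise ValueError("need >= 2 (G, y'^2) points")
    if np.any(g <= 0) or np.any(q <= 0):
        raise ValueError("power-law fit requires positive G and y'^2")
    beta, logA = np.polyfit(np.log(g), np.log(q), 1)
    return float(np.exp(logA)), float(beta)


def combine(model: PhaseModel, A_pow: float, beta: float) -> PhaseModel:
    """Attach the power law and form the one-parameter coefficient."""
    return replace(model, A_pow=float(A_pow), beta=float(beta),
                   k_comb=float(model.b_quad * A_pow))


def steady_state_branch(model: PhaseModel, G) -> np.ndarray | float:
    """Steady state of the one-parameter equation.

    ``y*(G) = y_inf - (k_comb/a_lin) G^beta``; as G -> infinity (with
    beta < 0) the steady state approaches y_inf.
    """
    if not model.has_parameter:
        raise ValueError("model has no combined parameter; call combine() first")
    g = np.asarray(G, dtype=float)
    if np.any(g <= 0):
        raise ValueError("curvature parameter G must be positive")
    y = model.y_inf - (model.k_comb / model.a_lin) * g ** model.beta
    return float(y) if np.isscalar(G) else y


def phase_vertex(model: PhaseModel) -> tuple[float, float]:
    """Branch-merging point of the phase parabola.

    ``y_v = y_inf + 1/(4 a_lin b_quad)``, ``y'_v = -1/(2 b_quad)``.
    """
    if model.b_quad == 0:
        raise ValueError("linear phase model has no vertex")
    return (model.y_inf + 1.0 / (4.0 * model.a_lin * model.b_quad),
            -1.0 / (2.0 * model.b_quad))


def _discriminant(model: PhaseModel, y) -> np.ndarray:
    return 1.0 + 4.0 * model.b_quad * model.a_lin * (model.y_inf - np.asarray(y, float))


def phase_curve(model: PhaseModel, y: float) -> list[float]:
    """Real roots y' of ``b_quad y'^2 + y' - a_lin (y_inf - y) = 0``.

    Returns 0, 1 or 2 roots, upper branch first.  With b_quad = 0 the
    equation is linear and has the single root ``a_lin (y_inf - y)``.
    """
    if model.b_quad == 0:
        return [model.a_lin * (model.y_inf - y)]
    disc = float(_discriminant(model, y))
    if disc < 0:
        return []
    s = np.sqrt(disc)
    upper = (-1.0 + s) / (2.0 * model.b_quad)
    lower = (-1.0 - s) / (2.0 * model.b_quad)
    return [upper] if disc == 0 else [upper, lower]


def _branch_value(model: PhaseModel, y, branch: Branch) -> np.ndarray:
    """y'(y) on one branch; analytic continuation past the vertex keeps
    the real part -1/(2 b_quad) so sign probes remain defined there."""
    if model.b_quad == 0:
        return model.a_lin * (model.y_inf - np.asarray(y, float))
    disc = _discriminant(model, y)
    s = np.sqrt(np.clip(disc, 0.0, None))
    sign = 1.0 if branch in (Branch.UPPER, Branch.VERTEX) else -1.0
    return (-1.0 + sign * s) / (2.0 * model.b_quad)


def classify_fixed_point(model: PhaseModel, y_star: float,
                         branch: Branch = Branch.UPPER,
                         eps: float = 1e-6) -> FixedPointReport:
    """Stability of a fixed point from the sign pattern of the phase map.

    Evaluates y'(y) on the stated branch at ``y_star +- eps_abs`` with
    ``eps_abs = eps * max(1, |y_star|)``: (+,-) attracting, (-,+)
    repelling, equal signs half-stable.  lambda is the central-difference
    slope.  For branches other than the vertex, a probe window that
    crosses the branch-merging point raises, since the branch is not
    defined there.
    """
    e = eps * max(1.0, abs(y_star))
    if model.b_quad != 0 and branch != Branch.VERTEX:
        y_v, _ = phase_vertex(model)
        at_vertex = abs(y_star - y_v) < 1e-12 * max(1.0, abs(y_star))
        if (y_star - e <= y_v <= y_star + e) and not at_vertex:
            raise ValueError(
                f"probe window [{y_star - e:.6g}, {y_star + e:.6g}] crosses the "
                f"branch boundary at y_v = {y_v:.6g}; shrink eps"
            )
    left = float(_branch_value(model, y_star - e, branch))
    right = float(_branch_value(model, y_star + e, branch))
    lam = (right - left) / (2.0 * e)
    sl, sr = np.sign(left), np.sign(right)
    if sl > 0 and sr < 0:
        cls = Stability.ATTRACTING
    elif sl < 0 and sr > 0:
        cls = Stability.REPELLING
    else:
        cls = Stability.HALF_STABLE
    return FixedPointReport(y_star=float(y_star), lam=float(lam),
                            classification=cls, branch=branch)


def bifurcation_diagram(model: PhaseModel, G_min: float = 0.3,
                        G_max: float = 3.5, step: float = 0.01):
    """Steady-state branch over a curvature grid, with the knee location.

    Returns ``(table, knee)`` where ``table`` has columns
    (G, y_star, dy_star/dG, curvature) and ``knee`` is the G of maximum
    curvature of y*(G), or None when the branch is flat (k_comb = 0).
    The knee falling near G = 1 marks the bifurcation between the steep
    far-from-equilibrium branch and the near-flat plateau.
    """
    if G_min <= 0:
        raise ValueError("curvature grid must be positive")
    if not model.has_parameter:
        raise ValueError("model has no combined parameter; call combine() first")
    G = np.arange(G_min, G_max + step / 2, step)
    y = steady_state_branch(model, G)
    c = model.k_comb / model.a_lin
    dy = -c * model.beta * G ** (model.beta - 1.0)
    d2y = -c * model.beta * (model.beta - 1.0) * G ** (model.beta - 2.0)
    if model.k_comb == 0:
        kappa = np.zeros_like(G)
        knee = None
    else:
        kappa = np.abs(d2y) / (1.0 + dy ** 2) ** 1.5
        knee = float(G[int(np.argmax(kappa))])
    table = np.column_stack([G, y, dy, kappa])
    return table, knee
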