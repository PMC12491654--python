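"""Run configuration shared across the pipeline.

All physical constants that the analysis cannot measure from a
force-velocity experiment live here, so that every derived molecular
quantity is reproducible from (data, config, seed) alone.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

#: 29 degC bath temperature, stored absolute because entropy-production
#: rates divide by T.
T_BATH_K = 302.15


@dataclass(frozen=True)
class RunConfig:
    """Physical constants and pipeline switches.

    Parameters
    ----------
    h:
        Myosin power-stroke (step) size in nm. Optical-tweezer work on
        smooth and skeletal myosin puts the stroke at 10-11 nm.
    ell:
        Actin site spacing in nm (one available binding site per ``ell``
        of filament); the 36 nm default is the actin helical repeat.
    k_cb:
        Crossbridge spring stiffness in pN/nm.
    e_atp:
        Free energy liberated per ATP split, in J (~60 pN nm).
    L_ref:
        Crossbridge-level sliding distance, in nm, corresponding to one
        Lo of whole-muscle shortening.  Sets the conversion between the
        muscle velocity scale (Lo/s) and the molecular scale (nm/s).
    partition:
        Default attachment partition f1/(f1+g1) used when inverting a
        macroscopic fit to molecular rates; the normalized force-velocity
        curve does not constrain it (see the methods note).
    kappa_geom:
        Geometric factor (nmol pN / g / (mN/mm^2)) used to derive myosin
        content from isometric tension when no assayed content is given;
        ``None`` means "refuse to derive" (configuration error).
    alpha_linearity:
        Significance level for the force-flow linearity (regime) test.
    seed:
        Root RNG seed for every stochastic operation.
    noise_cv:
        Multiplicative coefficient of variation applied to simulated
        velocity measurements.
    inclusion_prob:
        Probability that a simulated strip contracts spontaneously and
        is therefore included (the experimental inclusion rate is 90 %).
    n_afterloads:
        Number of intermediate afterload levels in the emulated protocol
        (levels ``{1..n}/(n+3)``-free grid ``0.1..0.7`` of TT by default).
    epr_trend_degree:
        Polynomial degree for the near-equilibrium EPR(ts) trend.  The
        default 2 lets the trend's derivative rise linearly with ts; set
        1 to force a straight line.
    """

    h: float = 11.0
    ell: float = 36.0
    k_cb: float = 0.5
    e_atp: float = 6.0e-20
    L_ref: float = 4500.0
    partition: float = 0.7
    kappa_geom: Optional[float] = None
    alpha_linearity: float = 0.05
    seed: int = 0
    noise_cv: float = 0.05
    inclusion_prob: float = 0.90
    n_afterloads: int = 7
    epr_trend_degree: int = 2
    stability_eps: float = 1e-6

    def __post_init__(self) -> None:
        if not self.h > 0:
            raise ValueError("step size h must be positive")
        if self.ell < self.h:
            raise ValueError("actin site spacing ell must be >= h")
        if not 0 < self.inclusion_prob <= 1:
            raise ValueError("inclusion_prob must be in (0, 1]")
        if not 0 <= self.noise_cv < 1:
            raise ValueError("noise_cv must be in [0, 1)")
        if not 0 < self.partition < 1:
            raise ValueError("partition f1/(f1+g1) must be in (0, 1)")
        if self.L_ref <= 0 or self.k_cb <= 0 or self.e_atp <= 0:
            raise ValueError("L_ref, k_cb and e_atp must be positive")
        if not 0 < self.alpha_linearity < 1:
            raise ValueError("alpha_linearity must be in (0, 1)")
        if self.epr_trend_degree not in (1, 2):
            raise ValueError("epr_trend_degree must be 1 or 2")

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
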