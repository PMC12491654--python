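"""Seeded synthetic cohorts with the statistical structure of the assay.

Each simulated muscle strip gets molecular parameters (f1, g1, g2, TT,
myosin content) drawn from lognormal marginals moment-matched to the
target group means and standard deviations.  Lognormals are used because
several rate constants have sd of the order of the mean, which a normal
distribution would push negative.

Dependence between parameters is a Gaussian copula on the log scale, so
the marginals (and hence the moment matching) are untouched by the
correlation structure.  The default calibration encodes two features of
the biology the cohorts are meant to emulate:

* a shared *kinetic tempo*: f1, g1 and g2 scale together across samples
  (faster myosin attaches and detaches faster at every strain), which
  links high-flow samples to short stroke times;
* in the term-pregnant (caesarean) group, myosin content anti-correlates
  with the stroke-tempo rates f1 and g2 (hypertrophied, slow, economical
  myosin carries more heads), which makes the entropy production rate
  rise with stroke time; the flow rate g1 is left uncoupled from content
  there, keeping the force-flow scatter in the linear regime;
* in the non-pregnant (hysterectomy) group, content and kinetics co-vary
  (flow rate coupled to content), so entropy production concentrates in
  fast, short-stroke samples and falls steeply with stroke time.

The measurement protocol is then emulated: the forward crossbridge model
produces each strip's force-velocity curve, sampled at a zero-load clamp
point, intermediate afterloads and the isometric point, with
multiplicative Gaussian noise on velocities.  One root seed drives
everything; per-sample substreams are derived from (seed, group, index)
so changing the cohort size never reshuffles earlier samples.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .config import T_BATH_K, RunConfig
from .huxley import HuxleyRates, _u_at_load, _u_max

__all__ = [
    "GroupSpec",
    "GroundTruth",
    "CAESAREAN_SPEC",
    "HYSTERECTOMY_SPEC",
    "DEFAULT_SPECS",
    "draw_cohort",
    "emulate_protocol",
    "simulate_cohorts",
    "simulate",
]

_PARAMS = ("f1", "g1", "g2", "TT", "MC")
_GROUP_CODE = {"caesarean": 1, "hysterectomy": 2}


@dataclass(frozen=True)
class GroupSpec:
    """Target moments and dependence structure for one cohort."""

    group: str
    n: int
    f1_mean: float
    f1_sd: float
    g1_mean: float
    g1_sd: float
    g2_mean: float
    g2_sd: float
    TT_mean: float
    TT_sd: float
    MC_mean: float
    MC_sd: float
    rate_corr: float = 0.45     # log-scale correlation among f1, g1, g2
    mc_rate_corr: float = 0.0   # log-scale correlation of MC with f1 and g2
    flow_mc_corr: float = 0.0   # log-scale correlation of MC with g1 (flow)

    def __post_init__(self):
        for p in _PARAMS:
            if getattr(self, f"{p}_mean") <= 0:
                raise ValueError(f"{p}_mean must be positive")
            if getattr(self, f"{p}_sd") < 0:
                raise ValueError(f"{p}_sd must be >= 0")
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")
        for c in (self.rate_corr, self.mc_rate_corr, self.flow_mc_corr):
            if not -1 < c < 1:
                raise ValueError("correlations must be in (-1, 1)")

    def replace(self, **kw) -> "GroupSpec":
        return replace(self, **kw)


#: Default calibration: group means and sd of the two cohorts the
#: pipeline is designed around (term caesarean n=23, non-pregnant
#: hysterectomy n=20).
CAESAREAN_SPEC = GroupSpec(
    group="caesarean", n=23,
    f1_mean=2.3, f1_sd=1.3, g1_mean=1.0, g1_sd=0.5, g2_mean=6.9, g2_sd=5.1,
    TT_mean=28.3, TT_sd=23.9, MC_mean=2.2, MC_sd=2.2,
    rate_corr=0.45, mc_rate_corr=-0.72,
)
HYSTERECTOMY_SPEC = GroupSpec(
    group="hysterectomy", n=20,
    f1_mean=2.6, f1_sd=1.5, g1_mean=3.9, g1_sd=4.5, g2_mean=2.6, g2_sd=1.5,
    TT_mean=20.5, TT_sd=12.5, MC_mean=2.7, MC_sd=1.2,
    rate_corr=0.7, mc_rate_corr=0.56, flow_mc_corr=0.8,
)
DEFAULT_SPECS = (CAESAREAN_SPEC, HYSTERECTOMY_SPEC)


@dataclass(frozen=True)
class GroundTruth:
    """True per-sample parameters behind one simulated cohort."""

    spec: GroupSpec
    seed: int
    noise_cv: float
    table: pd.DataFrame = field(repr=False)  # per-sample truth


def _lognormal_mu_sigma(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the lognormal with the given mean and sd."""
    if sd == 0:
        return np.log(mean), 0.0
    s2 = np.log1p((sd / mean) ** 2)
    if not np.isfinite(s2):
        raise ValueError(f"sd {sd} with mean {mean} overflows the lognormal")
    return np.log(mean) - s2 / 2.0, np.sqrt(s2)


def _latent_correlation(spec: GroupSpec) -> np.ndarray:
    """Copula correlation over (f1, g1, g2, TT, MC).

    TT is independent; MC couples to the stroke-tempo rates f1 and g2
    through ``mc_rate_corr`` and to the flow rate g1 through
    ``flow_mc_corr``.
    """
    C = np.eye(5)
    for i in range(3):
        for j in range(3):
            if i != j:
                C[i, j] = spec.rate_corr
    for i in (0, 2):  # f1, g2
        C[i, 4] = C[4, i] = spec.mc_rate_corr
    C[1, 4] = C[4, 1] = spec.flow_mc_corr
    # positive definiteness check (fails loudly for extreme user settings)
    if np.linalg.eigvalsh(C).min() <= 1e-10:
        raise ValueError("correlation settings do not form a valid copula")
    return C


def _sample_rng(seed: int, group: str, index: int, stream: int) -> np.random.Generator:
    """Documented substream split: (root seed, group code, sample, stream)."""
    return np.random.default_rng(
        np.random.SeedSequence((int(seed), _GROUP_CODE[group], int(index), int(stream)))
    )


def draw_cohort(spec: GroupSpec, seed: int,
                inclusion_prob: float = 0.90) -> tuple[GroundTruth, pd.DataFrame]:
    """Draw one cohort; returns ``(truth, sample_table)``.

    Deterministic given (spec, seed).  The sample table has the pipeline
    input schema; excluded (non-contracting) strips stay in the table
    with ``contracted_spontaneously = False``.
    """
    L = np.linalg.cholesky(_latent_correlation(spec))
    mus, sigmas = zip(*(
        _lognormal_mu_sigma(getattr(spec, f"{p}_mean"), getattr(spec, f"{p}_sd"))
        for p in _PARAMS
    ))
    mus, sigmas = np.array(mus), np.array(sigmas)

    rows = []
    prefix = spec.group[:3]
    for i in range(spec.n):
        rng = _sample_rng(seed, spec.group, i, 0)
        z = L @ rng.standard_normal(5)
        vals = np.exp(mus + sigmas * z)
        included = bool(rng.random() < inclusion_prob)
        rows.append({
            "sample_id": f"{prefix}{i + 1:03d}",
            "group": spec.group,
            "f1": vals[0], "g1": vals[1], "g2": vals[2],
            "TT": vals[3], "MC": vals[4],
            "contracted_spontaneously": included,
        })
    truth_table = pd.DataFrame(rows)
    samples = pd.DataFrame({
        "sample_id": truth_table["sample_id"],
        "group": spec.group,
        "temperature_K": T_BATH_K,
        "cross_section_mm2": 1.0,
        "Lo_mm": 5.0,
        "TT_mN_per_mm2": truth_table["TT"],
        "MC_nmol_per_g": truth_table["MC"],
        "contracted_spontaneously": truth_table["contracted_spontaneously"],
    })
    truth = GroundTruth(spec=spec, seed=int(seed), noise_cv=np.nan,
                        table=truth_table)
    return truth, samples


def _protocol_rel_loads(n_afterloads: int) -> np.ndarray:
    """Zero-load clamp + intermediate afterloads + isometric point."""
    inter = np.round(np.linspace(0.1, 0.7, n_afterloads), 10)
    return np.concatenate([[0.0], inter, [1.0]])


def emulate_protocol(truth: GroundTruth, cfg: RunConfig) -> pd.DataFrame:
    """Afterloaded force-velocity points for every included strip.

    The forward crossbridge model gives each strip's normalized
    force-velocity curve; it is sampled at relative loads
    ``{0, 0.1 .. 0.7, 1}`` of TT (zero-load clamp, afterloads,
    isometric), converted to muscle units through L_ref, and velocity
    noise (multiplicative Gaussian, cv = ``cfg.noise_cv``) is applied.
    Deterministic given (truth, cfg).
    """
    rel = _protocol_rel_loads(cfg.n_afterloads)
    rows = []
    for i, row in truth.table.iterrows():
        if not row["contracted_spontaneously"]:
            continue
        rates = HuxleyRates(f1=row["f1"], g1=row["g1"], g2=row["g2"],
                            h=cfg.h, ell=cfg.ell)
        umax = _u_max(rates.r)
        u = np.array([_u_at_load(rates.r, p, umax) for p in rel])
        vel = u * rates.phi / cfg.L_ref  # nm/s -> Lo/s
        if cfg.noise_cv > 0:
            rng = _sample_rng(truth.seed, truth.spec.group, i, 1)
            vel = np.clip(vel * (1.0 + cfg.noise_cv * rng.standard_normal(vel.size)),
                          0.0, None)
        for p, v in zip(rel, vel):
            rows.append({
                "sample_id": row["sample_id"],
                "load_mN_per_mm2": p * row["TT"],
                "velocity_Lo_per_s": v,
            })
    return pd.DataFrame(rows)


def simulate_cohorts(cfg: RunConfig, specs=DEFAULT_SPECS):
    """Draw and measure every cohort; returns ``(samples, points, truths)``.

    ``truths`` maps group name to its :class:`GroundTruth` (with the
    noise descriptor filled in).
    """
    all_samples, all_points, truths = [], [], {}
    for spec in specs:
        truth, samples = draw_cohort(spec, cfg.seed, cfg.inclusion_prob)
        truth = GroundTruth(spec=truth.spec, seed=truth.seed,
                            noise_cv=cfg.noise_cv, table=truth.table)
        points = emulate_protocol(truth, cfg)
        all_samples.append(samples)
        all_points.append(points)
        truths[spec.group] = truth
    return (pd.concat(all_samples, ignore_index=True),
            pd.concat(all_points, ignore_index=True),
            truths)


def simulate(cfg: RunConfig, out_dir, specs=DEFAULT_SPECS):
    """Write ``samples.csv``, ``points.csv`` and ``truth.json`` to a directory."""
    import os

    from .io import write_cohort, write_results

    samples, points, truths = simulate_cohorts(cfg, specs)
    os.makedirs(out_dir, exist_ok=True)
    write_cohort(samples, points,
                 os.path.join(out_dir, "samples.csv"),
                 os.path.join(out_dir, "points.csv"))
    truth_doc = {
        g: {"spec": t.spec, "seed": t.seed, "noise_cv": t.noise_cv,
            "table": t.table}
        for g, t in truths.items()
    }
    write_results(truth_doc, os.path.join(out_dir, "truth.json"), cfg)
    return samples, points, truths
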