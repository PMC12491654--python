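"""End-to-end analysis: force-velocity tables in, thermodynamics out.

Per included sample: Hill fit -> molecular rate inversion -> crossbridge
energetics -> thermodynamic force/flow/EPR.  Per group: force-flow
regime classification, EPR(ts) trend and its derivative (EEP), deviation
EEP, descriptive statistics.  Pooled: reconstruction of the
one-parameter phase equation and its bifurcation diagram.
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import hill, huxley, phase, stats, thermo
from .config import RunConfig

__all__ = ["analyze", "table_report"]

#: variables reported per sample and summarized per group
_REPORT_VARS = [
    "Vmax", "TT", "MC", "po", "f1", "g1", "g2", "ts", "kcat", "atpase",
    "G", "eff_max", "flow", "force", "epr", "eep",
]


def _analyze_sample(sid: str, srow: pd.Series, pts: pd.DataFrame, cfg: RunConfig):
    fit = hill.fit_hill(pts["load_mN_per_mm2"].to_numpy(),
                        pts["velocity_Lo_per_s"].to_numpy(),
                        TT=float(srow["TT_mN_per_mm2"]))
    rates = huxley.fit_rates(pts["load_mN_per_mm2"].to_numpy(),
                             pts["velocity_Lo_per_s"].to_numpy(),
                             TT=float(srow["TT_mN_per_mm2"]), cfg=cfg)
    mc = srow.get("MC_nmol_per_g", np.nan)
    mc_in = None if pd.isna(mc) else float(mc)
    kin = huxley.molecular_outputs(rates, fit, cfg, MC_input=mc_in)
    T = float(srow["temperature_K"])
    Eo, force = thermo.thermo_force(kin.MC, T)
    v0 = thermo.thermo_flow(kin)
    y = thermo.epr(force, v0)
    state = thermo.ThermoState(v0=v0, Eo=Eo, force=force, epr=y, T=T)
    return fit, kin, state


def analyze(samples: pd.DataFrame, points: pd.DataFrame, cfg: RunConfig,
            fit_phase: bool = True) -> dict:
    """Run the full pipeline on validated cohort tables.

    Returns a nested result tree: ``samples`` (per-sample hill,
    crossbridge and thermo records), ``groups`` (regime verdict, EEP
    trend, summaries, stationary means) and, when ``fit_phase`` and the
    data allow it, the pooled ``phase_model`` with its bifurcation table.
    """
    if "excluded" not in samples.columns:
        samples = samples.copy()
        samples["excluded"] = ~samples["contracted_spontaneously"].astype(bool)

    per_sample: dict[str, dict] = {}
    failures: dict[str, str] = {}
    for _, srow in samples.iterrows():
        if srow["excluded"]:
            continue
        sid = srow["sample_id"]
        pts = points[points["sample_id"] == sid]
        try:
            fit, kin, state = _analyze_sample(sid, srow, pts, cfg)
        except (hill.HillFitError, huxley.InversionError) as exc:
            # degenerate strip (e.g. force-velocity points collapse to a
            # line under noise, leaving no invertible curvature): record
            # and continue, mirroring how unusable strips are set aside
            failures[sid] = str(exc)
            continue
        per_sample[sid] = {"group": srow["group"], "hill": fit,
                           "crossbridge": kin, "thermo": state}

    groups: dict[str, dict] = {}
    pooled = {"y": [], "eep": [], "G": []}
    for g in sorted(samples["group"].unique()):
        sids = [s for s, rec in per_sample.items() if rec["group"] == g]
        if not sids:
            continue
        force = np.array([per_sample[s]["thermo"].force for s in sids])
        v0 = np.array([per_sample[s]["thermo"].v0 for s in sids])
        Eo = np.array([per_sample[s]["thermo"].Eo for s in sids])
        y = np.array([per_sample[s]["thermo"].epr for s in sids])
        ts = np.array([per_sample[s]["crossbridge"].ts for s in sids])
        T = np.array([per_sample[s]["thermo"].T for s in sids])

        verdict = thermo.classify_regime(force, v0, cfg.alpha_linearity, group=g)
        eep = thermo.eep_from_trend(ts, y, verdict.regime, cfg.epr_trend_degree)
        Eo_star, v0_star = float(np.mean(Eo)), float(np.mean(v0))
        for k, s in enumerate(sids):
            st = per_sample[s]["thermo"]
            per_sample[s]["thermo"] = thermo.ThermoState(
                v0=st.v0, Eo=st.Eo, force=st.force, epr=st.epr, T=st.T,
                eep_fit=float(eep[k]),
                eep_dev=thermo.eep_deviation(st.Eo, st.v0, Eo_star, v0_star, st.T),
                stable=bool(eep[k] > 0),
            )
        values = _collect(per_sample, sids)
        groups[g] = {
            "n": len(sids),
            "regime": verdict,
            "stationary": {"Eo": Eo_star, "v0": v0_star},
            "mean_eep_fit": float(np.mean(eep)),
            "mean_epr": float(np.mean(y)),
            "summaries": {v: stats.summarize(values[v], v, g) for v in _REPORT_VARS},
        }
        pooled["y"].extend(y.tolist())
        pooled["eep"].extend(eep.tolist())
        pooled["G"].extend(values["G"])

    result: dict = {"samples": per_sample, "groups": groups, "failures": failures}
    if len(groups) == 2:
        ga, gb = sorted(groups)
        va = _collect(per_sample, [s for s, r in per_sample.items() if r["group"] == ga])
        vb = _collect(per_sample, [s for s, r in per_sample.items() if r["group"] == gb])
        result["anova"] = {
            v: stats.one_way_anova(va[v], vb[v], variable=v) for v in _REPORT_VARS
        }
    if fit_phase:
        try:
            model = phase.fit_phase_equation(pooled["y"], pooled["eep"])
            A, beta = phase.fit_eep_power_law(
                pooled["G"], np.asarray(pooled["eep"], float) ** 2)
            model = phase.combine(model, A, beta)
            table, knee = phase.bifurcation_diagram(model)
            result["phase_model"] = {
                "model": model,
                "bifurcation_knee": knee,
                "bifurcation_table": table,
            }
        except ValueError as exc:
            result["phase_model"] = {"error": str(exc)}
    return result


def _collect(per_sample: dict, sids: Sequence[str]) -> dict[str, list[float]]:
    out: dict[str, list[float]] = {v: [] for v in _REPORT_VARS}
    for s in sids:
        rec = per_sample[s]
        f, k, t = rec["hill"], rec["crossbridge"], rec["thermo"]
        out["Vmax"].append(f.Vmax)
        out["TT"].append(f.TT)
        out["G"].append(f.G)
        out["MC"].append(k.MC)
        out["po"].append(k.po)
        out["f1"].append(k.rates.f1)
        out["g1"].append(k.rates.g1)
        out["g2"].append(k.rates.g2)
        out["ts"].append(k.ts)
        out["kcat"].append(k.kcat)
        out["atpase"].append(k.atpase)
        out["eff_max"].append(k.eff_max)
        out["flow"].append(t.v0)
        out["force"].append(t.force)
        out["epr"].append(t.epr)
        out["eep"].append(t.eep_fit if t.eep_fit is not None else np.nan)
    return out


def table_report(result: dict) -> pd.DataFrame:
    """Cohort comparison table: variable x group mean +- sd and ANOVA p."""
    rows = []
    groups = sorted(result["groups"])
    for v in _REPORT_VARS:
        row = {"variable": v}
        for g in groups:
            s = result["groups"][g]["summaries"][v]
            row[f"{g}_mean"] = s.mean
            row[f"{g}_sd"] = s.sd
        if "anova" in result:
            row["p"] = result["anova"][v].p
        rows.append(row)
    return pd.DataFrame(rows)
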