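"""Parameter-sweep orchestration: flow → transport → zones per case.

A :class:`SweepPlan` names the study cases to run (see
:mod:`spherotrap.fixtures`), the species to transport and the outputs to
collect. Results are aggregated into tidy per-case records and written as
CSV tables plus optional VTK fields; the headline comparisons (shear
envelope, trap ranking, deficiency-free operating window) are assembled by
:func:`report` from the computed records only.
"""

from __future__ import annotations

import logging
import traceback
from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np
import pandas as pd

from .fixtures import make_fixture
from .flow import solve_flow, wall_shear
from .transport import (centerline_profile, glucose_spec, mismatch_percent,
                        oxygen_spec, solve_steady, solve_transient_noflow)
from .zones import ZoneMap, classify, midplane_fractions

log = logging.getLogger("spherotrap.sweep")

__all__ = ["SweepPlan", "CaseResult", "run_sweep", "report"]


@dataclass(frozen=True)
class SweepPlan:
    """Cases to execute and how."""

    cases: tuple[str, ...]
    species: tuple[str, ...] = ("oxygen", "glucose")
    resolution: str = "coarse"
    flow_mode: str = "stokes"
    transient: bool = False
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self):
        if len(set(self.cases)) != len(self.cases):
            raise ValueError("duplicate cases in plan")


@dataclass
class CaseResult:
    case: str
    trap_variant: str
    D_um: float
    Q_uL_min: float
    max_shear_mPa: float | None = None
    profiles: dict = dfield(default_factory=dict)       # species -> (x/D, c)
    mismatch_pct: dict = dfield(default_factory=dict)
    zone_fractions: dict = dfield(default_factory=dict)  # species -> dict
    spheroid_avg_mM: dict = dfield(default_factory=dict)
    transient: dict = dfield(default_factory=dict)       # species -> series
    diagnostics: dict = dfield(default_factory=dict)
    error: str | None = None

    def row(self) -> dict:
        r = {
            "case": self.case, "trap": self.trap_variant, "D_um": self.D_um,
            "Q_uL_min": self.Q_uL_min, "max_shear_mPa": self.max_shear_mPa,
            "error": self.error or "",
        }
        for sp, v in self.mismatch_pct.items():
            r[f"mismatch_{sp}_pct"] = v
        for sp, v in self.spheroid_avg_mM.items():
            r[f"avg_{sp}_mM"] = v
        for sp, fr in self.zone_fractions.items():
            for lab, pct in fr.items():
                r[f"{sp}_{lab}_pct"] = pct
        return r


def _species_spec(name: str, conditions: dict):
    if name == "oxygen":
        if "c0_O2_mM" not in conditions:
            return None
        return oxygen_spec(conditions["c0_O2_mM"])
    if name == "glucose":
        if "c0_glucose_mM" not in conditions:
            return None
        return glucose_spec(conditions["c0_glucose_mM"])
    raise ValueError(f"unknown species {name!r}")


def run_case(case_name: str, plan: SweepPlan) -> CaseResult:
    fx = make_fixture(case_name, plan.resolution)
    cfg = fx.config
    result = CaseResult(case=case_name, trap_variant=cfg.trap_variant.value,
                        D_um=cfg.spheroid_diameter, Q_uL_min=fx.Q_uL_min)
    flow = solve_flow(fx.mesh, fx.Q_uL_min, mode=plan.flow_mode)
    result.max_shear_mPa, _ = wall_shear(flow)
    result.diagnostics["flow_residuals"] = flow.residual_norms
    for sp_name in plan.species:
        spec = _species_spec(sp_name, fx.conditions)
        if spec is None:
            continue
        fld = solve_steady(fx.mesh, flow, spec)
        xod, c = centerline_profile(fld, cfg)
        result.profiles[sp_name] = (xod, c)
        result.mismatch_pct[sp_name] = mismatch_percent(c)
        result.spheroid_avg_mM[sp_name] = fld.spheroid_average()
        zm = classify(fld)
        result.zone_fractions[sp_name] = midplane_fractions(zm, cfg)
        result.diagnostics[f"{sp_name}_solver"] = fld.diagnostics
        if plan.transient or fx.conditions.get("transient"):
            tr = solve_transient_noflow(fx.mesh, fld, spec,
                                        t_end=4 * 3600.0, dt=120.0)
            result.transient[sp_name] = (tr.times_s, tr.spheroid_avg_mM)
    return result


def run_sweep(plan: SweepPlan) -> list[CaseResult]:
    """Execute all cases; failures are recorded per case, not raised."""
    results = []
    for case_name in plan.cases:
        try:
            results.append(run_case(case_name, plan))
        except Exception as exc:                       # noqa: BLE001
            log.error("case %s failed: %s", case_name, exc)
            cr = CaseResult(case=case_name, trap_variant="?", D_um=np.nan,
                            Q_uL_min=np.nan, error=f"{exc}")
            cr.diagnostics["traceback"] = traceback.format_exc()
            results.append(cr)
    if plan.output_dir:
        report(results, plan.output_dir)
    return results


def _render_figures(results: list[CaseResult], out: Path) -> dict[str, Path]:
    """Centre-line profiles and depletion transients as PNG figures."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = {}
    species = sorted({sp for r in results for sp in r.profiles})
    if species:
        fig, axes = plt.subplots(1, len(species), figsize=(5 * len(species), 4),
                                 squeeze=False)
        for ax, sp in zip(axes[0], species):
            for r in results:
                if sp in r.profiles:
                    xod, c = r.profiles[sp]
                    ax.plot(xod, c, label=r.case)
            ax.set_xlabel("x / D")
            ax.set_ylabel(f"{sp} (mM)")
            ax.legend(fontsize=7)
        fig.tight_layout()
        p = out / "centerline_profiles.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written["profiles_png"] = p
    if any(r.transient for r in results):
        fig, ax = plt.subplots(figsize=(5, 4))
        for r in results:
            for sp, (t, avg) in r.transient.items():
                ax.plot(np.asarray(t) / 3600.0, avg, label=f"{r.case} {sp}")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("spheroid average (mM)")
        ax.legend(fontsize=7)
        fig.tight_layout()
        p = out / "transients.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written["transients_png"] = p
    return written


def report(results: list[CaseResult], output_dir) -> dict[str, Path]:
    """Write tidy CSV tables and summary comparisons for a finished sweep."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}

    summary = pd.DataFrame([r.row() for r in results])
    p = out / "cases.csv"
    summary.to_csv(p, index=False)
    written["cases"] = p

    prof_rows = []
    for r in results:
        for sp, (xod, c) in r.profiles.items():
            for xi, ci in zip(xod, c):
                prof_rows.append({"case": r.case, "species": sp,
                                  "x_over_D": xi, "c_mM": ci})
    if prof_rows:
        p = out / "centerline_profiles.csv"
        pd.DataFrame(prof_rows).to_csv(p, index=False)
        written["profiles"] = p

    tr_rows = []
    for r in results:
        for sp, (t, avg) in r.transient.items():
            for ti, ai in zip(t, avg):
                tr_rows.append({"case": r.case, "species": sp,
                                "t_s": ti, "spheroid_avg_mM": ai})
    if tr_rows:
        p = out / "transients.csv"
        pd.DataFrame(tr_rows).to_csv(p, index=False)
        written["transients"] = p

    ok = summary[summary["error"] == ""] if len(summary) else summary
    if prof_rows or tr_rows:
        written.update(_render_figures(results, out))
    if len(ok):
        shear = ok[["case", "trap", "D_um", "Q_uL_min", "max_shear_mPa"]]
        p = out / "shear.csv"
        shear.to_csv(p, index=False)
        written["shear"] = p

        # deficiency-free operating window: cases with zero quiescent and
        # necrotic area for every species computed
        zone_cols = [c for c in ok.columns
                     if c.endswith("_quiescent_pct") or c.endswith("_necrotic_pct")]
        if zone_cols:
            free = ok[(ok[zone_cols].fillna(0.0) < 0.5).all(axis=1)]
            window = (free.groupby("Q_uL_min")["D_um"].max()
                      .reset_index()
                      .rename(columns={"D_um": "largest_deficiency_free_D_um"}))
            p = out / "operating_window.csv"
            window.to_csv(p, index=False)
            written["operating_window"] = p
    return written
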