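"""End-to-end orchestration: simulate or load captures, classify, run the
four analyses, and write a reproducible report bundle.

Outputs are plain text and CSV.  Every filter logs its row counts, since
the analysis Ns are filter-dependent and auditability is the point of
the pipeline.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: header for every model summary the pipeline writes
P_VALUE_NOTE = "p-values are raw; no multiple-testing correction is applied\n"

from . import __version__
from .mass import (
    adult_mass_table,
    conditional_logistic,
    fit_lmm_mass,
    match_mass_controls,
    percent_effect,
    pre_impaired_rows,
    unimpaired_capture_rows,
)
from .movement import fit_lmm_logmsd, movement_records, percent_msd_effect
from .parasites import (
    botfly_season_diagnostic,
    burden_rows,
    fit_logistic_mixed,
    fit_nb_mixed,
    tick_season_diagnostic,
)
from .records import TrapGrid, build_histories, read_captures, write_captures
from .simulate import SimulationConfig, simulate_population, study_end, truth_report
from .stats import describe_cohort
from .survival import (
    session_calendar,
    fit_proportional_hazards,
    km_estimate,
    logrank_test,
    match_survival_controls,
    matched_analysis_table,
    persistence_times,
)


@dataclass
class RunConfig:
    """One pipeline run: exactly one of captures_path / sim_config set."""

    captures_path: str | None = None
    sim_config: SimulationConfig | None = None
    seed: int = 0
    out_dir: str = "impairfit_out"
    study_end: dict | None = None  # plot -> (year, week); required for captures mode
    session_interval_weeks: float = 3.0
    exclude_tick_years: tuple[int, ...] = ()
    modules: tuple[str, ...] = ("describe", "survive", "mass", "move", "parasites")

    def __post_init__(self):
        if (self.captures_path is None) == (self.sim_config is None):
            raise ValueError("set exactly one of captures_path / sim_config")


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured analyses; returns the summary dict (also written
    to ``<out_dir>/summary.json`` with a provenance block)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    summary: dict = {}

    if config.sim_config is not None:
        events, truth = simulate_population(config.sim_config, config.seed)
        write_captures(events, out / "captures.csv")
        truth.individuals.to_csv(out / "truth_individuals.csv", index=False)
        truth_report(truth).to_csv(out / "truth_effects.csv", index=False)
        ends = study_end(config.sim_config)
        log.append(f"simulated {len(events)} capture events")
    else:
        events, report = read_captures(config.captures_path)
        (out / "validation.txt").write_text(str(report) + "\n")
        if not report.ok:
            log.append(f"validation: {len(report.errors)} rows rejected")
        ends = config.study_end
        if ends is None:
            last = events.sort_values(["year", "week"]).iloc[-1]
            ends = {p: (int(last["year"]), int(last["week"])) for p in events["plot"].unique()}

    histories = build_histories(events)
    log.append(f"{len(histories)} individuals from {len(events)} events")

    if "describe" in config.modules:
        summary["describe"] = describe_cohort(histories)

    if "survive" in config.modules:
        persist = persistence_times(histories, ends)
        log.append(
            f"persistence: {len(persist)} residents, "
            f"{persist.attrs['n_excluded']} non-residents excluded"
        )
        persist.to_csv(out / "persistence.csv", index=False)
        cases = persist[persist["category"] != "none"]
        pool = persist[persist["category"] == "none"]
        sets, dropped = match_survival_controls(
            cases, pool, config.session_interval_weeks,
            sessions=session_calendar(events),
        )
        log.append(f"survival matching: {len(sets)} matched sets, {len(dropped)} cases dropped")
        surv = {"n_cases_matched": len(sets), "n_cases_dropped": len(dropped)}
        if sets:
            table = matched_analysis_table(persist, sets)
            km = km_estimate(table)
            for g, c in km.curves.items():
                c.to_csv(out / f"km_{g}.csv", index=False)
            surv["km_medians"] = km.medians
            surv["mean_persistence_weeks"] = float(table["persistence_weeks"].mean())
            if table["category"].nunique() >= 2:
                stat, dof, p = logrank_test(table)
                surv["logrank"] = {"statistic": stat, "df": dof, "p": p}
            try:
                cox = fit_proportional_hazards(persist, sets=sets)
                (out / "cox_summary.txt").write_text(P_VALUE_NOTE + cox.summary() + "\n")
                surv["hazard_ratios"] = {
                    t: float(np.exp(cox.coef(t)))
                    for t in cox.fixed_effects.index
                    if t.startswith("category")
                }
            except Exception as e:  # keep partial outputs on model failure
                surv["cox_error"] = str(e)
        summary["survival"] = surv

    if "mass" in config.modules:
        rows = adult_mass_table(histories)
        log.append(
            f"mass: {len(rows)} adult rows "
            f"({rows.attrs['n_dropped_age']} non-adult, "
            f"{rows.attrs['n_dropped_mass']} out-of-bounds dropped)"
        )
        rows.to_csv(out / "mass_rows.csv", index=False)
        ms: dict = {"n_rows": len(rows)}
        if len(rows) and rows["tag"].nunique() > 2:
            fit = fit_lmm_mass(rows)
            (out / "mass_model.txt").write_text(P_VALUE_NOTE + fit.summary() + "\n")
            baseline = float(rows.loc[rows["category"] == "none", "mass_g"].mean())
            ms["baseline_mean_g"] = baseline
            ms["effects_g"] = {
                t: fit.coef(t)
                for t in fit.fixed_effects.index
                if t.startswith("category")
            }
            ms["effects_percent"] = {
                t: round(percent_effect(v, baseline))
                for t, v in ms["effects_g"].items()
            }
            cases = pre_impaired_rows(histories)
            pool = unimpaired_capture_rows(histories)
            msets, mdropped = match_mass_controls(cases, pool)
            ms["n_mass_matched"] = len(msets)
            ms["n_mass_dropped"] = len(mdropped)
            if msets:
                try:
                    clog = conditional_logistic(
                        msets,
                        cases.set_index("tag")["mass_g"],
                        pool.groupby("tag")["mass_g"].mean(),
                    )
                    ms["mass_odds_ratio_per_g"] = float(np.exp(clog.coef("exposure")))
                    ms["mass_or_ci"] = [float(np.exp(v)) for v in clog.ci("exposure")]
                except ValueError as e:
                    ms["clogit_error"] = str(e)
        summary["mass"] = ms

    if "move" in config.modules:
        grids = (
            config.sim_config.grids()
            if config.sim_config is not None
            else {p: TrapGrid(p) for p in events["plot"].unique()}
        )
        recs = movement_records(histories, grids)
        recs.to_csv(out / "movement_records.csv", index=False)
        log.append(f"movement: {len(recs)} resident plot-season records")
        mv: dict = {"n_records": len(recs), "mean_msd_m2": float(recs["msd"].mean()) if len(recs) else np.nan}
        if len(recs) > 50 and recs["tag"].nunique() > 2:
            fit = fit_lmm_logmsd(recs)
            (out / "movement_model.txt").write_text(P_VALUE_NOTE + fit.summary() + "\n")
            mv["effects_log"] = {
                t: fit.coef(t)
                for t in fit.fixed_effects.index
                if t.startswith("category")
            }
            mv["effects_percent_msd"] = {
                t: percent_msd_effect(v) for t, v in mv["effects_log"].items()
            }
        summary["movement"] = mv

    if "parasites" in config.modules:
        pr: dict = {}
        for parasite in ("tick", "botfly"):
            rows = burden_rows(
                histories,
                parasite,
                exclude_years=(
                    config.exclude_tick_years if parasite == "tick" else ()
                ),
            )
            rows.to_csv(out / f"{parasite}_rows.csv", index=False)
            diag = (
                tick_season_diagnostic(rows.rename(columns={"count": "ticks"}))
                if parasite == "tick"
                else botfly_season_diagnostic(rows.rename(columns={"count": "botflies"}))
            )
            diag.to_csv(out / f"{parasite}_season_diagnostic.csv", index=False)
            res: dict = {"n_rows": len(rows)}
            if len(rows) > 100 and 0 < rows["infested"].mean() < 1:
                future = "by_type" if parasite == "botfly" else None
                try:
                    logit = fit_logistic_mixed(rows, future_level=future)
                    nb = fit_nb_mixed(rows, future_level=future)
                    (out / f"{parasite}_models.txt").write_text(
                        P_VALUE_NOTE
                        + "infestation (log-odds):\n"
                        + logit.summary()
                        + "\n\nload (log-rate):\n"
                        + nb.summary()
                        + "\n"
                    )
                    res["infestation_or"] = {
                        t: float(np.exp(logit.coef(t)))
                        for t in logit.fixed_effects.index
                        if t.startswith("category")
                    }
                    res["load_irr"] = {
                        t: float(np.exp(nb.coef(t)))
                        for t in nb.fixed_effects.index
                        if t.startswith("category")
                    }
                except Exception as e:
                    res["model_error"] = str(e)
            pr[parasite] = res
        summary["parasites"] = pr

    provenance = {
        "impairfit_version": __version__,
        "seed": config.seed,
        "mode": "simulate" if config.sim_config is not None else "captures",
        "config_hash": hashlib.sha256(
            repr(
                {
                    k: v
                    for k, v in vars(config).items()
                    if k != "out_dir"  # identical analyses hash alike
                }
            ).encode("utf-8")
        ).hexdigest()[:16],
    }
    summary["provenance"] = provenance
    (out / "run_log.txt").write_text("\n".join(log) + "\n")
    (out / "summary.json").write_text(json.dumps(_jsonable(summary), indent=2) + "\n")
    return summary


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj
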