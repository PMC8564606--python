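"""Persistence-time survival analysis with pre-impairment risk-set matching.

Persistence (weeks between first and last capture on a plot) proxies
survival in an open trapping study.  Impaired mice (cases) are matched to
never-impaired controls on age class and week of first capture; a control
is eligible only if it persisted at least one trapping event beyond the
case's pre-impairment period, which removes the immortal-time advantage a
case accrues merely by surviving long enough to be seen impaired.
Contrasts come from Kaplan-Meier curves, the log-rank test and a
sex-adjusted Cox proportional hazards model (Efron ties), stratified by
matched set when the matching is used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from .records import CaptureHistory
from .results import FitResult, MatchedSet
from .timeaxis import abs_week

#: weeks between consecutive trapping sessions; "one trapping event longer"
#: is operationalised as one inter-session interval on the week axis
DEFAULT_SESSION_INTERVAL_WEEKS = 3


def persistence_times(
    histories: dict[str, CaptureHistory],
    study_end: dict[str, tuple[int, int]],
    min_persistence_weeks: float = 1.0,
) -> pd.DataFrame:
    """Build one persistence record per resident individual.

    Persistence is the whole-week difference between last and first
    capture (across years).  Records with persistence <= 1 week are
    excluded as non-residents (count kept in ``attrs['n_excluded']``).
    A record is censored when its exit week reaches the plot's final
    trapping week of the last study year.  Histories spanning several
    plots are assigned to the modal plot and flagged.
    """
    rows = []
    n_excluded = 0
    for tag, h in histories.items():
        first, last = h.first_capture, h.last_capture
        persistence = float(abs_week(*last) - abs_week(*first))
        plot = h.modal_plot
        multi_plot = h.events["plot"].nunique() > 1
        if persistence <= min_persistence_weeks:
            n_excluded += 1
            continue
        end = study_end[plot]
        censored = abs_week(*last) >= abs_week(*end)
        asg = h.impairment
        impaired = asg is not None and asg.general != "none"
        rows.append(
            dict(
                tag=tag,
                plot=plot,
                entry_year=first[0],
                entry_week=first[1],
                exit_year=last[0],
                exit_week=last[1],
                persistence_weeks=persistence,
                censored=bool(censored),
                category=asg.general if asg else "none",
                pre_period_weeks=(
                    asg.pre_period_weeks if asg and asg.general != "none" else np.nan
                ),
                onset_year=asg.onset_week[0] if impaired else np.nan,
                onset_week=asg.onset_week[1] if impaired else np.nan,
                sex=h.sex,
                age_first=h.first_age,
                multi_plot=multi_plot,
            )
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "tag", "plot", "entry_year", "entry_week", "exit_year", "exit_week",
            "persistence_weeks", "censored", "category", "pre_period_weeks",
            "onset_year", "onset_week", "sex", "age_first", "multi_plot",
        ],
    )
    out.attrs["n_excluded"] = n_excluded
    return out


def match_survival_controls(
    cases: pd.DataFrame,
    pool: pd.DataFrame,
    session_interval_weeks: float = DEFAULT_SESSION_INTERVAL_WEEKS,
    sessions: np.ndarray | None = None,
) -> tuple[list[MatchedSet], list[str]]:
    """Attach all eligible never-impaired controls to each case.

    Eligibility: identical (age class at first capture, (year, week) of
    first capture) and persistence of at least one trapping event beyond
    the case's pre-impairment period.  The bar for "one trapping event
    longer" is the case's own first impaired capture -- the index event
    of the matched set: a control qualifies iff it persisted at least to
    that week.  This holds both arms to exactly the same guarantee; in
    particular a case whose pre-impairment period ends late in the
    trapping season is necessarily detected only at the next session the
    following spring, and its controls must carry the same overwinter
    persistence.  When onset weeks are unavailable the bar falls back to
    the first calendar session after the case's last unimpaired week
    (``sessions``, sorted absolute week indices), or to a fixed
    inter-session interval (default 3 weeks).  Cases with no eligible
    control are dropped and returned separately.
    """
    if (pool["category"] != "none").any():
        raise ValueError("control pool must contain only never-impaired records")
    sets: list[MatchedSet] = []
    dropped: list[str] = []
    if pool.empty:
        warnings.warn("empty control pool: all cases dropped")
        return sets, list(cases["tag"])
    if sessions is not None:
        sessions = np.asarray(sorted(sessions))
    grouped = {
        key: sub for key, sub in pool.groupby(["age_first", "entry_year", "entry_week"])
    }
    for case in cases.itertuples():
        key = (case.age_first, case.entry_year, case.entry_week)
        sub = grouped.get(key)
        if sub is None:
            dropped.append(case.tag)
            continue
        entry_abs = int(abs_week(case.entry_year, case.entry_week))
        last_unimp_abs = entry_abs + case.pre_period_weeks
        if np.isfinite(getattr(case, "onset_year", np.nan)):
            need = float(
                abs_week(int(case.onset_year), int(case.onset_week)) - entry_abs
            )
        elif sessions is not None:
            later = sessions[sessions > last_unimp_abs]
            if len(later) == 0:
                dropped.append(case.tag)
                continue
            need = float(later[0] - entry_abs)
        else:
            need = case.pre_period_weeks + session_interval_weeks
        ok = sub.loc[sub["persistence_weeks"] >= need, "tag"]
        if ok.empty:
            dropped.append(case.tag)
            continue
        sets.append(
            MatchedSet(
                case_tag=case.tag,
                control_tags=sorted(ok),
                keys=key,
                case_pre_period_weeks=float(case.pre_period_weeks),
            )
        )
    return sets, dropped


def session_calendar(events: pd.DataFrame) -> np.ndarray:
    """Sorted absolute week indices of all trapping sessions in a capture
    table (the weeks at which any capture occurred)."""
    wk = np.unique(abs_week(events["year"], events["week"]))
    return wk


def matched_analysis_table(
    records: pd.DataFrame, sets: list[MatchedSet]
) -> pd.DataFrame:
    """Cases plus the union of their matched controls (each mouse once)."""
    case_tags = {s.case_tag for s in sets}
    control_tags = set().union(*(s.control_tags for s in sets)) if sets else set()
    keep = case_tags | control_tags
    return records[records["tag"].isin(keep)].copy()


@dataclass
class KMResult:
    curves: dict[str, pd.DataFrame]  # group -> columns (time, survival)
    medians: dict[str, float]  # NaN when survival never reaches 0.5


def km_estimate(records: pd.DataFrame, grouping: str = "category") -> KMResult:
    """Product-limit survival curves and median persistence per group."""
    curves, medians = {}, {}
    for grp, sub in records.groupby(grouping):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["persistence_weeks"], event_observed=~sub["censored"])
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        curves[str(grp)] = sf
        med = kmf.median_survival_time_
        medians[str(grp)] = float(med) if np.isfinite(med) else float("nan")
    return KMResult(curves=curves, medians=medians)


def logrank_test(records: pd.DataFrame, grouping: str = "category"):
    """Log-rank chi-squared across groups; df = groups - 1."""
    groups = records[grouping].astype(str)
    if groups.nunique() < 2:
        raise ValueError("need at least two groups")
    res = multivariate_logrank_test(
        records["persistence_weeks"], groups, ~records["censored"]
    )
    return float(res.test_statistic), int(groups.nunique() - 1), float(res.p_value)


def fit_proportional_hazards(
    records: pd.DataFrame,
    sets: list[MatchedSet] | None = None,
    category_levels: tuple[str, ...] = ("tail", "limb", "eye"),
) -> FitResult:
    """Sex-adjusted Cox model of persistence vs impairment category.

    With ``sets`` the model is stratified by matched set (one stratum per
    case with its eligible controls, controls repeated across the sets
    they serve), which is the standard analysis for risk-set matched
    data: case selection is length-biased toward long-lived animals, and
    only the within-set comparison -- where every member cleared the same
    persistence bar -- removes that. Without ``sets`` the records are
    pooled unstratified.  Hazard ratios are exp(estimate) against the
    never-impaired reference; ties follow the Efron convention
    (lifelines' default).
    """
    if sets is not None:
        pmap = records.set_index("tag")
        parts = []
        for k, s in enumerate(sets):
            sub = pmap.loc[[s.case_tag] + list(s.control_tags)].reset_index()
            sub["stratum"] = k
            parts.append(sub)
        records = pd.concat(parts, ignore_index=True)
    df = pd.DataFrame(
        {
            "T": records["persistence_weeks"].astype(float),
            "E": (~records["censored"]).astype(int),
        }
    )
    for lev in category_levels:
        df[f"category[{lev}]"] = (records["category"] == lev).astype(float).to_numpy()
    df["sex[M]"] = (records["sex"] == "M").astype(float).to_numpy()
    # covariates absent from the data (no such category, single-sex sample)
    # would enter as all-zero columns; drop them
    for col in list(df.columns):
        if col not in ("T", "E") and df[col].nunique() == 1:
            df = df.drop(columns=col)
    cph = CoxPHFitter()
    fit_opts = {"precision": 1e-9}
    if sets is not None:
        df["stratum"] = records["stratum"].to_numpy()
        cph.fit(
            df, duration_col="T", event_col="E", strata="stratum",
            fit_options=fit_opts,
        )
    else:
        cph.fit(df, duration_col="T", event_col="E", fit_options=fit_opts)
    s = cph.summary
    fe = pd.DataFrame(
        {
            "estimate": s["coef"],
            "ci_low": s["coef lower 95%"],
            "ci_high": s["coef upper 95%"],
            "p": s["p"],
        }
    )
    fe.index = list(s.index)
    return FitResult(
        fixed_effects=fe,
        random_effects=pd.DataFrame(columns=["variance", "sd"]),
        aic=float(cph.AIC_partial_),
        n_obs=len(df),
        loglike=float(cph.log_likelihood_),
        metadata={
            "ties": "efron",
            "n_events": int(df["E"].sum()),
            "stratified": sets is not None,
            "n_strata": len(sets) if sets is not None else 1,
        },
    )
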