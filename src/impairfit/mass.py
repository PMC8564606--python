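"""Adult body-mass modelling with impairment effects.

The primary model is a linear mixed regression of adult mass on the
four-level impairment factor (none/tail/limb/eye) with sex, season and
their interaction as fixed effects and individual, plot and year as
crossed random intercepts; a secondary fit adds a fifth ``future
impaired`` level for captures that predate a later impairment.  A
matched case-control design with conditional logistic regression probes
reverse causality: does being heavier predict *becoming* impaired?
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.discrete.conditional_models import ConditionalLogit
from scipy.stats import norm

from .design import ModelSpec
from .lmm import fit_lmm
from .records import CaptureHistory, category_at
from .results import FitResult, MatchedSet
from .timeaxis import abs_week, season_of_week

#: adult mass plausibility window, grams: strictly above the lower bound,
#: inclusive at the upper (guards against data-entry errors)
MASS_MIN_G, MASS_MAX_G = 11.0, 40.0


def adult_mass_table(histories: dict[str, CaptureHistory]) -> pd.DataFrame:
    """One row per qualifying adult capture (11 g < mass <= 40 g).

    ``category`` holds the capture-level exposure: the assigned category
    after onset, ``future_<type>`` before onset, else ``none``.  Counts of
    filtered rows are kept in ``attrs``.
    """
    rows = []
    n_dropped_age = n_dropped_mass = 0
    for tag, h in histories.items():
        for _, ev in h.events.iterrows():
            if ev["age"] != "adult":
                n_dropped_age += 1
                continue
            mass = ev["mass_g"]
            if not np.isfinite(mass) or not (MASS_MIN_G < mass <= MASS_MAX_G):
                n_dropped_mass += 1
                continue
            rows.append(
                dict(
                    tag=tag,
                    plot=ev["plot"],
                    year=int(ev["year"]),
                    week=int(ev["week"]),
                    season=season_of_week(int(ev["year"]), int(ev["week"])),
                    sex=h.sex,
                    category=category_at(h, int(ev["year"]), int(ev["week"])),
                    mass_g=float(mass),
                )
            )
    out = pd.DataFrame(
        rows,
        columns=["tag", "plot", "year", "week", "season", "sex", "category", "mass_g"],
    )
    out.attrs["n_dropped_age"] = n_dropped_age
    out.attrs["n_dropped_mass"] = n_dropped_mass
    return out


def collapse_category(cat: pd.Series, future_level: str | None = None) -> pd.Series:
    """Map capture-level ``future_<type>`` labels onto the model's factor.

    ``future_level=None`` folds them into ``none`` (four-level factor);
    ``'pooled'`` gives one ``future_impaired`` level; ``'by_type'`` keeps
    ``future_tail``/``future_limb``/``future_eye``.
    """
    is_future = cat.str.startswith("future_")
    if future_level is None:
        return cat.where(~is_future, "none")
    if future_level == "pooled":
        return cat.where(~is_future, "future_impaired")
    if future_level == "by_type":
        return cat
    raise ValueError(f"unknown future_level {future_level!r}")


def mass_model_spec(future_level: str | None = None) -> ModelSpec:
    levels = ["none", "tail", "limb", "eye"]
    if future_level == "pooled":
        levels.append("future_impaired")
    elif future_level == "by_type":
        levels += ["future_tail", "future_limb", "future_eye"]
    return ModelSpec(
        response="mass_g",
        categorical={"category": "none", "sex": "F", "season": "fall"},
        levels={
            "category": levels,
            "sex": ["F", "M"],
            "season": ["fall", "spring", "summer"],
        },
        interactions=[("sex", "season")],
        random=["tag", "plot", "year"],
        family="gaussian",
    )


def fit_lmm_mass(
    rows: pd.DataFrame,
    future_level: str | None = None,
    reml: bool = True,
) -> FitResult:
    """Mixed-effects mass model (REML), reference levels: impairment
    absent, sex female, season fall."""
    df = rows.copy()
    df["category"] = collapse_category(df["category"], future_level)
    spec = mass_model_spec(future_level)
    fit = fit_lmm(df, spec, reml=reml)
    fit.metadata["future_level"] = future_level
    return fit


def percent_effect(coef: float, baseline: float) -> float:
    """Coefficient in grams as a percentage of the baseline mass."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    return 100.0 * coef / baseline


def match_mass_controls(
    case_rows: pd.DataFrame, pool_rows: pd.DataFrame
) -> tuple[list[MatchedSet], list[str]]:
    """Match each pre-impaired capture to unimpaired captures.

    ``case_rows``: one row per later-impaired mouse, its final capture
    before being recorded impaired.  Exact match on (sex, age class,
    year-week, plot); when no same-week candidate exists anywhere, fall
    back to the prior or following week on another plot.  Rows need
    columns tag, plot, year, week, sex, age, mass_g.
    """
    sets: list[MatchedSet] = []
    dropped: list[str] = []
    pool = pool_rows.copy()
    pool["absweek"] = abs_week(pool["year"], pool["week"])
    for case in case_rows.itertuples():
        wk = int(abs_week(case.year, case.week))
        base = pool[(pool["sex"] == case.sex) & (pool["age"] == case.age)]
        exact = base[(base["absweek"] == wk) & (base["plot"] == case.plot)]
        if len(exact):
            tags = sorted(exact["tag"].unique())
            sets.append(
                MatchedSet(case.tag, tags, (case.sex, case.age, case.year, case.week, case.plot))
            )
            continue
        fallback = base[
            (base["absweek"].isin([wk - 1, wk + 1])) & (base["plot"] != case.plot)
        ]
        if len(fallback):
            tags = sorted(fallback["tag"].unique())
            sets.append(
                MatchedSet(
                    case.tag,
                    tags,
                    (case.sex, case.age, case.year, case.week, "adjacent"),
                )
            )
        else:
            dropped.append(case.tag)
    return sets, dropped


def pre_impaired_rows(histories: dict[str, CaptureHistory]) -> pd.DataFrame:
    """Final capture of each later-impaired mouse before it was recorded
    impaired (the 'pre-impaired' measurement)."""
    rows = []
    for tag, h in histories.items():
        asg = h.impairment
        if asg is None or asg.general == "none" or not asg.future_impaired_events:
            continue
        ev = h.events.iloc[asg.future_impaired_events[-1]]
        rows.append(
            dict(
                tag=tag,
                plot=ev["plot"],
                year=int(ev["year"]),
                week=int(ev["week"]),
                sex=h.sex,
                age=ev["age"],
                mass_g=float(ev["mass_g"]) if np.isfinite(ev["mass_g"]) else np.nan,
                category=asg.general,
            )
        )
    return pd.DataFrame(
        rows, columns=["tag", "plot", "year", "week", "sex", "age", "mass_g", "category"]
    )


def unimpaired_capture_rows(histories: dict[str, CaptureHistory]) -> pd.DataFrame:
    """All captures of never-impaired mice (the mass-matching pool)."""
    rows = []
    for tag, h in histories.items():
        if h.impairment is not None and h.impairment.general != "none":
            continue
        for _, ev in h.events.iterrows():
            rows.append(
                dict(
                    tag=tag,
                    plot=ev["plot"],
                    year=int(ev["year"]),
                    week=int(ev["week"]),
                    sex=h.sex,
                    age=ev["age"],
                    mass_g=float(ev["mass_g"]) if np.isfinite(ev["mass_g"]) else np.nan,
                )
            )
    return pd.DataFrame(
        rows, columns=["tag", "plot", "year", "week", "sex", "age", "mass_g"]
    )


def conditional_logistic(
    sets: list[MatchedSet],
    case_exposure: pd.Series,
    pool_exposure: pd.Series,
) -> FitResult:
    """Conditional logistic regression of becoming impaired on an exposure.

    Each matched set is a stratum with one case (y=1) and its controls
    (y=0); the conditional likelihood prod exp(b x_case) / sum_set
    exp(b x_j) is maximised.  Exposure series are indexed by tag.  The
    odds ratio per exposure unit is exp(estimate).
    """
    ys, xs, strata = [], [], []
    for k, s in enumerate(sets):
        xc = case_exposure.get(s.case_tag, np.nan)
        ctrl = [(t, pool_exposure.get(t, np.nan)) for t in s.control_tags]
        ctrl = [(t, v) for t, v in ctrl if np.isfinite(v)]
        if not np.isfinite(xc) or not ctrl:
            continue
        ys += [1] + [0] * len(ctrl)
        xs += [xc] + [v for _, v in ctrl]
        strata += [k] * (1 + len(ctrl))
    if not ys:
        raise ValueError("no usable matched sets")
    xs = np.asarray(xs, float)
    ys_arr = np.asarray(ys)
    strata = np.asarray(strata)
    spread = pd.Series(xs).groupby(strata).transform(lambda v: v.max() - v.min())
    if (spread == 0).all():
        raise ValueError("exposure constant within every matched set")
    # perfect within-set ordering -> the conditional MLE diverges
    above = below = informative = 0
    for k in np.unique(strata):
        sel = strata == k
        xc = xs[sel][ys_arr[sel] == 1][0]
        xk = xs[sel][ys_arr[sel] == 0]
        if xk.max() == xk.min() == xc:
            continue
        informative += 1
        above += xc > xk.max()
        below += xc < xk.min()
    separated_data = informative > 0 and (
        above == informative or below == informative
    )
    model = ConditionalLogit(np.asarray(ys), xs[:, None], groups=strata)
    try:
        res = model.fit(method="newton", tol=1e-12, disp=False)
    except Exception:
        res = model.fit(disp=False)
    beta = float(res.params[0])
    se = float(res.bse[0])
    separated = separated_data or not np.isfinite(se) or abs(beta) > 15
    z = norm.ppf(0.975)
    fe = pd.DataFrame(
        {
            "estimate": [beta],
            "ci_low": [beta - z * se],
            "ci_high": [beta + z * se],
            "p": [2 * norm.sf(abs(beta) / se) if se > 0 else np.nan],
        },
        index=["exposure"],
    )
    return FitResult(
        fixed_effects=fe,
        random_effects=pd.DataFrame(columns=["variance", "sd"]),
        aic=float(2 * 1 - 2 * res.llf),
        n_obs=len(ys),
        loglike=float(res.llf),
        metadata={"n_sets": len(set(strata.tolist())), "separation": bool(separated)},
    )
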