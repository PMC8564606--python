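"""Ectoparasite analysis windows, season levels, and the infestation /
load model battery.

Larval tick burdens (head + ear counts) are analysed April-October;
larval bot fly burdens within each year's infestation window (first to
last week with any infested capture).  Season is dichotomised on the
calendar (August-September = high), with the burden-based criteria the
dichotomy rests on (mean tick burden above 10; more than 10% of mice
infested) recomputed as diagnostics.  Infestation risk is modelled by a
logistic mixed model, load by a negative binomial mixed model
(individual random intercept, plot and year absorbed as fixed effects),
and load among infested mice by a zero-truncated negative binomial whose
non-inflated form is checked against the zero-inflated variant with a
Vuong test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.discrete.count_model import ZeroInflatedNegativeBinomialP
from statsmodels.discrete.truncated_model import TruncatedLFNegativeBinomialP

from .design import ModelSpec, build_design
from .glmm import fit_glmm, vuong_test
from .records import CaptureHistory, category_at
from .results import FitResult
from .timeaxis import month_of_week
from scipy.stats import norm

HIGH_SEASON_MONTHS = (8, 9)
TICK_WINDOW_MONTHS = tuple(range(4, 11))  # April..October


@dataclass
class SeasonWindow:
    """Per-year analysis window with a weekly high/low season level."""

    year: int
    start_week: int
    end_week: int
    level: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.start_week > self.end_week:
            raise ValueError("start_week must not exceed end_week")

    def contains(self, week: int) -> bool:
        return self.start_week <= week <= self.end_week


def _months(events: pd.DataFrame) -> pd.Series:
    return pd.Series(
        [month_of_week(int(y), int(w)) for y, w in zip(events["year"], events["week"])],
        index=events.index,
    )


def tick_window(
    events: pd.DataFrame, exclude_years: tuple[int, ...] = ()
) -> pd.DataFrame:
    """Rows inside the April-October tick season, minus excluded years."""
    keep = _months(events).isin(TICK_WINDOW_MONTHS) & ~events["year"].isin(
        exclude_years
    )
    out = events.loc[keep].copy()
    out.attrs["n_dropped"] = int((~keep).sum())
    return out


def season_level(events: pd.DataFrame) -> pd.Series:
    """Calendar-defined burden season: high for August-September rows."""
    return _months(events).isin(HIGH_SEASON_MONTHS).map({True: "high", False: "low"})


def tick_season_diagnostic(events: pd.DataFrame) -> pd.DataFrame:
    """Mean larval tick burden by calendar month, to confirm the
    dichotomy (high months should exceed 10, low months fall below)."""
    m = _months(events)
    out = (
        pd.DataFrame({"month": m, "ticks": events["ticks"]})
        .groupby("month")["ticks"]
        .mean()
        .rename("mean_burden")
        .reset_index()
    )
    out["level"] = np.where(out["month"].isin(HIGH_SEASON_MONTHS), "high", "low")
    return out


def botfly_season(events_year: pd.DataFrame) -> SeasonWindow | None:
    """Bot fly window of one year: first to last week with any infested
    capture; None (year excluded) when no infestation occurred."""
    year = int(events_year["year"].iloc[0])
    infested = events_year.loc[events_year["botflies"] >= 1, "week"]
    if infested.empty:
        return None
    start, end = int(infested.min()), int(infested.max())
    level = {
        w: ("high" if month_of_week(year, w) in HIGH_SEASON_MONTHS else "low")
        for w in range(start, end + 1)
    }
    return SeasonWindow(year=year, start_week=start, end_week=end, level=level)


def botfly_windows(events: pd.DataFrame) -> dict[int, SeasonWindow]:
    out = {}
    for year, sub in events.groupby("year"):
        w = botfly_season(sub)
        if w is not None:
            out[int(year)] = w
    return out


def botfly_season_diagnostic(events: pd.DataFrame) -> pd.DataFrame:
    """Fraction of captures infested by season level (high should exceed
    10%, low fall below)."""
    lev = season_level(events)
    inf = (events["botflies"] >= 1).astype(float)
    return (
        pd.DataFrame({"level": lev, "infested": inf})
        .groupby("level")["infested"]
        .mean()
        .rename("fraction_infested")
        .reset_index()
    )


def burden_rows(
    histories: dict[str, CaptureHistory],
    parasite: str,
    exclude_years: tuple[int, ...] = (),
) -> pd.DataFrame:
    """Per-capture analysis rows for one parasite inside its window."""
    if parasite not in ("tick", "botfly"):
        raise ValueError("parasite must be 'tick' or 'botfly'")
    events = pd.concat(
        [h.events.assign(tag=t, sex=h.sex) for t, h in histories.items()],
        ignore_index=True,
    )
    count_col = "ticks" if parasite == "tick" else "botflies"
    events = events.dropna(subset=[count_col])
    if parasite == "tick":
        events = tick_window(events, exclude_years)
    else:
        windows = botfly_windows(events)
        keep = [
            (int(y) in windows and windows[int(y)].contains(int(w)))
            for y, w in zip(events["year"], events["week"])
        ]
        events = events.loc[keep].copy()
    cats = [
        category_at(histories[t], int(y), int(w))
        for t, y, w in zip(events["tag"], events["year"], events["week"])
    ]
    out = pd.DataFrame(
        {
            "tag": events["tag"].to_numpy(),
            "plot": events["plot"].to_numpy(),
            "year": events["year"].to_numpy(),
            "week": events["week"].to_numpy(),
            "season_level": season_level(events).to_numpy(),
            "sex": events["sex"].to_numpy(),
            "age": events["age"].to_numpy(),
            "mass_g": events["mass_g"].to_numpy(),
            "category": cats,
            "count": events[count_col].astype(int).to_numpy(),
        }
    )
    out["infested"] = (out["count"] >= 1).astype(int)
    return out


def _parasite_spec(response: str, future_level: str | None, with_mass: bool) -> ModelSpec:
    levels = ["none", "tail", "limb", "eye"]
    if future_level == "pooled":
        levels.append("future_impaired")
    elif future_level == "by_type":
        levels += ["future_tail", "future_limb", "future_eye"]
    return ModelSpec(
        response=response,
        categorical={
            "category": "none",
            "season_level": "low",
            "sex": "F",
            "age": "adult",
        },
        levels={
            "category": levels,
            "season_level": ["low", "high"],
            "sex": ["F", "M"],
            "age": ["adult", "juvenile", "subadult"],
        },
        numeric=["mass_g"] if with_mass else [],
        interactions=[("sex", "season_level")],
        random=["tag"],
    )


def _prepare(rows: pd.DataFrame, future_level, with_mass):
    df = rows.copy()
    from .mass import collapse_category

    df["category"] = collapse_category(df["category"], future_level)
    if with_mass:
        df = df.dropna(subset=["mass_g"])
    # plot/year enter the design as fixed adjustments
    spec = _parasite_spec("count", future_level, with_mass)
    X, names = build_design(df, spec)
    for col in ("plot", "year"):
        vals = df[col].astype(str)
        levs = sorted(vals.unique())
        for lev in levs[1:]:
            X = np.column_stack([X, (vals == lev).astype(float)])
            names.append(f"{col}[{lev}]")
    return df, X, names


def fit_logistic_mixed(
    rows: pd.DataFrame,
    future_level: str | None = None,
    with_mass: bool = True,
    n_nodes: int = 9,
) -> FitResult:
    """Odds of infestation vs impairment level (exp(estimate) = OR)."""
    df, X, names = _prepare(rows, future_level, with_mass)
    fit = fit_glmm(
        df["infested"].to_numpy(float), X, names, df["tag"].to_numpy(),
        family="binomial", n_nodes=n_nodes,
    )
    if not np.isfinite(fit.fixed_effects["estimate"]).all() or (
        np.abs(fit.fixed_effects["estimate"]) > 15
    ).any():
        fit.metadata["separation"] = True
    return fit


def fit_nb_mixed(
    rows: pd.DataFrame,
    future_level: str | None = None,
    with_mass: bool = True,
    n_nodes: int = 9,
) -> FitResult:
    """Parasite load vs impairment level (exp(estimate) = IRR)."""
    df, X, names = _prepare(rows, future_level, with_mass)
    return fit_glmm(
        df["count"].to_numpy(float), X, names, df["tag"].to_numpy(),
        family="negbin", n_nodes=n_nodes,
    )


def fit_ztnb(rows: pd.DataFrame, future_level: str | None = None,
             with_mass: bool = True) -> FitResult:
    """Zero-truncated NB for load among infested mice (counts >= 1)."""
    if (rows["count"] < 1).any():
        raise ValueError("zero-truncated model requires counts >= 1")
    df, X, names = _prepare(rows, future_level, with_mass)
    model = TruncatedLFNegativeBinomialP(
        df["count"].to_numpy(float), X, truncation=0
    )
    res = model.fit(method="bfgs", maxiter=500, disp=False)
    p = X.shape[1]
    z = norm.ppf(0.975)
    beta, se = np.asarray(res.params[:p]), np.asarray(res.bse[:p])
    fe = pd.DataFrame(
        {
            "estimate": beta,
            "ci_low": beta - z * se,
            "ci_high": beta + z * se,
            "p": 2 * norm.sf(np.abs(beta) / se),
        },
        index=names,
    )
    boundary = bool(np.exp(res.params[:p] @ X.mean(axis=0)) < 1e-6)
    return FitResult(
        fixed_effects=fe,
        random_effects=pd.DataFrame(columns=["variance", "sd"]),
        aic=float(res.aic),
        n_obs=len(df),
        loglike=float(res.llf),
        metadata={
            "alpha": float(res.params[-1]),
            "boundary": boundary,
            "statsmodels_result": res,
        },
    )


def ztnb_vs_zinb(rows: pd.DataFrame, future_level: str | None = None,
                 with_mass: bool = True) -> dict:
    """Fit the plain NB and its zero-inflated version on the full count
    rows and compare with the Vuong test (positive statistic favours the
    plain model)."""
    df, X, names = _prepare(rows, future_level, with_mass)
    y = df["count"].to_numpy(float)
    nb = sm.NegativeBinomial(y, X).fit(method="bfgs", maxiter=500, disp=False)
    zinb = ZeroInflatedNegativeBinomialP(
        y, X, exog_infl=np.ones((len(y), 1))
    ).fit(method="bfgs", maxiter=500, disp=False)
    stat, p = vuong_test(nb, zinb)
    return {
        "vuong_statistic": stat,
        "vuong_p": p,
        "nb_aic": float(nb.aic),
        "zinb_aic": float(zinb.aic),
    }
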