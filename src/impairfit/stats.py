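"""Shared inference utilities: AIC selection, change-in-estimate
confounder screening, and simple descriptive association tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .results import FitResult


def _n_params(fit: FitResult) -> int:
    if "n_params" in fit.metadata:
        return int(fit.metadata["n_params"])
    return len(fit.fixed_effects) + len(fit.random_effects)


def aic_select(fits: dict[str, FitResult]) -> tuple[str, pd.DataFrame]:
    """Smallest-AIC model among candidates fit on identical rows.

    Ties break toward the model with fewer parameters.  Returns the
    winning name and a ranking table.
    """
    if not fits:
        raise ValueError("no candidate fits")
    n_obs = {f.n_obs for f in fits.values()}
    if len(n_obs) > 1:
        raise ValueError("candidates were fit on different row sets")
    rank = pd.DataFrame(
        {
            "aic": {k: f.aic for k, f in fits.items()},
            "n_params": {k: _n_params(f) for k, f in fits.items()},
        }
    ).sort_values(["aic", "n_params"], kind="mergesort")
    rank["delta_aic"] = rank["aic"] - rank["aic"].iloc[0]
    return rank.index[0], rank


def change_in_estimate(
    base_fit: FitResult,
    fit_with_covariate: FitResult,
    focal_term: str,
    threshold: float = 0.10,
) -> tuple[bool, float]:
    """Confounder screen: keep the covariate iff adding it moves the focal
    coefficient by at least ``threshold`` (relative).  A zero base
    coefficient falls back to absolute change (flag in the return)."""
    b0 = base_fit.coef(focal_term)
    b1 = fit_with_covariate.coef(focal_term)
    if b0 == 0:
        change = abs(b1 - b0)
    else:
        change = abs(b1 - b0) / abs(b0)
    return change >= threshold, float(change)


def chi_square_assoc(table) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence on a two-way count table."""
    table = np.asarray(table, float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    stat, p, dof, expected = sps.chi2_contingency(table, correction=False)
    if (expected <= 0).any():
        raise ValueError("expected counts must be positive")
    return float(stat), int(dof), float(p)


def pearson_corr(x, y) -> tuple[float, int, float]:
    """Product-moment correlation with t-based p; df = n - 2."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance series")
    r, p = sps.pearsonr(x, y)
    return float(r), len(x) - 2, float(p)


def impairment_prevalence(n_impaired: int, n_total: int) -> float:
    """Percent of monitored individuals with a recorded impairment."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return 100.0 * n_impaired / n_total


def describe_cohort(histories) -> dict:
    """Descriptive battery: prevalence, sex-by-impairment chi-squared and
    the yearly impaired-vs-total correlation.  Raw p-values; no
    multiple-testing correction is applied."""
    cats = {t: (h.impairment.general if h.impairment else "none") for t, h in histories.items()}
    sexes = {t: h.sex for t, h in histories.items()}
    first_years = {t: h.first_capture[0] for t, h in histories.items()}
    n_total = len(cats)
    n_impaired = sum(1 for c in cats.values() if c != "none")
    out = {
        "n_individuals": n_total,
        "n_impaired": n_impaired,
        "prevalence_percent": impairment_prevalence(n_impaired, n_total)
        if n_total
        else np.nan,
    }
    tab = pd.crosstab(
        pd.Series(sexes, name="sex"), pd.Series(cats, name="impaired") != "none"
    )
    tab = tab.loc[[s for s in ("F", "M") if s in tab.index]]
    if tab.shape == (2, 2) and (tab.to_numpy() > 0).all():
        stat, dof, p = chi_square_assoc(tab.to_numpy())
        out["sex_chi2"] = stat
        out["sex_chi2_p"] = p
    yearly = pd.DataFrame(
        {
            "year": pd.Series(first_years),
            "impaired": pd.Series(cats) != "none",
        }
    )
    g = yearly.groupby("year")["impaired"].agg(["sum", "count"])
    if len(g) >= 3 and g["sum"].std() > 0 and g["count"].std() > 0:
        r, dof, p = pearson_corr(g["sum"], g["count"])
        out["yearly_corr_r"] = r
        out["yearly_corr_p"] = p
    return out
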