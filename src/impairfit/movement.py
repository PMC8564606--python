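"""Centre-of-activity / mean-squared-distance home-range statistics.

A mouse's seasonal home range within a plot is summarised by the mean
squared distance (MSD, m^2) of its capture stations from their centroid
(the centre of activity).  Only residents -- at least three captures in
the same plot, year and season -- get an MSD.  Centres within 15 m of
the grid boundary are flagged (edge effects shrink apparent ranges) and
reported as a diagnostic, not adjusted for.  The natural log of MSD is
modelled with the same crossed random-intercept machinery as mass.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import ModelSpec
from .lmm import fit_lmm
from .records import CaptureHistory, TrapGrid, category_at
from .results import FitResult
from .timeaxis import season_of_week

EDGE_BUFFER_M = 15.0
#: added inside the log for residents whose captures were all at one
#: station (MSD 0); such rows are counted in the fit metadata
ZERO_MSD_OFFSET_M2 = 1.0


def center_of_activity(coords: np.ndarray) -> tuple[float, float]:
    """Arithmetic mean coordinate; repeat captures count repeatedly."""
    coords = np.asarray(coords, float)
    if coords.size == 0:
        raise ValueError("no coordinates")
    return float(coords[:, 0].mean()), float(coords[:, 1].mean())


def msd(coords: np.ndarray) -> float:
    """Mean squared Euclidean distance to the centre of activity (m^2)."""
    coords = np.asarray(coords, float)
    if len(coords) < 3:
        raise ValueError(
            "MSD needs >=3 captures; apply the residency filter upstream"
        )
    cx, cy = center_of_activity(coords)
    return float(np.mean((coords[:, 0] - cx) ** 2 + (coords[:, 1] - cy) ** 2))


def residency_filter(
    history: CaptureHistory, plot: str, year: int, season: str
) -> bool:
    """Resident in a (plot, year, season) cell iff captured >= 3 times there."""
    ev = history.events
    n = 0
    for _, e in ev.iterrows():
        if (
            e["plot"] == plot
            and int(e["year"]) == year
            and season_of_week(int(e["year"]), int(e["week"])) == season
        ):
            n += 1
    return n >= 3


def edge_flag(center: tuple[float, float], grid: TrapGrid) -> bool:
    """True iff the centre lies within 15 m of any grid boundary (centres
    outside the grid are flagged true)."""
    x, y = center
    if not (0 <= x <= grid.extent and 0 <= y <= grid.extent):
        return True
    d = min(x, y, grid.extent - x, grid.extent - y)
    return d < EDGE_BUFFER_M


def seasonal_category(cell_events: pd.DataFrame, history: CaptureHistory) -> str:
    """Impairment level of a seasonal cell: the status at its last capture
    (mice can change status mid-season; the final status is used)."""
    last = cell_events.sort_values(["year", "week", "day"]).iloc[-1]
    return category_at(history, int(last["year"]), int(last["week"]))


def movement_records(
    histories: dict[str, CaptureHistory],
    grids: dict[str, TrapGrid],
) -> pd.DataFrame:
    """One MSD record per resident (tag, plot, year, season) cell."""
    rows = []
    for tag, h in histories.items():
        ev = h.events.copy()
        ev["season"] = [
            season_of_week(int(y), int(w)) for y, w in zip(ev["year"], ev["week"])
        ]
        for (plot, year, season), cell in ev.groupby(["plot", "year", "season"]):
            if len(cell) < 3:
                continue
            coords = cell[["x", "y"]].to_numpy(float)
            center = center_of_activity(coords)
            last = cell.sort_values(["year", "week", "day"]).iloc[-1]
            rows.append(
                dict(
                    tag=tag,
                    plot=plot,
                    year=int(year),
                    season=season,
                    n_captures=len(cell),
                    center_x=center[0],
                    center_y=center[1],
                    msd=msd(coords),
                    edge=edge_flag(center, grids[plot]),
                    category=category_at(h, int(last["year"]), int(last["week"])),
                    sex=h.sex,
                    age=str(last["age"]),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "tag", "plot", "year", "season", "n_captures", "center_x", "center_y",
            "msd", "edge", "category", "sex", "age",
        ],
    )


def logmsd_model_spec(interaction: bool) -> ModelSpec:
    return ModelSpec(
        response="msd",
        categorical={
            "category": "none",
            "sex": "M",
            "season": "fall",
            "age": "adult",
        },
        levels={
            "category": ["none", "tail", "limb", "eye", "future_impaired"],
            "sex": ["M", "F"],
            "season": ["fall", "spring", "summer"],
            "age": ["adult", "juvenile", "subadult"],
        },
        interactions=[("sex", "season")] if interaction else [],
        random=["tag", "plot", "year"],
        family="gaussian",
        transform="log",
    )


def fit_lmm_logmsd(
    records: pd.DataFrame,
    interaction: str = "aic",
    reml: bool = True,
) -> FitResult:
    """Mixed model of log(MSD) on the five-level impairment factor.

    ``interaction`` = 'with'/'without' forces the sex x season term;
    'aic' fits both and keeps the smaller-AIC structure (AIC from the ML
    criterion).  Reference levels: impairment absent, sex male, season
    fall, age adult.
    """
    from .stats import aic_select

    df = records.copy()
    df["category"] = df["category"].where(
        ~df["category"].str.startswith("future_"), "future_impaired"
    )
    if interaction in ("with", "without"):
        fit = fit_lmm(
            df, logmsd_model_spec(interaction == "with"), reml=reml,
            zero_offset=ZERO_MSD_OFFSET_M2,
        )
        fit.metadata["interaction"] = interaction
        return fit
    fits = {
        "without": fit_lmm(
            df, logmsd_model_spec(False), reml=reml, zero_offset=ZERO_MSD_OFFSET_M2
        ),
        "with": fit_lmm(
            df, logmsd_model_spec(True), reml=reml, zero_offset=ZERO_MSD_OFFSET_M2
        ),
    }
    best_name, _ = aic_select(fits)
    best = fits[best_name]
    best.metadata["interaction"] = best_name
    best.metadata["aic_candidates"] = {k: v.aic for k, v in fits.items()}
    return best


def percent_msd_effect(beta: float) -> float:
    """Log-scale coefficient as percent change in mean MSD."""
    return float((np.exp(beta) - 1.0) * 100.0)
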