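"""Capture-event data model: read/validate/write capture tables, assemble
per-individual histories, and classify impairments.

The canonical table is a long-format CSV, one row per capture, with columns

    tag,plot,year,week,day,x,y,sex,age,mass_g,ticks,botflies,impair_codes,tail_snip

``impair_codes`` is a semicolon-joined list from the controlled vocabulary
(tail_missing/tail_partial/tail_broken, limb_missing/limb_partial/
limb_broken, eye_missing/cataract).  ``tail_snip`` marks mice whose only
tail damage is the 1 mm tissue snip taken for sampling; such events are
treated as unimpaired.  The schema (and the reader/simulator dialect) is
versioned in ``data/schema.yaml``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .timeaxis import abs_week

CANONICAL_COLUMNS = [
    "tag", "plot", "year", "week", "day", "x", "y",
    "sex", "age", "mass_g", "ticks", "botflies", "impair_codes", "tail_snip",
]

GENERAL_CATEGORIES = ("none", "tail", "limb", "eye")
SPECIFIC_BY_GENERAL = {
    "tail": ("tail_missing", "tail_partial", "tail_broken"),
    "limb": ("limb_missing", "limb_partial", "limb_broken"),
    "eye": ("eye_missing", "cataract"),
}
GENERAL_OF_CODE = {
    code: gen for gen, codes in SPECIFIC_BY_GENERAL.items() for code in codes
}
VALID_CODES = frozenset(GENERAL_OF_CODE)


def load_schema() -> dict:
    text = (
        importlib.resources.files("impairfit").joinpath("data/schema.yaml").read_text()
    )
    return yaml.safe_load(text)


@dataclass(frozen=True)
class TrapGrid:
    """A square trapping plot with a regular grid of stations.

    Default geometry is an 11 x 11 grid at 15 m spacing on a 150 m plot,
    coordinates in meters with origin at the plot's SW corner.
    """

    plot_id: str
    spacing: float = 15.0
    extent: float = 150.0

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.extent < 0:
            raise ValueError("extent must be non-negative")

    @property
    def n_per_side(self) -> int:
        return int(round(self.extent / self.spacing)) + 1

    @property
    def station_coords(self) -> np.ndarray:
        ticks = np.arange(self.n_per_side) * self.spacing
        xx, yy = np.meshgrid(ticks, ticks, indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel()])

    def contains(self, x: float, y: float, tol: float = 1e-9) -> bool:
        """Whether (x, y) is a station of this grid."""
        if not (0 - tol <= x <= self.extent + tol and 0 - tol <= y <= self.extent + tol):
            return False
        return (
            abs(x / self.spacing - round(x / self.spacing)) < tol
            and abs(y / self.spacing - round(y / self.spacing)) < tol
        )

    def nearest_station(self, x: float, y: float) -> tuple[float, float]:
        """Grid station nearest to an arbitrary point (clipped to the plot)."""
        gx = np.clip(round(x / self.spacing), 0, self.n_per_side - 1)
        gy = np.clip(round(y / self.spacing), 0, self.n_per_side - 1)
        return gx * self.spacing, gy * self.spacing


@dataclass
class ValidationReport:
    """Row-level problems found while reading a capture table."""

    n_rows: int = 0
    n_valid: int = 0
    errors: list[tuple[int, str]] = field(default_factory=list)
    warnings: list[tuple[int, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def add_error(self, line: int, message: str) -> None:
        self.errors.append((int(line), message))

    def to_frame(self) -> pd.DataFrame:
        rows = [("error", ln, msg) for ln, msg in self.errors]
        rows += [("warning", ln, msg) for ln, msg in self.warnings]
        return pd.DataFrame(rows, columns=["severity", "line", "message"])

    def __str__(self) -> str:
        head = f"{self.n_valid}/{self.n_rows} rows valid"
        if self.ok and not self.warnings:
            return head + ", no problems"
        body = "\n".join(
            f"  line {ln}: {msg}" for ln, msg in self.errors + self.warnings
        )
        return f"{head}\n{body}"


@dataclass
class ImpairmentAssignment:
    """Per-individual impairment classification.

    ``general`` is the four-level exposure (none/tail/limb/eye); once a
    mouse is assigned a category the status is permanent.  ``onset_week``
    is the (year, week) of the first capture bearing an impairment code;
    ``pre_period_weeks`` runs from first capture to the last capture at
    which the mouse was still recorded unimpaired.  ``future_impaired_events``
    are positional indices (into the sorted history) of unimpaired captures
    that predate onset.
    """

    tag: str
    general: str = "none"
    specific: str = "none"
    onset_week: tuple[int, int] | None = None
    pre_period_weeks: float = float("nan")
    future_impaired_events: list[int] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def __post_init__(self):
        if (self.general == "none") != (self.specific == "none"):
            raise ValueError("general and specific must be none together")
        if (self.general == "none") != (self.onset_week is None):
            raise ValueError("onset_week defined iff impaired")


@dataclass
class CaptureHistory:
    """All captures of one tagged individual, time-ordered."""

    tag: str
    sex: str
    events: pd.DataFrame  # sorted by (year, week, day)
    impairment: ImpairmentAssignment | None = None

    @property
    def first_capture(self) -> tuple[int, int]:
        r = self.events.iloc[0]
        return int(r["year"]), int(r["week"])

    @property
    def last_capture(self) -> tuple[int, int]:
        r = self.events.iloc[-1]
        return int(r["year"]), int(r["week"])

    @property
    def first_age(self) -> str:
        return str(self.events.iloc[0]["age"])

    @property
    def modal_plot(self) -> str:
        return self.events["plot"].mode().iloc[0]

    def __len__(self) -> int:
        return len(self.events)


# ---------------------------------------------------------------------------
# reading / writing


def _parse_codes(raw) -> list[str]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return []
    s = str(raw).strip()
    if not s or s.lower() == "nan":
        return []
    return [c for c in (p.strip() for p in s.split(";")) if c]


def read_captures(
    path,
    dialect: dict | None = None,
    grids: dict[str, TrapGrid] | None = None,
) -> tuple[pd.DataFrame, ValidationReport]:
    """Read and validate a capture table.

    ``dialect`` maps file headers to canonical column names (identity by
    default).  If ``grids`` is given, stations are checked for membership
    in each plot's grid.  Malformed rows are collected into the report
    (with 1-based file line numbers, header = line 1) and excluded from
    the returned frame; missing covariates become explicit unknowns
    (NaN / ``U``), never silent zeros.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if dialect:
        unknown = set(dialect.values()) - set(CANONICAL_COLUMNS)
        if unknown:
            raise ValueError(f"dialect maps to unknown canonical columns: {unknown}")
        raw = raw.rename(columns=dialect)
    missing = [c for c in ("tag", "plot", "year", "week", "day", "x", "y") if c not in raw]
    if missing:
        raise ValueError(f"capture table is missing required columns: {missing}")
    for c in CANONICAL_COLUMNS:
        if c not in raw:
            raw[c] = ""
    raw = raw[CANONICAL_COLUMNS]

    report = ValidationReport(n_rows=len(raw))
    lines = np.arange(len(raw)) + 2  # header is file line 1
    bad = np.zeros(len(raw), dtype=bool)
    df = pd.DataFrame(index=raw.index)

    def numeric(col, kind, lo=None, hi=None, required=True):
        s = raw[col].str.strip()
        s = s.mask(s == "")
        vals = pd.to_numeric(s, errors="coerce")
        malformed = s.notna() & vals.isna()
        for ln in lines[malformed]:
            report.add_error(ln, f"{col} not numeric")
        out_dom = vals.notna() & (
            ((vals < lo) if lo is not None else False)
            | ((vals > hi) if hi is not None else False)
        )
        for ln in lines[out_dom]:
            report.add_error(ln, f"{col} out of domain")
        if kind is int:
            frac = vals.notna() & ~out_dom & ~malformed & (vals != np.floor(vals))
            for ln in lines[frac]:
                report.add_error(ln, f"{col} not an integer")
            out_dom = out_dom | frac
        reject = malformed | out_dom
        if required:
            absent = s.isna()
            for ln in lines[absent]:
                report.add_error(ln, f"{col} missing")
            reject = reject | absent
        return vals.where(~(malformed | out_dom)), reject

    for col in ("tag", "plot"):
        s = raw[col].str.strip()
        empty = s == ""
        for ln in lines[empty]:
            report.add_error(ln, f"{col} missing")
        bad |= empty.to_numpy()
        df[col] = s

    v, b = numeric("year", int, 1900, 2100); df["year"] = v; bad |= b.to_numpy()
    v, b = numeric("week", int, 1, 52); df["week"] = v; bad |= b.to_numpy()
    v, b = numeric("day", int, 1, 3); df["day"] = v; bad |= b.to_numpy()
    v, b = numeric("x", float, 0); df["x"] = v; bad |= b.to_numpy()
    v, b = numeric("y", float, 0); df["y"] = v; bad |= b.to_numpy()
    v, b = numeric("mass_g", float, 0, required=False); df["mass_g"] = v; bad |= b.to_numpy()
    v, b = numeric("ticks", int, 0, required=False); df["ticks"] = v; bad |= b.to_numpy()
    v, b = numeric("botflies", int, 0, required=False); df["botflies"] = v; bad |= b.to_numpy()

    sex = raw["sex"].str.strip().str.upper().replace({"": "U", "UNKNOWN": "U"})
    odd = ~sex.isin(["F", "M", "U"])
    for ln in lines[odd]:
        report.warnings.append((int(ln), "unrecognised sex set to U"))
    df["sex"] = sex.where(~odd, "U")

    age = raw["age"].str.strip().str.lower().replace({"": "U", "unknown": "U", "u": "U"})
    odd = ~age.isin(["juvenile", "subadult", "adult", "U"])
    for ln in lines[odd]:
        report.warnings.append((int(ln), "unrecognised age class set to U"))
    df["age"] = age.where(~odd, "U")

    codes = raw["impair_codes"].map(_parse_codes)
    for i, cl in zip(raw.index, codes):
        unknown = [c for c in cl if c not in VALID_CODES]
        if unknown:
            report.add_error(lines[i], f"unknown impairment code {unknown[0]!r}")
            bad[i] = True
    df["impair_codes"] = codes.map(lambda cl: ";".join(cl))

    snip = raw["tail_snip"].str.strip().str.lower()
    df["tail_snip"] = snip.isin(["1", "true", "t", "yes"])

    if grids is not None:
        for i in raw.index[~bad]:
            plot = df.at[i, "plot"]
            if plot not in grids:
                report.add_error(lines[i], f"unknown plot {plot!r}")
                bad[i] = True
            elif not grids[plot].contains(df.at[i, "x"], df.at[i, "y"]):
                report.add_error(
                    lines[i],
                    f"station ({df.at[i, 'x']:g}, {df.at[i, 'y']:g}) not on grid {plot}",
                )
                bad[i] = True

    out = df.loc[~bad].copy()
    dup = out.duplicated(subset=["year", "week", "day", "tag", "plot"], keep="first")
    for ln in lines[out.index[dup]]:
        report.add_error(ln, "duplicate (year, week, day, tag, plot)")
    out = out.loc[~dup]
    for c in ("year", "week", "day"):
        out[c] = out[c].astype(int)
    report.n_valid = len(out)
    return out.reset_index(drop=True), report


def write_captures(events: pd.DataFrame, path) -> None:
    """Write events in the canonical dialect (round-trips with read_captures)."""
    df = events.copy()
    df["tail_snip"] = df["tail_snip"].astype(int)
    df.to_csv(path, index=False, columns=CANONICAL_COLUMNS)


# ---------------------------------------------------------------------------
# histories and impairment classification


def _effective_codes(codes: list[str], tail_snip: bool) -> list[str]:
    """Impairment codes after the tail-snip exclusion: a mouse missing only
    what a snip removed is not tail impaired."""
    if tail_snip:
        return [c for c in codes if GENERAL_OF_CODE[c] != "tail"]
    return list(codes)


def classify_impairment(history: CaptureHistory) -> ImpairmentAssignment:
    """Classify one individual's impairment from its capture history.

    Rules: tail-snip-only tail codes are ignored; if both a tail code and a
    limb-or-eye code ever occur, the general category is the limb/eye one
    (tail yields to the rarer types; a limb-vs-eye tie goes to the earlier
    observed code); onset is the first capture bearing any effective code;
    status is permanent from onset, with later unimpaired records logged,
    not honoured.
    """
    ev = history.events
    if ev.empty:
        raise ValueError("empty history")
    asg = ImpairmentAssignment(tag=history.tag)
    per_event = [
        _effective_codes(_parse_codes(c), bool(s))
        for c, s in zip(ev["impair_codes"], ev["tail_snip"])
    ]
    impaired_idx = [i for i, cl in enumerate(per_event) if cl]
    if not impaired_idx:
        return asg

    onset_i = impaired_idx[0]
    onset_row = ev.iloc[onset_i]
    first_seen: dict[str, tuple[int, str]] = {}
    for i in impaired_idx:
        for code in per_event[i]:
            first_seen.setdefault(GENERAL_OF_CODE[code], (i, code))
    cats = set(first_seen)
    if cats == {"tail"}:
        general = "tail"
    elif "limb" in cats and "eye" in cats:
        general = "limb" if first_seen["limb"][0] <= first_seen["eye"][0] else "eye"
        asg.notes.append("limb/eye tie resolved to earlier-observed code")
    else:
        general = "limb" if "limb" in cats else "eye"
        if "tail" in cats:
            asg.notes.append("tail code yields to rarer limb/eye category")
    specific = first_seen[general][1]

    # gaps: recorded impaired then unimpaired later
    if any(not per_event[i] for i in range(onset_i + 1, len(ev))):
        asg.notes.append("impairment codes absent in some post-onset events")

    pre_events = list(range(onset_i))
    first = history.first_capture
    if pre_events:
        last_un = ev.iloc[pre_events[-1]]
        pre_weeks = int(
            abs_week(int(last_un["year"]), int(last_un["week"]))
            - abs_week(first[0], first[1])
        )
    else:
        pre_weeks = 0
    return ImpairmentAssignment(
        tag=history.tag,
        general=general,
        specific=specific,
        onset_week=(int(onset_row["year"]), int(onset_row["week"])),
        pre_period_weeks=float(pre_weeks),
        future_impaired_events=pre_events,
        notes=asg.notes,
    )


def build_histories(events: pd.DataFrame) -> dict[str, CaptureHistory]:
    """Assemble per-tag histories, sorted in time, with impairment assigned.

    A tag recorded with two sexes gets the majority sex (ties -> U) and a
    note in the impairment assignment.
    """
    if events.empty:
        return {}
    histories: dict[str, CaptureHistory] = {}
    for tag, sub in events.groupby("tag", sort=True):
        sub = sub.sort_values(["year", "week", "day"], kind="mergesort").reset_index(
            drop=True
        )
        sexes = sub["sex"][sub["sex"] != "U"]
        if sexes.nunique() > 1:
            counts = sexes.value_counts()
            sex = "U" if counts.iloc[0] == counts.iloc[1] else counts.index[0]
            note = "conflicting sex records resolved by majority"
        else:
            sex = sexes.iloc[0] if len(sexes) else "U"
            note = None
        h = CaptureHistory(tag=str(tag), sex=str(sex), events=sub)
        h.impairment = classify_impairment(h)
        if note:
            h.impairment.notes.append(note)
        histories[str(tag)] = h
    return histories


def category_at(history: CaptureHistory, year: int, week: int) -> str:
    """Impairment level of one capture: the assigned category after onset,
    ``future_<category>`` before onset, ``none`` for the never impaired."""
    asg = history.impairment
    if asg is None or asg.general == "none":
        return "none"
    if abs_week(year, week) >= abs_week(*asg.onset_week):
        return asg.general
    return f"future_{asg.general}"
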