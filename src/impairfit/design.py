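"""Fixed-effects design matrices with explicit reference levels.

Every model stage in the package reports coefficients against the
reference levels printed in its summary tables, so the design builder is
explicit rather than formula-driven: categorical terms are treatment-coded
against a named reference, and two-way interactions are products of the
coded columns.  Term names follow the ``col[level]`` and
``a[la]:b[lb]`` convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ModelSpec:
    """Declarative model description shared by the fitting stages."""

    response: str
    categorical: dict[str, str] = field(default_factory=dict)  # column -> reference
    levels: dict[str, list[str]] = field(default_factory=dict)  # optional level order
    numeric: list[str] = field(default_factory=list)
    interactions: list[tuple[str, str]] = field(default_factory=list)
    random: list[str] = field(default_factory=list)
    family: str = "gaussian"
    transform: str = "none"  # none | log

    def __post_init__(self):
        for col, ref in self.categorical.items():
            if col in self.levels and ref not in self.levels[col]:
                raise ValueError(f"reference {ref!r} not among levels of {col!r}")


def _coded_columns(df: pd.DataFrame, col: str, ref: str, levels=None):
    observed = list(pd.unique(df[col].astype(str)))
    if levels is None:
        levels = [ref] + sorted(l for l in observed if l != ref)
    if ref not in levels:
        raise ValueError(f"reference level {ref!r} missing for {col!r}")
    cols, names = [], []
    vals = df[col].astype(str).to_numpy()
    for lev in levels:
        if lev == ref or lev not in observed:
            continue
        cols.append((vals == lev).astype(float))
        names.append(f"{col}[{lev}]")
    return cols, names


def build_design(df: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    """Intercept + treatment-coded categoricals + numerics + interactions."""
    n = len(df)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    coded: dict[str, tuple[list[np.ndarray], list[str]]] = {}
    for col, ref in spec.categorical.items():
        c, nm = _coded_columns(df, col, ref, spec.levels.get(col))
        coded[col] = (c, nm)
        cols += c
        names += nm
    for col in spec.numeric:
        cols.append(df[col].astype(float).to_numpy())
        names.append(col)
    for a, b in spec.interactions:
        if a in coded and b in coded:
            for ca, na in zip(*coded[a]):
                for cb, nb in zip(*coded[b]):
                    cols.append(ca * cb)
                    names.append(f"{na}:{nb}")
        elif a in coded:
            for ca, na in zip(*coded[a]):
                cols.append(ca * df[b].astype(float).to_numpy())
                names.append(f"{na}:{b}")
        elif b in coded:
            for cb, nb in zip(*coded[b]):
                cols.append(df[a].astype(float).to_numpy() * cb)
                names.append(f"{a}:{nb}")
        else:
            cols.append(df[a].astype(float).to_numpy() * df[b].astype(float).to_numpy())
            names.append(f"{a}:{b}")
    X = np.column_stack(cols)
    keep = [
        i
        for i in range(X.shape[1])
        if i == 0 or X[:, i].std() > 0 or X[:, i].any()
    ]
    return X[:, keep], [names[i] for i in keep]
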