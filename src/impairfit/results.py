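"""Shared result containers used by every model stage."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd


@dataclass
class FitResult:
    """Uniform output of every model stage.

    ``fixed_effects`` has one row per term with columns
    ``estimate, ci_low, ci_high, p``; ``random_effects`` one row per
    variance component with columns ``variance, sd``. Estimates are on the
    link scale of the model that produced them (grams for a Gaussian mass
    model, log-odds for a logistic model, log-rate for a count model);
    helpers such as :func:`exp_effects` translate to OR/IRR scale.
    """

    fixed_effects: pd.DataFrame
    random_effects: pd.DataFrame
    aic: float
    n_obs: int
    n_groups: dict[str, int] = field(default_factory=dict)
    loglike: float = float("nan")
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        fe = self.fixed_effects
        if len(fe):
            bad = (fe["ci_low"] > fe["estimate"] + 1e-12) | (
                fe["ci_high"] < fe["estimate"] - 1e-12
            )
            if bad.any():
                raise ValueError(
                    f"confidence bounds do not bracket estimates: {list(fe.index[bad])}"
                )
        re = self.random_effects
        if len(re) and (re["variance"] < -1e-12).any():
            raise ValueError("negative variance component")

    def coef(self, term: str) -> float:
        return float(self.fixed_effects.loc[term, "estimate"])

    def ci(self, term: str) -> tuple[float, float]:
        row = self.fixed_effects.loc[term]
        return float(row["ci_low"]), float(row["ci_high"])

    def covers(self, term: str, value: float) -> bool:
        lo, hi = self.ci(term)
        return lo <= value <= hi

    def exp_effects(self) -> pd.DataFrame:
        """Fixed effects exponentiated to ratio scale (OR/IRR/HR)."""
        out = self.fixed_effects.copy()
        for c in ("estimate", "ci_low", "ci_high"):
            out[c] = np.exp(out[c])
        return out

    def summary(self) -> str:
        lines = [f"n_obs={self.n_obs}  loglike={self.loglike:.3f}  AIC={self.aic:.2f}"]
        lines.append(self.fixed_effects.to_string(float_format=lambda v: f"{v:.4g}"))
        if len(self.random_effects):
            lines.append("random effects:")
            lines.append(
                self.random_effects.to_string(float_format=lambda v: f"{v:.4g}")
            )
        return "\n".join(lines)


@dataclass
class MatchedSet:
    """One case with its eligible controls and the keys that bound them."""

    case_tag: str
    control_tags: list[str]
    keys: tuple
    case_pre_period_weeks: float = float("nan")

    def __len__(self) -> int:
        return len(self.control_tags)
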