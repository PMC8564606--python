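"""Adult mass table, mixed model, percent effects, matched case-control."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from impairfit.mass import (
    adult_mass_table,
    conditional_logistic,
    fit_lmm_mass,
    match_mass_controls,
    percent_effect,
    pre_impaired_rows,
    unimpaired_capture_rows,
)
from impairfit.records import build_histories
from impairfit.results import MatchedSet
from impairfit.timeaxis import abs_week
from tests.conftest import make_events


class TestAdultMassTable:
    @pytest.mark.parametrize(
        "age,mass,included",
        [
            ("adult", 11.0, False),   # strictly above 11 g
            ("adult", 11.01, True),
            ("adult", 40.0, True),    # inclusive upper bound
            ("adult", 40.01, False),
            ("juvenile", 15.0, False),
            ("adult", np.nan, False),
        ],
    )
    def test_inclusion_rules(self, age, mass, included):
        ev = make_events([{"age": age, "mass_g": mass}, {"age": age, "mass_g": mass, "week": 23}])
        rows = adult_mass_table(build_histories(ev))
        assert (len(rows) == 2) is included

    def test_future_and_post_onset_categories(self):
        ev = make_events(
            [
                {"week": 20, "mass_g": 20.0},
                {"week": 27, "mass_g": 21.0, "impair_codes": "tail_broken"},
            ]
        )
        rows = adult_mass_table(build_histories(ev)).set_index("week")
        assert rows.loc[20, "category"] == "future_tail"
        assert rows.loc[27, "category"] == "tail"

    def test_season_assignment(self):
        ev = make_events([{"week": 20}, {"week": 30}, {"week": 40}])
        rows = adult_mass_table(build_histories(ev))
        assert list(rows["season"]) == ["spring", "summer", "fall"]


class TestPercentEffect:
    def test_paper_scale_values(self):
        assert round(percent_effect(1.44, 22.76)) == 6
        assert round(percent_effect(1.09, 22.76)) == 5
        assert percent_effect(0.0, 22.76) == 0.0

    def test_invalid_baseline(self):
        with pytest.raises(ValueError):
            percent_effect(1.0, 0.0)

    @given(
        coef=st.floats(-10, 10),
        baseline=st.floats(1.0, 100.0),
        c=st.floats(0.1, 10.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_linear_and_scale_invariant(self, coef, baseline, c):
        assert percent_effect(2 * coef, baseline) == pytest.approx(
            2 * percent_effect(coef, baseline), rel=1e-9, abs=1e-9
        )
        assert percent_effect(c * coef, c * baseline) == pytest.approx(
            percent_effect(coef, baseline), rel=1e-9, abs=1e-9
        )


class TestMassLMM:
    def test_noiseless_fixed_effects_recovered(self):
        rng = np.random.default_rng(0)
        rows = []
        effects = {"none": 0.0, "tail": 1.44, "limb": 0.0, "eye": 1.09}
        for i in range(300):
            cat = ["none", "tail", "limb", "eye"][rng.integers(4)]
            sex = "M" if rng.integers(2) else "F"
            season = ["fall", "spring", "summer"][rng.integers(3)]
            mass = (
                22.76 + effects[cat] + (-0.81 if sex == "M" else 0.0)
                + {"fall": 0.0, "spring": 0.5, "summer": -1.91}[season]
            )
            for wk in (20, 21):  # two captures per mouse
                rows.append(
                    dict(tag=f"m{i}", plot="GX", year=2015, week=wk, season=season,
                         sex=sex, category=cat, mass_g=mass)
                )
        fit = fit_lmm_mass(pd.DataFrame(rows))
        assert fit.coef("intercept") == pytest.approx(22.76, abs=1e-6)
        assert fit.coef("category[tail]") == pytest.approx(1.44, abs=1e-6)
        assert fit.coef("category[eye]") == pytest.approx(1.09, abs=1e-6)
        assert fit.coef("sex[M]") == pytest.approx(-0.81, abs=1e-6)

    def test_reference_levels_absent_from_terms(self, small_histories):
        fit = fit_lmm_mass(adult_mass_table(small_histories))
        terms = set(fit.fixed_effects.index)
        assert "category[none]" not in terms and "sex[F]" not in terms
        assert {"category[tail]", "sex[M]", "season[spring]"} <= terms
        assert {"tag", "plot", "year", "residual"} == set(fit.random_effects.index)

    def test_five_level_fit_adds_future_level(self, small_histories):
        fit = fit_lmm_mass(adult_mass_table(small_histories), future_level="pooled")
        assert "category[future_impaired]" in fit.fixed_effects.index


class TestMassMatching:
    def pool(self):
        return pd.DataFrame(
            [
                dict(tag="k1", plot="GX", year=2015, week=30, sex="F", age="adult", mass_g=21.0),
                dict(tag="k2", plot="GX", year=2015, week=30, sex="M", age="adult", mass_g=22.0),
                dict(tag="k3", plot="HC", year=2015, week=31, sex="F", age="adult", mass_g=23.0),
            ]
        )

    def test_exact_match(self):
        cases = pd.DataFrame(
            [dict(tag="c", plot="GX", year=2015, week=30, sex="F", age="adult", mass_g=25.0)]
        )
        sets, dropped = match_mass_controls(cases, self.pool())
        assert len(sets) == 1 and sets[0].control_tags == ["k1"]

    def test_adjacent_week_fallback_on_other_plot(self):
        cases = pd.DataFrame(
            [dict(tag="c", plot="GX", year=2015, week=32, sex="F", age="adult", mass_g=25.0)]
        )
        sets, _ = match_mass_controls(cases, self.pool())
        assert len(sets) == 1 and sets[0].control_tags == ["k3"]
        assert sets[0].keys[-1] == "adjacent"

    def test_fallback_requires_other_plot(self):
        pool = self.pool()
        pool.loc[2, "plot"] = "GX"  # adjacent-week candidate now on same plot
        cases = pd.DataFrame(
            [dict(tag="c", plot="GX", year=2015, week=32, sex="F", age="adult", mass_g=25.0)]
        )
        sets, dropped = match_mass_controls(cases, pool)
        assert sets == [] and dropped == ["c"]

    def test_brute_force_oracle_on_simulated_cohort(self, small_histories):
        cases = pre_impaired_rows(small_histories)
        pool = unimpaired_capture_rows(small_histories)
        sets, dropped = match_mass_controls(cases, pool)
        assert len(sets) >= 20
        pool = pool.assign(absweek=abs_week(pool["year"], pool["week"]))
        cmap = cases.set_index("tag")
        violations = 0
        for s in sets:
            c = cmap.loc[s.case_tag]
            wk = int(abs_week(c["year"], c["week"]))
            base = pool[(pool["sex"] == c["sex"]) & (pool["age"] == c["age"])]
            exact = base[(base["absweek"] == wk) & (base["plot"] == c["plot"])]
            if len(exact):
                expected = set(exact["tag"])
            else:
                expected = set(
                    base[
                        base["absweek"].isin([wk - 1, wk + 1])
                        & (base["plot"] != c["plot"])
                    ]["tag"]
                )
            if set(s.control_tags) != expected or not expected:
                violations += 1
        assert violations == 0


class TestConditionalLogistic:
    def test_two_set_symmetric_instance_gives_zero(self):
        sets = [MatchedSet("c1", ["k1"], ()), MatchedSet("c2", ["k2"], ())]
        beta = conditional_logistic(
            sets,
            pd.Series({"c1": 1.0, "c2": 0.0}),
            pd.Series({"k1": 0.0, "k2": 1.0}),
        ).coef("exposure")
        assert beta == pytest.approx(0.0, abs=1e-10)

    def test_closed_form_log2(self):
        # two sets case-higher, one reversed: beta_hat = ln(2) exactly
        sets = [MatchedSet(f"c{i}", [f"k{i}"], ()) for i in range(3)]
        beta = conditional_logistic(
            sets,
            pd.Series({"c0": 1.0, "c1": 1.0, "c2": 0.0}),
            pd.Series({"k0": 0.0, "k1": 0.0, "k2": 1.0}),
        ).coef("exposure")
        assert beta == pytest.approx(np.log(2), abs=1e-10)

    def test_within_set_shift_invariance(self):
        sets = [MatchedSet(f"c{i}", [f"k{i}"], ()) for i in range(3)]
        case = pd.Series({"c0": 20.0, "c1": 23.0, "c2": 19.0})
        ctrl = pd.Series({"k0": 19.0, "k1": 24.0, "k2": 21.0})
        b1 = conditional_logistic(sets, case, ctrl).coef("exposure")
        # shift set 1 by +5 on both sides
        case2 = case.copy(); ctrl2 = ctrl.copy()
        case2["c1"] += 5; ctrl2["k1"] += 5
        b2 = conditional_logistic(sets, case2, ctrl2).coef("exposure")
        assert b1 == pytest.approx(b2, abs=1e-8)

    def test_separation_detected(self):
        sets = [MatchedSet(f"c{i}", [f"k{i}"], ()) for i in range(4)]
        case = pd.Series({f"c{i}": 10.0 for i in range(4)})
        ctrl = pd.Series({f"k{i}": 0.0 for i in range(4)})
        fit = conditional_logistic(sets, case, ctrl)
        assert fit.metadata["separation"]

    def test_constant_exposure_rejected(self):
        sets = [MatchedSet("c0", ["k0"], ())]
        with pytest.raises(ValueError, match="constant"):
            conditional_logistic(
                sets, pd.Series({"c0": 1.0}), pd.Series({"k0": 1.0})
            )

    def test_null_simulation_covers_or_one(self, small_histories):
        cases = pre_impaired_rows(small_histories)
        pool = unimpaired_capture_rows(small_histories)
        sets, _ = match_mass_controls(cases, pool)
        fit = conditional_logistic(
            sets,
            cases.set_index("tag")["mass_g"],
            pool.groupby("tag")["mass_g"].mean(),
        )
        lo, hi = np.exp(fit.ci("exposure"))
        assert lo <= 1.0 <= hi
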