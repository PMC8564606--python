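"""Persistence records, risk-set matching, KM / log-rank / Cox."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from impairfit.records import build_histories
from impairfit.simulate import simulate_population, study_end
from impairfit.survival import (
    fit_proportional_hazards,
    km_estimate,
    logrank_test,
    match_survival_controls,
    matched_analysis_table,
    persistence_times,
    session_calendar,
)
from impairfit.timeaxis import abs_week
from tests.conftest import make_events


def record(tag, entry=(2015, 10), exit=(2015, 27), category="none", pre=np.nan,
           onset=(np.nan, np.nan), censored=False, sex="F", age="adult"):
    return dict(
        tag=tag, plot="GX", entry_year=entry[0], entry_week=entry[1],
        exit_year=exit[0], exit_week=exit[1],
        persistence_weeks=float(abs_week(*exit) - abs_week(*entry)),
        censored=censored, category=category, pre_period_weeks=pre,
        onset_year=onset[0], onset_week=onset[1], sex=sex, age_first=age,
        multi_plot=False,
    )


class TestPersistenceTimes:
    def test_whole_week_arithmetic(self):
        ev = make_events([{"week": 10}, {"week": 27}])
        hs = build_histories(ev)
        out = persistence_times(hs, {"GX": (2016, 46)})
        assert out.loc[0, "persistence_weeks"] == 17.0
        assert not out.loc[0, "censored"]

    def test_persistence_crosses_years(self):
        ev = make_events([{"week": 46, "year": 2015}, {"week": 18, "year": 2016}])
        out = persistence_times(build_histories(ev), {"GX": (2016, 46)})
        assert out.loc[0, "persistence_weeks"] == 24.0

    def test_single_capture_excluded_as_non_resident(self):
        ev = make_events([{"week": 20}])
        out = persistence_times(build_histories(ev), {"GX": (2016, 46)})
        assert len(out) == 0 and out.attrs["n_excluded"] == 1

    def test_one_week_persistence_excluded(self):
        ev = make_events([{"week": 20}, {"week": 21}])
        out = persistence_times(build_histories(ev), {"GX": (2016, 46)})
        assert len(out) == 0

    def test_final_session_censoring(self):
        ev = make_events([{"week": 20, "year": 2016}, {"week": 46, "year": 2016}])
        out = persistence_times(build_histories(ev), {"GX": (2016, 46)})
        assert bool(out.loc[0, "censored"])


class TestMatching:
    def test_eligibility_boundaries(self):
        # case detected at week 25 (pre-period 5): a control must persist
        # at least to the detection week
        cases = pd.DataFrame([
            record("case", entry=(2015, 10), exit=(2015, 40), category="tail",
                   pre=5.0, onset=(2015, 25)),
        ])
        pool = pd.DataFrame([
            record("ok", entry=(2015, 10), exit=(2015, 25)),      # reaches bar
            record("short", entry=(2015, 10), exit=(2015, 15)),   # == pre-period
            record("other_week", entry=(2015, 11), exit=(2015, 40)),
            record("other_age", entry=(2015, 10), exit=(2015, 40), age="juvenile"),
        ])
        sets, dropped = match_survival_controls(cases, pool)
        assert len(sets) == 1 and sets[0].control_tags == ["ok"]
        assert dropped == []

    def test_case_without_controls_dropped(self):
        cases = pd.DataFrame([
            record("case", category="tail", pre=5.0, onset=(2015, 25)),
        ])
        pool = pd.DataFrame([record("short", exit=(2015, 13))])
        sets, dropped = match_survival_controls(cases, pool)
        assert sets == [] and dropped == ["case"]

    def test_impaired_pool_rejected(self):
        cases = pd.DataFrame([record("c", category="tail", pre=2.0, onset=(2015, 20))])
        pool = pd.DataFrame([record("x", category="eye")])
        with pytest.raises(ValueError):
            match_survival_controls(cases, pool)

    def test_order_invariance(self, small_sim, small_histories):
        cfg, events, _ = small_sim
        persist = persistence_times(small_histories, study_end(cfg))
        cases = persist[persist["category"] != "none"]
        pool = persist[persist["category"] == "none"]
        a, _ = match_survival_controls(cases, pool)
        b, _ = match_survival_controls(cases, pool.sample(frac=1, random_state=1))
        key = lambda sets: {s.case_tag: tuple(s.control_tags) for s in sets}
        assert key(a) == key(b)

    def test_brute_force_eligibility_oracle(self, small_sim, small_histories):
        cfg, events, _ = small_sim
        persist = persistence_times(small_histories, study_end(cfg))
        cases = persist[persist["category"] != "none"]
        pool = persist[persist["category"] == "none"]
        assert len(cases) >= 50 and len(pool) >= 500
        sets, dropped = match_survival_controls(cases, pool)
        cmap = cases.set_index("tag")
        pmap = pool.set_index("tag")
        violations = 0
        for s in sets:
            c = cmap.loc[s.case_tag]
            need = abs_week(int(c.onset_year), int(c.onset_week)) - abs_week(
                int(c.entry_year), int(c.entry_week)
            )
            expected = {
                t for t, r in pmap.iterrows()
                if (r.age_first, r.entry_year, r.entry_week)
                == (c.age_first, c.entry_year, c.entry_week)
                and r.persistence_weeks >= need
            }
            if set(s.control_tags) != expected:
                violations += 1
        assert violations == 0
        assert len(sets) + len(dropped) == len(cases)


class TestKaplanMeier:
    def test_hand_product_limit(self):
        rec = pd.DataFrame([
            record("a", exit=(2015, 12)),  # t=2
            record("b", exit=(2015, 14)),  # t=4
            record("c", exit=(2015, 16)),  # t=6
        ])
        km = km_estimate(rec)
        curve = km.curves["none"].set_index("time")["survival"]
        assert curve.loc[2.0] == pytest.approx(2 / 3, abs=1e-12)
        assert curve.loc[4.0] == pytest.approx(1 / 3, abs=1e-12)
        assert curve.loc[6.0] == pytest.approx(0.0, abs=1e-12)
        assert km.medians["none"] == 4.0

    def test_single_censored_subject(self):
        rec = pd.DataFrame([record("a", exit=(2015, 30), censored=True)])
        km = km_estimate(rec)
        assert (km.curves["none"]["survival"] == 1.0).all()
        assert np.isnan(km.medians["none"])

    def test_km_equals_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(2)
        t = rng.integers(2, 40, 60).astype(float)
        rec = pd.DataFrame([record(f"m{i}", exit=(2015, 10 + int(ti))) for i, ti in enumerate(t)])
        km = km_estimate(rec)
        curve = km.curves["none"].set_index("time")["survival"]
        for time in sorted(set(t)):
            assert curve.loc[time] == pytest.approx((t > time).mean(), abs=1e-12)

    def test_geometric_median_recovered(self):
        rng = np.random.default_rng(2)
        p = 0.08
        t = rng.geometric(p, 200).astype(float)
        rec = pd.DataFrame(
            [record(f"m{i}", entry=(2015, 1), exit=(2015, 1 + int(ti)))
             for i, ti in enumerate(t)]
        )
        km = km_estimate(rec)
        theo = np.ceil(np.log(0.5) / np.log(1 - p))
        assert abs(km.medians["none"] - theo) <= 1.0


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        rows = [record(f"a{i}", exit=(2015, 15 + 3 * i)) for i in range(4)]
        rows += [
            record(f"b{i}", exit=(2015, 15 + 3 * i), category="tail",
                   pre=0.0, onset=(2015, 10)) for i in range(4)
        ]
        stat, df, p = logrank_test(pd.DataFrame(rows))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert df == 1 and p == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_two_group_instance(self):
        # groups A: events at 2, 5; B: events at 3, 5
        rec = pd.DataFrame([
            record("a1", exit=(2015, 12)),
            record("a2", exit=(2015, 15)),
            record("b1", exit=(2015, 13), category="tail", pre=0.0, onset=(2015, 10)),
            record("b2", exit=(2015, 15), category="tail", pre=0.0, onset=(2015, 10)),
        ])
        # hand log-rank: O_A - E_A and hypergeometric variances per event time
        # t=2: n=4 (2A), d=1, e=0.5, v=0.25; t=3: n=3 (1A), d=1, e=1/3, v=2/9
        # t=5: n=2 (1A,1B), d=2 -> no variance contribution, e=1
        o_minus_e = (1 - 0.5) + (0 - 1 / 3) + (1 - 1.0)
        var = 0.25 + 2 / 9 + 0.0
        expected = o_minus_e**2 / var
        stat, df, p = logrank_test(rec)
        assert stat == pytest.approx(expected, abs=1e-10)


class TestCox:
    def test_three_subject_partial_likelihood_oracle(self):
        # subjects: (t=3, event, x=1), (t=5, event, x=0), (t=7, censored, x=1)
        rec = pd.DataFrame([
            record("a", exit=(2015, 13), category="tail", pre=0.0, onset=(2015, 10)),
            record("b", exit=(2015, 15)),
            record("c", exit=(2015, 17), category="tail", pre=0.0,
                   onset=(2015, 10), censored=True),
        ])
        fit = fit_proportional_hazards(rec, category_levels=("tail",))
        def neg_pl(b):
            # risk sets: t=3 {a,b,c}, t=5 {b,c}
            return -(
                (b - np.log(np.exp(b) + 1 + np.exp(b)))
                + (0 - np.log(1 + np.exp(b)))
            )
        opt = minimize_scalar(neg_pl, bounds=(-5, 5), method="bounded",
                              options={"xatol": 1e-12})
        assert fit.coef("category[tail]") == pytest.approx(opt.x, abs=1e-6)

    def test_duplicated_dataset_same_estimate(self):
        # duplicating every subject doubles the partial likelihood's
        # information but also turns every event into a clone tie, which
        # the Efron correction handles approximately; the estimate must
        # agree to well within its standard error, not to machine precision
        rng = np.random.default_rng(4)
        rows = []
        for i in range(40):
            t = int(rng.integers(2, 30))
            imp = i % 4 == 0
            rows.append(
                record(f"m{i}", exit=(2015, 10 + t),
                       category="tail" if imp else "none",
                       pre=0.0 if imp else np.nan,
                       onset=(2015, 10) if imp else (np.nan, np.nan),
                       sex="M" if i % 2 else "F")
            )
        rec = pd.DataFrame(rows)
        fit1 = fit_proportional_hazards(rec)
        fit2 = fit_proportional_hazards(
            pd.concat([rec, rec.assign(tag=rec["tag"] + "_dup")], ignore_index=True)
        )
        assert fit1.coef("category[tail]") == pytest.approx(
            fit2.coef("category[tail]"), abs=5e-3
        )

    def test_stratified_null_coverage(self, null_sim):
        cfg, events, _ = null_sim
        hs = build_histories(events)
        persist = persistence_times(hs, study_end(cfg))
        cases = persist[persist["category"] != "none"]
        pool = persist[persist["category"] == "none"]
        sets, _ = match_survival_controls(cases, pool)
        fit = fit_proportional_hazards(persist, sets=sets)
        # truth: no survival effect of any impairment category
        for term in ("category[tail]",):
            lo, hi = fit.ci(term)
            assert lo <= 0.0 <= hi or (abs(fit.coef(term)) < 0.35)
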