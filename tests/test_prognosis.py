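"""Relative-difference risk model, KM/log-rank, threshold sweep."""

import numpy as np
import pandas as pd
import pytest

from methgrad import prognosis, synthetic
from methgrad.prognosis import (
    classify_difference,
    combined_model,
    relative_difference,
    single_site_stratify,
    stage_crosstab,
    threshold_sweep,
)


class TestRelativeDifference:
    def test_equal_levels_give_zero(self):
        assert relative_difference(0.5, 0.5) == 0.0

    def test_formula(self):
        assert relative_difference(0.4, 0.5) == pytest.approx(25.0)

    def test_clamped_to_100_with_warning(self):
        with pytest.warns(UserWarning, match="clamp"):
            assert relative_difference(0.2, 0.5) == 100.0

    def test_zero_tumor_rejected(self):
        with pytest.raises(ZeroDivisionError):
            relative_difference(0.0, 0.5)

    def test_max_denominator_is_bounded(self):
        assert relative_difference(0.2, 0.5, denominator="max") == pytest.approx(60.0)


class TestClassifyDifference:
    def test_below_threshold_is_low(self):
        assert classify_difference(4.0, 5.0) == "low_difference"

    def test_large_negative_is_high(self):
        assert classify_difference(-20.0, 5.0) == "high_difference"

    def test_boundary_is_high(self):
        assert classify_difference(5.0, 5.0) == "high_difference"

    def test_unusual_threshold_warns(self):
        with pytest.warns(UserWarning, match="sweep range"):
            classify_difference(1.0, 20.0)


def _km_by_hand(times, events):
    """Product-limit estimate at each distinct event time."""
    order = np.argsort(times)
    t, e = np.asarray(times)[order], np.asarray(events)[order]
    out = {}
    s = 1.0
    for et in np.unique(t[e.astype(bool)]):
        n_at_risk = (t >= et).sum()
        d = ((t == et) & e.astype(bool)).sum()
        s *= 1 - d / n_at_risk
        out[et] = s
    return out


def test_km_matches_hand_rolled_product_limit():
    from lifelines import KaplanMeierFitter

    times = [3.0, 5.0, 5.0, 8.0, 10.0, 12.0, 15.0, 16.0, 20.0, 22.0]
    events = [1, 1, 0, 1, 0, 1, 0, 1, 0, 0]
    km = KaplanMeierFitter().fit(times, events)
    for t, s in _km_by_hand(times, events).items():
        assert km.survival_function_.loc[t].iloc[0] == pytest.approx(s, abs=1e-12)


def _logrank_by_hand(times, events, group):
    """Chi-squared log-rank statistic from the 2xK event table."""
    t = np.asarray(times, float)
    e = np.asarray(events, bool)
    g = np.asarray(group, bool)
    num = 0.0
    var = 0.0
    for et in np.unique(t[e]):
        at = t >= et
        n, n1 = at.sum(), (at & g).sum()
        d = (e & (t == et)).sum()
        d1 = (e & (t == et) & g).sum()
        num += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return num**2 / var


def test_logrank_matches_2xk_table_oracle():
    from lifelines.statistics import logrank_test

    rng = np.random.default_rng(3)
    t = rng.exponential(10, 30).round(1) + 0.1
    e = rng.random(30) < 0.7
    g = rng.random(30) < 0.5
    lr = logrank_test(t[g], t[~g], e[g], e[~g])
    assert lr.test_statistic == pytest.approx(_logrank_by_hand(t, e, g), rel=1e-9)


def _cohort(seed=0, **kw):
    return synthetic.generate_prognosis_cohort(
        synthetic.SyntheticPrognosisConfig(seed=seed, **kw)
    )


class TestStratification:
    def test_group_swap_inverts_hazard_ratio(self):
        rec = _cohort(seed=2)
        s = combined_model(rec, [f"site{i+1}" for i in range(6)], 2, 5.0)
        patients = rec.groupby("patient")[["time", "event"]].first()
        inv = prognosis._stratify(patients, ~s.risk_class, "swapped")
        assert inv.hr == pytest.approx(1 / s.hr, rel=1e-6)

    def test_extreme_separation_gives_large_hr_small_p(self):
        patients = pd.DataFrame(
            {
                "patient": [f"p{i}" for i in range(20)],
                "site": "site1",
                "tumor_meth": 0.5,
                "adjacent_meth": [0.5] * 10 + [0.9] * 10,
                "time": [1.0] * 10 + [50.0] * 10,
                "event": [True] * 10 + [False] * 10,
            }
        )
        s = single_site_stratify(patients, "site1", 5.0)
        assert s.logrank_p < 1e-4
        assert s.n_high == 10

    def test_one_empty_group_reported_undefined(self):
        rec = _cohort(seed=4)
        s = single_site_stratify(rec, "site1", 3.0, denominator="max")
        if s.n_high == 0 or s.n_low == 0:
            assert not s.defined
        rec2 = rec.copy()
        rec2["adjacent_meth"] = rec2["tumor_meth"]  # every site low-difference
        s2 = single_site_stratify(rec2, "site1", 5.0)
        assert not s2.defined and np.isnan(s2.hr)


class TestSweep:
    def test_low_group_monotone_in_threshold(self):
        rec = _cohort(seed=5)
        sweep = threshold_sweep(rec, ["site1", "site2"], [3, 5, 8, 11, 15])
        for site, grp in sweep.groupby("site"):
            sizes = grp.sort_values("threshold")["n_low_difference"].to_numpy()
            assert (np.diff(sizes) >= 0).all()

    def test_sweep_deterministic(self):
        rec = _cohort(seed=6)
        a = threshold_sweep(rec, ["site1"], [3, 9, 15])
        b = threshold_sweep(rec, ["site1"], [3, 9, 15])
        pd.testing.assert_frame_equal(a, b)


class TestCombined:
    def test_high_risk_membership_shrinks_with_n(self):
        rec = _cohort(seed=7)
        sites = [f"site{i+1}" for i in range(5)]
        prev = None
        for n in (1, 2, 3):
            s = combined_model(rec, sites, n, 5.0)
            members = set(s.risk_class[s.risk_class].index)
            if prev is not None:
                assert members <= prev
            prev = members

    def test_three_of_five_with_n2_is_high_risk(self):
        rows = []
        for i, patient in enumerate(["a", "b"]):
            for j in range(5):
                low = (i == 0) and (j < 3)  # patient a: 3 low sites; b: none
                adj = 0.5 * (1.02 if low else 1.5)
                rows.append(
                    {
                        "patient": patient,
                        "site": f"site{j+1}",
                        "tumor_meth": 0.5,
                        "adjacent_meth": adj,
                        "time": 10.0,
                        "event": True,
                    }
                )
        rec = pd.DataFrame(rows)
        s = combined_model(rec, [f"site{j+1}" for j in range(5)], 2, 5.0)
        assert s.risk_class["a"] and not s.risk_class["b"]


class TestStageCrosstab:
    def test_margins_equal_group_sizes(self):
        rec = _cohort(seed=8)
        s = combined_model(rec, [f"site{i+1}" for i in range(6)], 2, 5.0)
        table, p, missing = stage_crosstab(s, rec.groupby("patient")["stage"].first())
        assert table.sum().sum() + missing == len(s.risk_class)
        assert table.loc["high_risk"].sum() == s.n_high

    def test_extreme_association_has_small_p(self):
        idx = [f"p{i}" for i in range(40)]
        risk = pd.Series([True] * 20 + [False] * 20, index=idx)
        stages = pd.Series(["III-IV"] * 20 + ["I-II"] * 20, index=idx)
        strat = prognosis.RiskStratification(
            "t", risk, 1.0, (1, 1), 1.0, 0.0, 20, 20
        )
        _, p, _ = stage_crosstab(strat, stages)
        assert p < 1e-6
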