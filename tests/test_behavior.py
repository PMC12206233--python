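"""WEE activity scoring and composite performance z-scores."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from natpipe.behavior import (
    ActivityEntry,
    TestBatteryResult,
    composite_scores,
    composites_frame,
    lifetime_pa,
    lifetime_pa_from_diary,
    period_wee,
)
from natpipe.errors import ContractError, DomainError
from natpipe.synthetic import CohortConfig, generate_behavior
from test_synthetic import _pd_profile


class TestPeriodWEE:
    def test_hand_evaluated_example(self):
        """16 years of a year-round 2 h/week MET-8 activity over a 16-year
        period: (16*12*2)/(12*16) * 8 = 16 MET-hours/week."""
        entry = ActivityEntry(activity="swim", met=8.0, years=16.0,
                              months_per_year=12.0, hours_per_week=2.0,
                              period="19-35")
        assert period_wee([entry], 16.0).wee == pytest.approx(16.0)

    def test_empty_diary_scores_zero(self):
        assert period_wee([], 16.0).wee == 0.0

    def test_halving_months_halves_contribution(self):
        full = ActivityEntry(activity="run", met=7.0, years=10.0,
                             months_per_year=12.0, hours_per_week=3.0)
        half = ActivityEntry(activity="run", met=7.0, years=10.0,
                             months_per_year=6.0, hours_per_week=3.0)
        assert period_wee([half], 16.0).wee == pytest.approx(
            period_wee([full], 16.0).wee / 2)

    @given(years=st.floats(0.5, 16), months=st.floats(0.5, 12),
           hours=st.floats(0.1, 30), met=st.floats(0.5, 15),
           c=st.floats(0.1, 4))
    @settings(max_examples=50, deadline=None)
    def test_linearity_in_each_factor(self, years, months, hours, met, c):
        def wee(**kw):
            base = dict(activity="a", met=met, years=years,
                        months_per_year=months, hours_per_week=hours)
            base.update(kw)
            return period_wee([ActivityEntry(**base)], 16.0).wee

        base = wee()
        assert wee(hours_per_week=hours * c) == pytest.approx(base * c, rel=1e-9)
        assert wee(met=met * c) == pytest.approx(base * c, rel=1e-9)
        if months * c <= 12:
            assert wee(months_per_year=months * c) == pytest.approx(
                base * c, rel=1e-9)

    @pytest.mark.parametrize("bad", [
        dict(met=-1.0), dict(years=-2.0), dict(months_per_year=13.0),
        dict(hours_per_week=-0.5),
    ])
    def test_invalid_entries_rejected(self, bad):
        base = dict(activity="a", met=5.0, years=5.0, months_per_year=10.0,
                    hours_per_week=2.0)
        base.update(bad)
        with pytest.raises(DomainError):
            ActivityEntry(**base)

    def test_years_exceeding_period_span_rejected(self):
        with pytest.raises(DomainError):
            ActivityEntry(activity="a", met=5.0, years=20.0,
                          months_per_year=12.0, hours_per_week=2.0,
                          period="35-50")


class TestLifetimePA:
    def test_mean_of_two_periods(self):
        a = period_wee([], 16.0, period="19-35")
        b = ActivityEntry(activity="x", met=8.0, years=15.0,
                          months_per_year=12.0, hours_per_week=5.0,
                          period="35-50")
        w2 = period_wee([b], 15.0, period="35-50")
        assert lifetime_pa(a, w2) == pytest.approx(w2.wee / 2)

    def test_missing_period_rejected(self):
        w = period_wee([], 16.0)
        with pytest.raises(ContractError):
            lifetime_pa(w, None)

    def test_diary_table_matches_manual_formula(self, rng):
        """Randomized diaries: the table scorer equals a direct re-evaluation
        of the WEE formula followed by the two-period mean."""
        rows, expected = [], {}
        for pid in ("P1", "P2", "P3"):
            total = {}
            for period, span in (("19-35", 16.0), ("35-50", 15.0)):
                wee = 0.0
                for k in range(int(rng.integers(0, 4))):
                    years = float(rng.uniform(1, span))
                    months = float(rng.uniform(1, 12))
                    hours = float(rng.uniform(0.5, 10))
                    met = float(rng.uniform(2, 12))
                    rows.append(dict(participant=pid, period=period,
                                     activity=f"a{k}", met=met, years=years,
                                     months_per_year=months,
                                     hours_per_week=hours))
                    wee += years * months * hours / (12 * span) * met
                total[period] = wee
            expected[pid] = (total["19-35"] + total["35-50"]) / 2
        pa = lifetime_pa_from_diary(pd.DataFrame(rows))
        for pid, val in expected.items():
            assert pa[pid] == pytest.approx(val, rel=1e-12)


def _battery(pid, scores, directions=None, kinds=None):
    directions = directions or {t: "higher_better" for t in scores}
    kinds = kinds or {t: "motor" for t in scores}
    return TestBatteryResult(participant=pid, scores=scores,
                             directions=directions, kinds=kinds)


class TestCompositeScores:
    def _hc_sample(self, rng, n=20, direction="higher_better"):
        return [
            _battery(f"HC{i}", {"t1": float(rng.normal(10, 2)),
                                "t2": float(rng.normal(30, 5))},
                     directions={"t1": direction, "t2": direction})
            for i in range(n)
        ]

    def test_hc_self_reference_standardizes(self, rng):
        hc = self._hc_sample(rng)
        comps = composite_scores(hc, hc)
        z1 = np.array([c.per_test_z["t1"] for c in comps])
        assert z1.mean() == pytest.approx(0.0, abs=1e-12)
        assert z1.std(ddof=1) == pytest.approx(1.0, rel=1e-12)

    def test_pd_at_hc_mean_scores_zero(self, rng):
        hc = self._hc_sample(rng)
        m1 = np.mean([b.scores["t1"] for b in hc])
        m2 = np.mean([b.scores["t2"] for b in hc])
        comps = composite_scores([_battery("PD1", {"t1": m1, "t2": m2})], hc)
        assert comps[0].gmp == pytest.approx(0.0, abs=1e-12)

    def test_slow_duration_lowers_gmp(self, rng):
        hc = self._hc_sample(rng, direction="lower_better")
        slow = {"t1": max(b.scores["t1"] for b in hc) + 5,
                "t2": np.mean([b.scores["t2"] for b in hc])}
        comps = composite_scores(
            [_battery("PD1", slow,
                      directions={"t1": "lower_better", "t2": "lower_better"})],
            hc)
        assert comps[0].per_test_z["t1"] < 0
        assert comps[0].gmp < 0

    def test_direction_flip_negates_contribution(self, rng):
        scores = {f"HC{i}": float(rng.normal(10, 2)) for i in range(15)}
        for direction, opposite in (("higher_better", "lower_better"),):
            hc_a = [_battery(k, {"t": v}, directions={"t": direction})
                    for k, v in scores.items()]
            hc_b = [_battery(k, {"t": v}, directions={"t": opposite})
                    for k, v in scores.items()]
            target_a = [_battery("PD1", {"t": 14.0}, directions={"t": direction})]
            target_b = [_battery("PD1", {"t": 14.0}, directions={"t": opposite})]
            za = composite_scores(target_a, hc_a)[0].per_test_z["t"]
            zb = composite_scores(target_b, hc_b)[0].per_test_z["t"]
            assert za == pytest.approx(-zb, rel=1e-12)

    def test_zero_variance_test_excluded(self, rng):
        hc = [_battery(f"HC{i}", {"t1": 5.0, "t2": float(rng.normal(0, 1))})
              for i in range(10)]
        with pytest.warns(UserWarning, match="t1"):
            comps = composite_scores([_battery("PD1", {"t1": 9.0, "t2": 0.0})], hc)
        assert "t1" not in comps[0].per_test_z

    def test_mean_mode_rescales_sum(self, rng):
        hc = self._hc_sample(rng)
        target = [_battery("PD1", {"t1": 12.0, "t2": 28.0})]
        total = composite_scores(target, hc, mode="sum")[0].gmp
        mean = composite_scores(target, hc, mode="mean")[0].gmp
        assert mean == pytest.approx(total / 2)

    def test_planted_nat_effect_recovered_end_to_end(self):
        """GMP computed from generated batteries correlates positively with
        the NAT values the generator planted (200 PD + HC reference)."""
        cfg = CohortConfig(noise_sd=0.5, seed=6)
        rng = np.random.default_rng(8)
        hc = [generate_behavior(
            _pd_profile(id=f"HC{i}", index=500 + i, group="HC", sex="f",
                        putaminal_dat=None),
            0.5, cfg) for i in range(39)]
        nats, pds = [], []
        for i in range(200):
            nat = float(rng.uniform(0.2, 0.8))
            nats.append(nat)
            pds.append(generate_behavior(
                _pd_profile(id=f"PD{i}", index=i, pa=30.0), nat, cfg))
        gmp = composites_frame(composite_scores(pds, hc))["gmp"]
        r = np.corrcoef(nats, gmp)[0, 1]
        assert r > 0.5
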