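import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import drivemap as dm
from drivemap.protocol import Vial, vial_series_from_daily


def _series(counted_then_block):
    """(day, n_days, total, counted) tuples -> VialSeries with all-female counts."""
    vials = [Vial(d, nd, tot, 0, c) for d, nd, tot, c in counted_then_block]
    return dm.VialSeries(vials)


class TestInterpolation:
    def test_block_estimate_is_twice_flanking_sum(self):
        s = _series([(1, 1, 10, True), (2, 1, 8, True), (3, 1, 6, True),
                     (4, 4, 0, False), (8, 1, 4, True)])
        r = dm.interpolate_total(s)
        assert r.block_estimates == [20.0]
        assert r.total == 48.0
        assert r.counted_total == 28
        assert not r.edge_rule_used

    def test_fully_counted_series_is_plain_sum(self):
        s = _series([(1, 1, 5, True), (2, 1, 4, True), (3, 1, 3, True)])
        assert dm.interpolate_total(s).total == 12.0

    @given(c0=st.integers(30, 120), slope=st.integers(1, 6))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_exact_under_linear_daily_decline(self, c0, slope):
        """The 2x(flank sum) rule reproduces a linear series' total exactly."""
        days = 13
        daily = [(max(c0 - slope * d, 0), 0) for d in range(1, days + 1)]
        if daily[-1][0] == 0:  # keep strictly linear over the observed span
            return
        series = vial_series_from_daily(daily)
        truth = sum(f for f, _ in daily)
        assert dm.interpolate_total(series).total == pytest.approx(truth, abs=1e-9)

    def test_geometric_decay_relative_error_below_5pct(self):
        r, c0, days = 0.9, 200, 18
        daily = [(round(c0 * r ** (d - 1)), 0) for d in range(1, days + 1)]
        series = vial_series_from_daily(daily)
        truth = sum(f for f, _ in daily)
        est = dm.interpolate_total(series).total
        assert abs(est - truth) / truth < 0.05

    def test_trailing_block_uses_edge_rule_and_flags(self):
        s = _series([(1, 1, 10, True), (2, 1, 8, True), (3, 1, 6, True), (4, 4, 0, False)])
        r = dm.interpolate_total(s)
        assert r.block_estimates == [24.0]  # 4 x preceding 1-day vial
        assert r.edge_rule_used

    def test_leading_uncounted_block_is_an_error(self):
        s = dm.VialSeries([Vial(1, 4, 0, 0, False), Vial(5, 1, 3, 0, True)])
        with pytest.raises(ValueError, match="no preceding counted"):
            dm.interpolate_total(s)

    def test_adjacent_uncounted_blocks_are_an_error(self):
        s = dm.VialSeries([Vial(1, 1, 9, 0, True), Vial(2, 4, 0, 0, False),
                           Vial(6, 4, 0, 0, False), Vial(10, 1, 1, 0, True)])
        with pytest.raises(ValueError, match="another uncounted"):
            dm.interpolate_total(s)

    def test_invariant_to_trailing_zero_counted_vials(self):
        base = [(1, 1, 10, True), (2, 1, 8, True), (3, 1, 6, True),
                (4, 4, 0, False), (8, 1, 4, True)]
        extended = base + [(9, 1, 0, True), (10, 1, 0, True)]
        assert dm.interpolate_total(_series(base)).total == dm.interpolate_total(_series(extended)).total


class TestSexRatioRule:
    def test_boundary_thirty_is_eligible(self):
        r = dm.observed_sex_ratio(dm.MalePhenotype(30, 15, 15))
        assert r.eligible and r.k == 0.5

    def test_twenty_nine_is_ineligible(self):
        r = dm.observed_sex_ratio(dm.MalePhenotype(29, 20, 9))
        assert not r.eligible and r.k is None

    def test_female_biased_ratio(self):
        r = dm.observed_sex_ratio(dm.MalePhenotype(50, 40, 10))
        assert r.k == pytest.approx(0.8)

    def test_series_uses_counted_vials_only(self):
        s = dm.VialSeries([Vial(1, 1, 20, 20, True), Vial(2, 4, 50, 0, False),
                           Vial(6, 1, 10, 10, True)])
        r = dm.observed_sex_ratio(s)
        assert r.females == 30 and r.males == 30 and r.k == 0.5


class TestBootstrap:
    def test_single_male_has_degenerate_resample_space(self):
        mean, sem = dm.bootstrap_sex_ratio([dm.MalePhenotype(50, 40, 10)], B=200, rng=0)
        assert mean == pytest.approx(0.8)
        assert sem == pytest.approx(0.0)

    def test_all_female_broods(self):
        recs = [dm.MalePhenotype(10, 10, 0) for _ in range(5)]
        mean, sem = dm.bootstrap_sex_ratio(recs, B=200, rng=1)
        assert mean == 1.0 and sem == 0.0

    def test_sterile_males_excluded_from_pooling(self):
        recs = [dm.MalePhenotype(0, 0, 0), dm.MalePhenotype(40, 30, 10)]
        mean, _ = dm.bootstrap_sex_ratio(recs, B=100, rng=2)
        assert mean == pytest.approx(0.75)

    def test_large_sample_sem_matches_pooled_binomial(self):
        rng = np.random.default_rng(3)
        k = 0.7
        recs = [dm.MalePhenotype(100, int(f), 100 - int(f)) for f in rng.binomial(100, k, 1000)]
        mean, sem = dm.bootstrap_sex_ratio(recs, B=400, rng=4)
        analytic = np.sqrt(k * (1 - k) / 1e5)
        assert abs(mean - k) < 5 * analytic
        assert 0.5 * analytic < sem < 2.0 * analytic

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no records"):
            dm.bootstrap_sex_ratio([], B=10)


def test_schedule_counted_days():
    cfg = dm.ProtocolConfig()
    counted = [d for d in range(1, 25) if cfg.is_counted_day(d)]
    assert counted == [1, 2, 3, 8, 13, 18, 23]
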