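"""Energetic balances, Tm/Tc location, mismatch regions, CREB and trends."""

import numpy as np
import pytest

from thermomatch.errors import InputError
from thermomatch.mismatch import (classify_trend, creb, energetic_balance,
                                  find_Tc, find_Tm, inter_tm, intra_tm,
                                  predict_is_trend)
from thermomatch.models import PredictionGrid, predict_grid


def grid(values, lo=14.0, hi=36.0):
    t = np.linspace(lo, hi, np.size(values)) if np.ndim(values) else None
    v = np.asarray(values, float)
    return PredictionGrid(np.linspace(lo, hi, v.size), v, step=(hi - lo) / (v.size - 1))


def balance_from(fn_gain, fn_loss, lo=14.0, hi=36.0, n=2201):
    t = np.linspace(lo, hi, n)
    g = PredictionGrid(t, np.asarray(fn_gain(t), float), step=t[1] - t[0])
    l = PredictionGrid(t, np.asarray(fn_loss(t), float), step=t[1] - t[0])
    return energetic_balance(g, l)


class TestBalance:
    def test_equal_curves_unit_ratio(self):
        b = balance_from(lambda t: 1 + t, lambda t: 1 + t)
        assert np.allclose(b.ratio, 1.0)

    def test_double_gain_doubles_ratio(self):
        b = balance_from(lambda t: 2 * (1 + t), lambda t: 1 + t)
        assert np.allclose(b.ratio, 2.0)

    def test_nonpositive_loss_masked_and_reported(self):
        b = balance_from(lambda t: np.ones_like(t), lambda t: t - 25.0)
        assert np.isnan(b.ratio[b.loss <= 0]).all()
        assert b.masked_fraction == pytest.approx(np.mean(b.loss <= 0))

    def test_mismatched_grids_raise(self):
        a = PredictionGrid(np.linspace(14, 36, 100), np.ones(100), 0.22)
        c = PredictionGrid(np.linspace(14, 37, 100), np.ones(100), 0.23)
        with pytest.raises(InputError):
            energetic_balance(a, c)


class TestTm:
    def test_symmetric_peak_found_exactly(self):
        b = balance_from(lambda t: np.exp(-((t - 25.0) ** 2) / 20.0),
                         lambda t: np.ones_like(t))
        tm, edge, diverge = find_Tm(b)
        assert tm == pytest.approx(25.0, abs=0.02)
        assert not edge and not diverge

    def test_monotone_decline_reports_boundary(self):
        b = balance_from(lambda t: 1.0 / t, lambda t: np.ones_like(t))
        tm, edge, _ = find_Tm(b)
        assert tm == 14.0
        assert edge

    def test_interior_maximum_preferred_over_edge_divergence(self):
        # loss collapsing at the top edge makes the raw ratio explode there;
        # the physiological optimum is the interior peak
        b = balance_from(lambda t: np.exp(-((t - 20.0) ** 2) / 30.0) + 0.1,
                         lambda t: np.maximum(1e-9, (36.5 - t)) ** 2 / 100.0)
        tm, edge, diverge = find_Tm(b)
        assert 18.0 < tm < 23.0
        assert diverge

    def test_agrees_with_brute_force_on_random_unimodal_curves(self, rng):
        for _ in range(20):
            peak = rng.uniform(16, 34)
            width = rng.uniform(5, 60)
            b = balance_from(lambda t: np.exp(-((t - peak) ** 2) / width),
                             lambda t: np.ones_like(t))
            tm, _, _ = find_Tm(b)
            brute = b.temperatures[np.nanargmax(b.ratio)]
            assert tm == pytest.approx(float(brute), abs=1e-9)


class TestTc:
    def test_ratio_above_one_everywhere_absent(self):
        b = balance_from(lambda t: 1.5 * np.ones_like(t),
                         lambda t: np.ones_like(t))
        tc, deficit = find_Tc(b)
        assert tc is None and not deficit

    def test_always_deficit_flag(self):
        b = balance_from(lambda t: 0.5 * np.ones_like(t),
                         lambda t: np.ones_like(t))
        tc, deficit = find_Tc(b)
        assert tc is None and deficit

    def test_interpolated_crossing(self):
        # ratio = 29/t crosses 1 downward at exactly t = 29
        b = balance_from(lambda t: 29.0 / t, lambda t: np.ones_like(t))
        tc, _ = find_Tc(b)
        assert tc == pytest.approx(29.0, abs=1e-6)

    def test_unimodal_gain_with_increasing_loss_has_tm_before_tc(self, rng):
        # constructed family: gain peaks inside the range, loss rises through
        # it and crosses gain -> a downward crossing exists with Tm < Tc
        for _ in range(20):
            peak = rng.uniform(20, 28)
            b = balance_from(
                lambda t: 2.0 * np.exp(-((t - peak) ** 2) / rng.uniform(20, 80)),
                lambda t: 0.2 + 0.08 * (t - 14.0))
            tc, _ = find_Tc(b)
            tm, _, _ = find_Tm(b)
            assert tc is not None
            assert tm < tc


class TestRegions:
    def test_strictly_increasing_balance_has_no_intra_tm(self):
        b = balance_from(lambda t: np.exp(0.05 * t), lambda t: np.ones_like(t))
        assert intra_tm(b) == ()

    def test_strictly_decreasing_balance_full_range(self):
        b = balance_from(lambda t: np.exp(-0.05 * t), lambda t: np.ones_like(t))
        ivs = intra_tm(b)
        assert len(ivs) == 1
        lo, hi = ivs[0]
        assert lo == pytest.approx(14.0, abs=0.5)
        assert hi == pytest.approx(36.0, abs=0.5)

    def test_both_increasing_yields_empty_report(self):
        c = balance_from(lambda t: np.exp(0.05 * t), lambda t: np.ones_like(t))
        r = balance_from(lambda t: np.exp(0.02 * t), lambda t: np.ones_like(t))
        rep = inter_tm(c, r)
        assert rep.region1 == () and rep.region2 == ()
        assert rep.onset_c is None

    def test_opposite_then_joint_decline(self):
        con = balance_from(lambda t: np.exp(-0.05 * t), lambda t: np.ones_like(t))
        res = balance_from(lambda t: np.exp(-((t - 30.7) ** 2) / 50.0),
                           lambda t: np.ones_like(t))
        rep = inter_tm(con, res)
        assert rep.region1[0][0] == pytest.approx(14.0, abs=0.5)
        assert rep.region1[0][1] == pytest.approx(30.7, abs=0.5)
        assert rep.region2[0][0] == pytest.approx(30.7, abs=0.5)
        assert rep.onset_c == pytest.approx(14.0, abs=0.5)

    def test_partition_every_declining_point_in_exactly_one_region(self, rng):
        con = balance_from(lambda t: np.exp(-((t - 22.0) ** 2) / 40.0),
                           lambda t: np.ones_like(t))
        res = balance_from(lambda t: np.exp(-((t - 28.0) ** 2) / 60.0),
                           lambda t: np.ones_like(t))
        rep = inter_tm(con, res)

        def member(t, ivs):
            return any(a <= t <= b for a, b in ivs)

        for t in np.linspace(14.5, 35.5, 43):
            in1, in2 = member(t, rep.region1), member(t, rep.region2)
            assert not (in1 and in2)


class TestCREB:
    def test_identical_balances_zero(self):
        a = balance_from(lambda t: 2 + t, lambda t: np.ones_like(t))
        c = creb(a, a)
        assert np.allclose(c.values, 0.0)

    def test_e_fold_ratio_gives_unit_creb(self):
        a = balance_from(lambda t: np.e * (2 + t), lambda t: np.ones_like(t))
        b = balance_from(lambda t: 2 + t, lambda t: np.ones_like(t))
        assert np.allclose(creb(a, b).values, 1.0)

    def test_antisymmetry(self, rng):
        a = balance_from(lambda t: 1 + np.exp(-((t - 24) ** 2) / 30.0),
                         lambda t: 0.5 + 0.01 * t)
        b = balance_from(lambda t: 2 + 0.05 * t, lambda t: 0.3 + 0.02 * t)
        assert np.allclose(creb(a, b).values, -creb(b, a).values)

    def test_domain_restricted_to_positive_balances(self):
        a = balance_from(lambda t: t - 25.0, lambda t: np.ones_like(t))
        b = balance_from(lambda t: np.ones_like(t), lambda t: np.ones_like(t))
        c = creb(a, b)
        assert c.temperatures.min() > 25.0
        assert "domain_trimmed" in c.flags


class TestTrend:
    def from_values(self, fn, lo=14.0, hi=36.0, n=2201):
        t = np.linspace(lo, hi, n)
        a = balance_from(lambda x: np.exp(np.asarray(fn(x))),
                         lambda x: np.ones_like(x), lo, hi, n)
        b = balance_from(lambda x: np.ones_like(x), lambda x: np.ones_like(x),
                         lo, hi, n)
        return creb(a, b)

    def test_linear_decline(self):
        assert classify_trend(self.from_values(lambda t: -0.1 * t)) == "declining"

    def test_linear_increase(self):
        assert classify_trend(self.from_values(lambda t: 0.1 * t)) == "increasing"

    def test_upward_parabola_u_shaped(self):
        assert classify_trend(
            self.from_values(lambda t: 0.02 * (t - 25.0) ** 2)) == "u_shaped"

    def test_downward_parabola_hump_shaped(self):
        assert classify_trend(
            self.from_values(lambda t: -0.02 * (t - 25.0) ** 2)) == "hump_shaped"

    def test_flat_within_tolerance(self):
        assert classify_trend(self.from_values(lambda t: 0.0 * t)) == "flat"

    def test_is_trend_mapping(self):
        assert predict_is_trend("declining")["predicted_is_trend"] == "decreasing"
        assert predict_is_trend("increasing")["predicted_is_trend"] == "increasing"
        u = predict_is_trend("u_shaped")
        assert u["predicted_is_trend"] == "constant_or_increasing"
        f = predict_is_trend("flat")
        assert f["indeterminate_direction"]
        with pytest.raises(InputError):
            predict_is_trend("sideways")
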