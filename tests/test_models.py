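"""Dose-response model cores against closed-form and brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import curve_fit

from cardrisk.models import (
    LinearRiskParams,
    LymanParams,
    RSParams,
    effective_volume,
    log_ntcp_relative_seriality,
    ntcp_lyman_dvh,
    ntcp_lyman_uniform,
    ntcp_relative_seriality,
    poisson_response,
    relative_risk,
    td50_partial,
)

from .conftest import make_dvh
from .test_dvh import uniform_dvhs

HD_HEART = RSParams(d50=70.3, gamma=0.96, s=1.0)


def naive_rs_ntcp(dvh, p):
    """Direct product evaluation of the seriality formula (test oracle)."""
    prod = 1.0
    for d, v in zip(dvh.doses, dvh.volumes):
        prod *= (1.0 - poisson_response(d, p) ** p.s) ** v
    return (1.0 - prod) ** (1.0 / p.s)


def naive_lyman_dvh(dvh, p):
    """Independent effective-volume reduction + normal CDF (test oracle)."""
    dmax = max(d for d, v in zip(dvh.doses, dvh.volumes) if v > 0)
    veff = sum(v * (d / dmax) ** (1.0 / p.n_vol) for d, v in zip(dvh.doses, dvh.volumes))
    td50v = p.td50_full / veff**p.n_vol
    t = (dmax - td50v) / (p.m * td50v)
    # Phi(t) = erfc(-t/sqrt(2))/2, accurate far into the lower tail
    return 0.5 * math.erfc(-t / math.sqrt(2.0))


class TestLinearRisk:
    def test_zero_dose_gives_unit_risk(self):
        rr = relative_risk(0.0)
        assert (rr.value, rr.ci_low, rr.ci_high) == (1.0, 1.0, 1.0)

    def test_point_and_interval(self):
        rr = relative_risk(10.0, LinearRiskParams(0.6, 0.2, 2.5))
        assert rr.value == pytest.approx(7.0)
        assert rr.ci_low == pytest.approx(3.0)
        assert rr.ci_high == pytest.approx(26.0)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            relative_risk(-1.0)

    def test_alpha_outside_interval_rejected(self):
        with pytest.raises(ValueError):
            LinearRiskParams(alpha1=3.0, ci_low=0.2, ci_high=2.5)


class TestPoissonResponse:
    def test_half_probability_at_d50(self):
        assert poisson_response(70.3, HD_HEART) == 0.5

    def test_zero_dose_hand_value(self):
        expected = 2.0 ** (-math.exp(math.e * 0.96))
        assert poisson_response(0.0, HD_HEART) == pytest.approx(expected, rel=1e-12)

    def test_limits(self):
        assert poisson_response(1e4, HD_HEART) > 1.0 - 1e-12
        assert poisson_response(0.0, RSParams(d50=70.3, gamma=5.0, s=1.0)) < 1e-100

    def test_strictly_increasing(self):
        doses = np.linspace(0.0, 150.0, 200)
        p = poisson_response(doses, HD_HEART)
        assert np.all(np.diff(p) > 0)


class TestRelativeSeriality:
    @pytest.mark.parametrize("s", [0.1, 0.5, 1.0])
    def test_uniform_dose_at_d50_gives_half_for_all_s(self, s):
        dvh = make_dvh([70.3], [1.0])
        p = RSParams(d50=70.3, gamma=0.96, s=s)
        assert ntcp_relative_seriality(dvh, p) == pytest.approx(0.5, abs=1e-12)

    def test_two_bin_against_direct_evaluation(self):
        dvh = make_dvh([35.15, 70.3], [0.5, 0.5])
        p1 = poisson_response(35.15, HD_HEART)
        p2 = poisson_response(70.3, HD_HEART)
        expected = 1.0 - (1.0 - p1) ** 0.5 * (1.0 - p2) ** 0.5
        assert ntcp_relative_seriality(dvh, HD_HEART) == pytest.approx(expected, rel=1e-12)

    @given(uniform_dvhs(max_bins=25))
    def test_log_space_matches_naive_product(self, dvh):
        # shift the dose grid into a range where the naive product is computable
        dvh = dvh.with_doses(dvh.doses + 30.0)
        for s in (0.4, 1.0):
            p = RSParams(d50=60.0, gamma=1.2, s=s)
            naive = naive_rs_ntcp(dvh, p)
            assert ntcp_relative_seriality(dvh, p) == pytest.approx(naive, abs=1e-12)

    def test_serial_organ_weighs_hot_subvolume_more(self):
        # 5% of the organ at a high dose, the rest cold
        dvh = make_dvh([2.0, 60.0], [0.95, 0.05])
        serial = ntcp_relative_seriality(dvh, RSParams(d50=70.3, gamma=0.96, s=1.0))
        parallel = ntcp_relative_seriality(dvh, RSParams(d50=70.3, gamma=0.96, s=0.1))
        assert serial >= parallel

    def test_underflow_returns_log_not_zero(self):
        dvh = make_dvh([0.05, 0.1], [0.5, 0.5])
        log_n = log_ntcp_relative_seriality(dvh, RSParams(d50=70.3, gamma=2.0, s=1.0))
        assert math.isfinite(log_n) and log_n < -100


class TestLyman:
    def test_td50_full_volume(self):
        assert td50_partial(48.0, 1.0, 0.35) == pytest.approx(48.0)
        assert td50_partial(50.6, 1.0, 0.64) == pytest.approx(50.6)

    def test_td50_half_volume(self):
        assert td50_partial(48.0, 0.5, 0.35) == pytest.approx(48.0 * 2**0.35, rel=1e-12)

    def test_invalid_volume_rejected(self):
        with pytest.raises(ValueError):
            td50_partial(48.0, 0.0, 0.35)

    def test_half_probability_at_tolerance_dose(self):
        p = LymanParams(td50_full=48.0, n_vol=0.35, m=0.1)
        assert ntcp_lyman_uniform(48.0, 1.0, p) == pytest.approx(0.5, abs=1e-12)
        td50_half = td50_partial(48.0, 0.5, 0.35)
        assert ntcp_lyman_uniform(td50_half, 0.5, p) == pytest.approx(0.5, abs=1e-12)

    def test_hand_evaluated_t(self):
        # t = (60 - 48) / (0.1 * 48) = 2.5
        p = LymanParams(td50_full=48.0, n_vol=0.35, m=0.1)
        expected = 0.5 * (1.0 + math.erf(2.5 / math.sqrt(2.0)))
        assert ntcp_lyman_uniform(60.0, 1.0, p) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("m", [0.1, 0.2])
    def test_zero_dose_negligible_probability(self, m):
        p = LymanParams(td50_full=48.0, n_vol=0.35, m=m)
        assert ntcp_lyman_uniform(0.0, 1.0, p) < 1e-6

    def test_uniform_dvh_matches_uniform_formula(self):
        p = LymanParams(td50_full=48.0, n_vol=0.35, m=0.1)
        dvh = make_dvh([55.0], [1.0])
        assert ntcp_lyman_dvh(dvh, p) == pytest.approx(ntcp_lyman_uniform(55.0, 1.0, p))

    def test_two_level_dvh_is_partial_volume(self):
        p = LymanParams(td50_full=48.0, n_vol=0.35, m=0.1)
        dvh = make_dvh([0.0, 55.0], [0.5, 0.5])
        assert ntcp_lyman_dvh(dvh, p) == pytest.approx(
            ntcp_lyman_uniform(55.0, 0.5, p), rel=1e-12
        )
        assert effective_volume(dvh, 0.35) == pytest.approx(0.5)

    @given(uniform_dvhs(max_bins=20))
    def test_random_dvh_matches_brute_force_reduction(self, dvh):
        dvh = dvh.with_doses(dvh.doses + 20.0)
        p = LymanParams(td50_full=50.6, n_vol=0.64, m=0.13)
        assert ntcp_lyman_dvh(dvh, p) == pytest.approx(naive_lyman_dvh(dvh, p), rel=1e-9)


class TestMonotonicityUnderDoseScaling:
    @given(uniform_dvhs(max_bins=15), st.floats(1.05, 2.0))
    def test_scaling_dose_increases_all_risks(self, dvh, k):
        dvh = dvh.with_doses(dvh.doses + 10.0)
        hot = dvh.with_doses(dvh.doses * k)
        rs = RSParams(d50=52.3, gamma=1.28, s=1.0)
        ly = LymanParams(td50_full=48.0, n_vol=0.35, m=0.3)
        assert ntcp_relative_seriality(hot, rs) > ntcp_relative_seriality(dvh, rs)
        assert ntcp_lyman_dvh(hot, ly) > ntcp_lyman_dvh(dvh, ly)
        assert relative_risk(hot.mean_dose()).value > relative_risk(dvh.mean_dose()).value


def test_parameter_recovery_from_sampled_response():
    """Least-squares refit of D50 and gamma recovers the generating values."""
    doses = np.linspace(5.0, 140.0, 60)
    target = poisson_response(doses, HD_HEART)

    def model(d, d50, gamma):
        return poisson_response(d, RSParams(d50=d50, gamma=gamma, s=1.0))

    popt, _ = curve_fit(model, doses, target, p0=(50.0, 0.5), bounds=([1.0, 0.01], [200.0, 5.0]))
    assert popt[0] == pytest.approx(70.3, abs=1e-6)
    assert popt[1] == pytest.approx(0.96, abs=1e-6)
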