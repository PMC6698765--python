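"""EQD2 conversion, EUD, Poisson-LQ TCP and LKB NTCP."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import dvhkit as dk
from dvhkit.radiobiology import EQD2_FLOOR, ParameterError

from conftest import uniform_ddvh


@st.composite
def differential_dvhs(draw, min_dose=0.5, max_dose=70.0):
    n = draw(st.integers(min_value=1, max_value=15))
    centers = np.array(sorted(draw(st.sets(
        st.floats(min_dose, max_dose), min_size=n, max_size=n
    ))))
    weights = np.array(draw(st.lists(st.floats(0.01, 1.0), min_size=n, max_size=n)))
    return dk.DifferentialDVH(centers, weights / weights.sum())


class TestEQD2:
    def test_zero_dose(self, frac):
        assert dk.eqd2_bin(0.0, frac, 4.0) == 0.0

    @pytest.mark.parametrize("alpha_beta", [1.0, 3.0, 4.0, 10.0])
    def test_two_gray_per_fraction_fixed_point(self, frac, alpha_beta):
        d = 2.0 * frac.n_fractions
        assert dk.eqd2_bin(d, frac, alpha_beta) == pytest.approx(d)

    def test_prescription_course_value(self, frac):
        # 50.4 Gy(RBE) in 28 fractions at alpha/beta = 4: 50.4 * (4 + 1.8) / 6
        assert dk.eqd2_bin(50.4, frac, 4.0) == pytest.approx(48.72)

    def test_negative_dose_rejected(self, frac):
        with pytest.raises(ParameterError):
            dk.eqd2_bin(-1.0, frac, 4.0)

    @given(st.floats(0.0, 80.0), st.floats(0.1, 10.0))
    def test_strictly_increasing_in_dose(self, d, alpha_beta):
        frac = dk.FractionationScheme(28, 50.4)
        assert dk.eqd2_bin(d + 0.5, frac, alpha_beta) > dk.eqd2_bin(d, frac, alpha_beta)

    @given(st.floats(0.0, 80.0), st.floats(0.5, 10.0))
    def test_inverse_round_trip(self, eqd2, alpha_beta):
        frac = dk.FractionationScheme(28, 50.4)
        d = dk.eqd2_inverse(eqd2, frac, alpha_beta)
        assert dk.eqd2_bin(d, frac, alpha_beta) == pytest.approx(eqd2, abs=1e-9)


class TestEUD:
    def test_uniform_dose_is_its_own_eud(self, frac, registry):
        p = registry["breast_tumor"]
        eud = dk.compute_eud(uniform_ddvh(50.4), p, frac)
        assert eud == pytest.approx(dk.eqd2_bin(50.4, frac, p.alpha_beta))

    def test_exponent_one_gives_mean_eqd2(self, frac):
        p = dk.TumorModelParams(d50=30.89, gamma=1.3, alpha_beta=4.0, a=1.0)
        ddvh = dk.DifferentialDVH(np.array([30.0, 50.0]), np.array([0.4, 0.6]))
        expected = 0.4 * dk.eqd2_bin(30.0, frac, 4.0) + 0.6 * dk.eqd2_bin(50.0, frac, 4.0)
        assert dk.compute_eud(ddvh, p, frac) == pytest.approx(expected)

    def test_two_bin_negative_exponent_value(self, frac):
        # power mean of EQD2 {40, 50} Gy(RBE), equal volumes, a = -7.2
        # (frozen from an independent high-precision evaluation)
        p = dk.TumorModelParams(d50=30.89, gamma=1.3, alpha_beta=4.0, a=-7.2)
        ddvh = dk.DifferentialDVH(np.array([40.0, 50.0]), np.array([0.5, 0.5]))
        eud = dk.compute_eud(ddvh, p, frac, use_eqd2=False)
        assert eud == pytest.approx(42.93822548612876, rel=1e-12)

    def test_zero_dose_bin_clamped_with_warning(self, frac, registry):
        p = registry["breast_tumor"]
        ddvh = dk.DifferentialDVH(np.array([0.0, 50.4]), np.array([0.01, 0.99]))
        with pytest.warns(UserWarning, match="clamping"):
            eud = dk.compute_eud(ddvh, p, frac)
        assert 0 < eud < 50.4
        # the cold spot penalty is severe but finite
        assert eud < 10.0 and eud > EQD2_FLOOR

    def test_zero_exponent_rejected(self):
        with pytest.raises(ParameterError):
            dk.TumorModelParams(d50=30.89, gamma=1.3, alpha_beta=4.0, a=0.0)

    @given(differential_dvhs(), st.floats(1.05, 1.5))
    def test_monotone_under_dose_scaling(self, ddvh, factor):
        frac = dk.FractionationScheme(28, 50.4)
        p = dk.TumorModelParams(d50=30.89, gamma=1.3, alpha_beta=4.0, a=-7.2)
        scaled = dk.DifferentialDVH(ddvh.bin_centers * factor, ddvh.bin_fractions)
        assert dk.compute_eud(scaled, p, frac) >= dk.compute_eud(ddvh, p, frac) - 1e-9

    @given(differential_dvhs(), st.sampled_from([-7.2, -2.0, 0.5, 1.0, 3.0]))
    def test_power_mean_inequality(self, ddvh, a):
        frac = dk.FractionationScheme(28, 50.4)
        p = dk.TumorModelParams(d50=30.89, gamma=1.3, alpha_beta=4.0, a=a)
        p1 = dk.TumorModelParams(d50=30.89, gamma=1.3, alpha_beta=4.0, a=1.0)
        eud = dk.compute_eud(ddvh, p, frac)
        mean_eqd2 = dk.compute_eud(ddvh, p1, frac)
        if a <= 1:
            assert eud <= mean_eqd2 + 1e-9
        else:
            assert eud >= mean_eqd2 - 1e-9

    def test_extreme_exponent_limits(self, frac):
        ddvh = dk.DifferentialDVH(np.array([30.0, 45.0, 50.0]), np.array([0.2, 0.5, 0.3]))
        lo = dk.TumorModelParams(d50=30.89, gamma=1.3, alpha_beta=4.0, a=-200.0)
        hi = dk.TumorModelParams(d50=30.89, gamma=1.3, alpha_beta=4.0, a=200.0)
        e = dk.eqd2_bin(ddvh.bin_centers, frac, 4.0)
        assert dk.compute_eud(ddvh, lo, frac) == pytest.approx(e.min(), rel=0.02)
        assert dk.compute_eud(ddvh, hi, frac) == pytest.approx(e.max(), rel=0.02)


class TestTCP:
    def test_half_control_at_d50(self, frac, registry):
        p = registry["breast_tumor"]
        d_phys = dk.eqd2_inverse(p.d50, frac, p.alpha_beta)
        tcp = dk.compute_tcp_poisson_lq(uniform_ddvh(d_phys), p, frac)
        assert tcp == pytest.approx(0.5, abs=1e-12)

    def test_prescription_course_value(self, frac, registry):
        # uniform 50.4 Gy(RBE) in 28 fractions, D50=30.89, gamma=1.3, a/b=4
        # (frozen from an independent high-precision evaluation)
        tcp = dk.compute_tcp_poisson_lq(uniform_ddvh(50.4), registry["breast_tumor"], frac)
        assert tcp == pytest.approx(0.9296344244513496, rel=1e-12)

    def test_zero_dose_kills_control(self, frac, registry):
        tcp = dk.compute_tcp_poisson_lq(uniform_ddvh(0.0), registry["breast_tumor"], frac)
        assert tcp < 1e-14

    @given(differential_dvhs(), st.floats(1.02, 1.3))
    def test_monotone_under_dose_increase(self, ddvh, factor):
        frac = dk.FractionationScheme(28, 50.4)
        p = dk.TumorModelParams(d50=30.89, gamma=1.3, alpha_beta=4.0, a=-7.2)
        scaled = dk.DifferentialDVH(ddvh.bin_centers * factor, ddvh.bin_fractions)
        assert (
            dk.compute_tcp_poisson_lq(scaled, p, frac)
            >= dk.compute_tcp_poisson_lq(ddvh, p, frac) - 1e-12
        )

    def test_result_is_probability(self, frac, registry):
        ddvh = dk.DifferentialDVH(np.array([20.0, 48.0, 55.0]), np.array([0.1, 0.8, 0.1]))
        tcp = dk.compute_tcp_poisson_lq(ddvh, registry["breast_tumor"], frac)
        assert 0.0 <= tcp <= 1.0


class TestDeff:
    def test_n_one_is_mean_eqd2(self, frac):
        ddvh = dk.DifferentialDVH(np.array([10.0, 30.0]), np.array([0.5, 0.5]))
        e = dk.eqd2_bin(ddvh.bin_centers, frac, 3.0)
        assert dk.compute_deff(ddvh, 1.0, frac, 3.0) == pytest.approx(e.mean())

    def test_small_n_approaches_max(self, frac):
        ddvh = dk.DifferentialDVH(np.array([10.0, 30.0]), np.array([0.5, 0.5]))
        e_max = dk.eqd2_bin(30.0, frac, 3.0)
        assert dk.compute_deff(ddvh, 0.01, frac, 3.0) == pytest.approx(e_max, rel=0.01)

    def test_two_bin_value(self, frac):
        # (0.5*10^(1/0.35) + 0.5*30^(1/0.35))^0.35 on raw doses
        # (frozen from an independent high-precision evaluation)
        ddvh = dk.DifferentialDVH(np.array([10.0, 30.0]), np.array([0.5, 0.5]))
        deff = dk.compute_deff(ddvh, 0.35, frac, 3.0, use_eqd2=False)
        assert deff == pytest.approx(23.88957710452539, rel=1e-12)

    def test_nonpositive_n_rejected(self, frac):
        ddvh = dk.DifferentialDVH(np.array([10.0]), np.array([1.0]))
        with pytest.raises(ParameterError):
            dk.compute_deff(ddvh, 0.0, frac, 3.0)

    @given(differential_dvhs(), st.floats(0.05, 1.0))
    def test_bounded_by_bin_eqd2(self, ddvh, n):
        frac = dk.FractionationScheme(28, 50.4)
        e = dk.eqd2_bin(ddvh.bin_centers, frac, 3.0)
        deff = dk.compute_deff(ddvh, n, frac, 3.0)
        assert e.min() - 1e-9 <= deff <= e.max() + 1e-9


class TestNTCP:
    def test_half_complication_at_d50(self, frac, registry):
        heart = registry["heart"]
        d_phys = dk.eqd2_inverse(heart.d50, frac, heart.alpha_beta)
        res = dk.compute_ntcp_lkb(uniform_ddvh(d_phys), heart, frac)
        assert res.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.ntcp == pytest.approx(0.5, abs=1e-12)

    def test_heart_at_max_cohort_mean_dose_is_zero_percent(self, frac, registry):
        # uniform 1.07 Gy(RBE) heart dose: t ~ -9.86, NTCP far below 0.05%
        res = dk.compute_ntcp_lkb(uniform_ddvh(1.07), registry["heart"], frac)
        assert res.t_statistic == pytest.approx(-9.8645462797619, rel=1e-10)
        assert 0.0 < res.ntcp < 1e-20
        assert round(100.0 * res.ntcp, 1) == 0.0

    def test_standard_normal_quantile(self, frac):
        # Deff placed so that t = 1.645 -> NTCP ~ 95%
        p = dk.NormalTissueModelParams(d50=48.0, m=0.1, n=0.35, alpha_beta=3.0)
        deff_target = p.d50 * (1 + 1.645 * p.m)
        d_phys = dk.eqd2_inverse(deff_target, frac, 3.0)
        res = dk.compute_ntcp_lkb(uniform_ddvh(d_phys), p, frac)
        assert res.ntcp == pytest.approx(0.95, abs=0.001)

    @given(differential_dvhs(), st.floats(1.02, 1.3))
    def test_monotone_under_dose_increase(self, ddvh, factor):
        frac = dk.FractionationScheme(28, 50.4)
        p = dk.NormalTissueModelParams(d50=37.6, m=0.35, n=0.87)
        scaled = dk.DifferentialDVH(ddvh.bin_centers * factor, ddvh.bin_fractions)
        assert (
            dk.compute_ntcp_lkb(scaled, p, frac).ntcp
            >= dk.compute_ntcp_lkb(ddvh, p, frac).ntcp - 1e-12
        )

    def test_parameter_invariants(self):
        with pytest.raises(ParameterError):
            dk.NormalTissueModelParams(d50=48.0, m=0.1, n=1.5)
        with pytest.raises(ParameterError):
            dk.NormalTissueModelParams(d50=48.0, m=-0.1, n=0.35)


class TestBinningInvariance:
    def test_refining_uniform_dvh_changes_nothing(self, frac, registry):
        p = registry["breast_tumor"]
        heart = registry["heart"]
        one = uniform_ddvh(50.4)
        many = dk.DifferentialDVH(
            np.full(64, 50.4) + np.arange(64) * 1e-12,  # 64 identical-dose bins
            np.full(64, 1.0 / 64),
        )
        assert dk.compute_eud(many, p, frac) == pytest.approx(dk.compute_eud(one, p, frac), rel=1e-9)
        assert dk.compute_tcp_poisson_lq(many, p, frac) == pytest.approx(
            dk.compute_tcp_poisson_lq(one, p, frac), rel=1e-9
        )
        assert dk.compute_ntcp_lkb(many, heart, frac).deff == pytest.approx(
            dk.compute_ntcp_lkb(one, heart, frac).deff, rel=1e-9
        )


def test_registry_ships_study_parameter_sets(registry):
    tum = registry["breast_tumor"]
    assert (tum.d50, tum.gamma, tum.alpha_beta, tum.a) == (30.89, 1.3, 4.0, -7.2)
    heart = registry["heart"]
    assert (heart.d50, heart.m, heart.n) == (48.0, 0.1, 0.35)
    lung = registry["lung_ipsilateral"]
    assert (lung.d50, lung.m, lung.n) == (37.6, 0.35, 0.87)
    skin = registry["skin"]
    assert (skin.d50, skin.m, skin.n) == (39.0, 0.14, 0.38)
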