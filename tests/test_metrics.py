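import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vrscreen import (
    ScatteringProfile,
    channel_means,
    chi_lin,
    guinier_rg,
    invariants_vc_vp,
    metric_curve,
    mix_profiles,
    ratio_curve,
    shannon_binning,
    sphere_profile,
    volatility_ratio,
)
from vrscreen.metrics import (
    BinningError,
    DegenerateCurveError,
    EmptyChannelError,
    NoGuinierRegionError,
)
from vrscreen.profiles import TitrationPoint, TitrationSeries

from .oracles import brute_force_vr


class TestShannonBinning:
    def test_channel_width_at_dmax_7p2(self):
        grid = np.linspace(0.2, 2.0, 100)
        b = shannon_binning((0.2, 2.0), grid, 7.2)
        assert b.delta_q == pytest.approx(math.pi / 7.2)
        assert b.delta_q == pytest.approx(0.4363, abs=1e-4)

    def test_exact_tiling_all_weights_one(self):
        d_max = 7.2
        dq = math.pi / d_max
        grid = np.linspace(0.2, 0.2 + 4 * dq, 80, endpoint=False)
        b = shannon_binning((0.2, 0.2 + 4 * dq), grid, d_max)
        assert b.n_channels == 4
        np.testing.assert_allclose(b.weights, 1.0)

    def test_partial_last_channel_weight_half(self):
        # window 2.5 channels wide on a uniform grid -> w = (1, 1, 0.5)
        d_max = 7.2
        dq = math.pi / d_max
        grid = 0.2 + np.arange(50) * (dq / 20)  # 20 points per channel
        b = shannon_binning((grid[0], grid[-1] + 1e-12), grid, d_max)
        assert b.n_channels == 3
        np.testing.assert_allclose(b.weights, [1.0, 1.0, 0.5])

    def test_single_channel_window_rejected(self):
        grid = np.linspace(0.2, 0.5, 30)
        with pytest.raises(BinningError):
            shannon_binning((0.2, 0.5), grid, 7.2)

    def test_empty_channel_raises_naming_channel(self):
        d_max = 7.2
        dq = math.pi / d_max
        grid = np.concatenate([np.linspace(0.2, 0.2 + dq, 20, endpoint=False),
                               np.linspace(0.2 + 2.2 * dq, 0.2 + 3 * dq, 20)])
        with pytest.raises(EmptyChannelError, match="channel 1"):
            shannon_binning((0.2, 0.2 + 3 * dq), grid, d_max)


class TestRatioCurve:
    def test_identity_gives_unit_ratio(self, smooth_profile):
        rc = ratio_curve(smooth_profile, smooth_profile)
        np.testing.assert_allclose(rc.R, 1.0)

    def test_scale_removed_by_geometric_normalization(self, smooth_profile):
        scaled = smooth_profile.copy()
        scaled.I = 7.3 * scaled.I
        rc = ratio_curve(scaled, smooth_profile)
        np.testing.assert_allclose(rc.R, 1.0, rtol=1e-12)

    def test_geometric_mean_is_unity(self, smooth_profile, wiggly_profile):
        rc = ratio_curve(smooth_profile, wiggly_profile)
        assert np.mean(np.log(rc.R)) == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_points_dropped_and_counted(self):
        q = np.linspace(0.1, 1.0, 10)
        I = np.ones(10)
        I[3] = -1.0
        J = np.ones(10)
        J[7] = 0.0
        rc = ratio_curve(ScatteringProfile(q=q, I=I),
                         ScatteringProfile(q=q, I=J))
        assert rc.dropped_points == 2
        assert len(rc.R) == 8

    def test_too_few_points_degenerate(self):
        q = np.linspace(0.1, 1.0, 5)
        I = -np.ones(5)
        with pytest.raises(DegenerateCurveError):
            ratio_curve(ScatteringProfile(q=q, I=I),
                        ScatteringProfile(q=q, I=np.ones(5)))


class TestChannelMeans:
    def test_unit_ratio_unit_means(self, smooth_profile):
        b = shannon_binning((0.2, 2.0), smooth_profile.q, 7.2)
        rc = ratio_curve(smooth_profile, smooth_profile)
        cm = channel_means(rc, b)
        np.testing.assert_allclose(cm.R_i, 1.0)
        assert len(cm.R_i) == b.n_channels

    def test_geometric_mean_of_2_and_8_is_4(self):
        d_max = 7.2
        dq = math.pi / d_max
        q = 0.2 + np.arange(4) * (dq / 2)  # 2 points per channel, 2 channels
        R = np.array([2.0, 8.0, 1.0, 1.0])
        prof_I = ScatteringProfile(q=q, I=R)
        prof_J = ScatteringProfile(q=q, I=np.ones(4))
        b = shannon_binning((q[0], q[-1] + 1e-9), q, d_max)
        rc = ratio_curve(prof_I, prof_J)
        cm = channel_means(rc, b)
        # normalization divides by the global geometric mean g; channel
        # means are geomean(2,8)/g and geomean(1,1)/g
        g = (2.0 * 8.0 * 1.0 * 1.0) ** 0.25
        np.testing.assert_allclose(cm.R_i, [4.0 / g, 1.0 / g], rtol=1e-12)


class TestVolatilityRatio:
    def test_identity_zero(self, smooth_profile):
        b = shannon_binning((0.2, 2.0), smooth_profile.q, 7.2)
        vr, c = volatility_ratio(smooth_profile, smooth_profile, b)
        assert vr == pytest.approx(0.0, abs=1e-14)
        assert c == 0.0

    def test_matches_brute_force_oracle(self, smooth_profile, wiggly_profile):
        b = shannon_binning((0.2, 2.0), smooth_profile.q, 7.2)
        vr, _ = volatility_ratio(smooth_profile, wiggly_profile, b)
        expected = brute_force_vr(
            smooth_profile.q, smooth_profile.I, wiggly_profile.I,
            0.2, 2.0, 7.2,
        )
        assert vr == pytest.approx(expected, abs=1e-10)

    def test_oracle_agreement_with_partial_channel(self):
        # non-integer number of channels exercises the last-channel weight
        q = np.linspace(0.25, 1.8, 97)
        rng = np.random.default_rng(5)
        I = np.exp(-q) * (1 + 0.2 * rng.random(97)) * 50
        J = np.exp(-1.1 * q) * (1 + 0.2 * rng.random(97)) * 40
        pi_, pj = ScatteringProfile(q=q, I=I), ScatteringProfile(q=q, I=J)
        b = shannon_binning((0.25, 1.8), q, 7.2)
        assert b.weights[-1] < 1.0
        vr, _ = volatility_ratio(pi_, pj, b)
        assert vr == pytest.approx(
            brute_force_vr(q, I, J, 0.25, 1.8, 7.2), abs=1e-10
        )

    def test_symmetry(self, smooth_profile, wiggly_profile):
        b = shannon_binning((0.2, 2.0), smooth_profile.q, 7.2)
        v_ij, _ = volatility_ratio(smooth_profile, wiggly_profile, b)
        v_ji, _ = volatility_ratio(wiggly_profile, smooth_profile, b)
        assert v_ij == pytest.approx(v_ji, rel=1e-12)

    @given(a=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, a):
        q = np.linspace(0.2, 2.0, 60)
        I = 50 * np.exp(-q) + 2 * np.sin(3 * q) ** 2
        scaled = ScatteringProfile(q=q, I=a * I)
        base = ScatteringProfile(q=q, I=I)
        b = shannon_binning((0.2, 2.0), q, 7.2)
        vr, _ = volatility_ratio(scaled, base, b)
        assert vr == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_three_channel_fixture(self):
        # 2 points per channel, 3 channels, last channel 1 point (w = 0.5);
        # expected value evaluated by hand below
        d_max = 7.2
        dq = math.pi / d_max
        q = 0.2 + np.arange(5) * (dq / 2)
        I = np.array([2.0, 2.0, 4.0, 4.0, 8.0])
        J = np.ones(5)
        b = shannon_binning((q[0], q[-1] + 1e-9), q, d_max)
        np.testing.assert_allclose(b.weights, [1, 1, 0.5])
        g = (2 * 2 * 4 * 4 * 8) ** 0.2          # global geometric mean
        r1, r2, r3 = 2 / g, 4 / g, 8 / g        # channel geometric means
        expected = (
            abs(r2 - r1) / ((r1 + r2) / 2)
            + 0.5 * abs(r3 - r2) / ((r2 + r3) / 2)
        )
        vr, _ = volatility_ratio(
            ScatteringProfile(q=q, I=I), ScatteringProfile(q=q, I=J), b
        )
        assert vr == pytest.approx(expected, rel=1e-12)

    def test_fit_c_cancels_additive_offset(self, smooth_profile):
        b_off = 0.05 * np.median(smooth_profile.I)
        offset = smooth_profile.copy()
        offset.I = offset.I + b_off
        b = shannon_binning((0.2, 2.0), smooth_profile.q, 7.2)
        v_plain, _ = volatility_ratio(offset, smooth_profile, b, fit_c=False)
        v_fit, c = volatility_ratio(offset, smooth_profile, b, fit_c=True)
        assert v_fit <= v_plain
        # c = -b/2 splits the offset symmetrically and cancels it exactly
        assert v_fit == pytest.approx(0.0, abs=1e-6)
        assert c == pytest.approx(-b_off / 2.0, rel=0.05)

    def test_fit_c_never_worse_than_zero(self, smooth_profile, wiggly_profile):
        b = shannon_binning((0.2, 2.0), smooth_profile.q, 7.2)
        v0, _ = volatility_ratio(smooth_profile, wiggly_profile, b)
        vf, _ = volatility_ratio(smooth_profile, wiggly_profile, b, fit_c=True)
        assert vf <= v0 + 1e-12


class TestChiLin:
    def test_exact_linear_transform_gives_zero(self, smooth_profile):
        target = smooth_profile.copy()
        target.I = 2.0 * smooth_profile.I + 3.0
        target.sigma = np.ones_like(target.I)
        value, _ = chi_lin(target, smooth_profile)
        assert value == pytest.approx(0.0, abs=1e-10)

    def test_pure_noise_reduced_chi_near_one(self, rng):
        q = np.linspace(0.1, 2.0, 150)
        J = ScatteringProfile(q=q, I=100 * np.exp(-q))
        values = []
        for _ in range(30):
            noise = rng.normal(0, 1.0, len(q))
            I = ScatteringProfile(q=q, I=J.I + noise, sigma=np.ones(len(q)))
            values.append(chi_lin(I, J)[0])
        assert np.mean(values) == pytest.approx(1.0, abs=0.05)

    def test_misfit_monotone_and_large(self, rng):
        q = np.linspace(0.1, 2.0, 100)
        J = ScatteringProfile(q=q, I=100 * np.exp(-q))
        values = []
        for amp in (10.0, 50.0):
            bump = amp * np.exp(-((q - 1.0) ** 2) / 0.05)
            I = ScatteringProfile(q=q, I=J.I + bump, sigma=np.ones(len(q)))
            values.append(chi_lin(I, J)[0])
        assert values[0] > 1.5
        assert values[1] > 5.0
        assert values[1] > values[0]


class TestGuinier:
    def test_exact_guinier_data_recovered_exactly(self):
        rg = 1.96
        q = np.linspace(0.05, 1.2, 120)
        I = 250.0 * np.exp(-(q**2) * rg**2 / 3.0)
        prof = ScatteringProfile(q=q, I=I)
        rg_fit, i0, window, sigma = guinier_rg(prof)
        assert rg_fit == pytest.approx(rg, rel=1e-9)
        assert i0 == pytest.approx(250.0, rel=1e-9)
        assert window[1] * rg_fit <= 1.3 + 1e-9
        assert sigma == pytest.approx(0.0, abs=1e-6)

    def test_hard_sphere_rg_within_one_percent(self):
        radius = 2.5
        q = np.linspace(0.02, 1.5, 300)
        prof = sphere_profile(q, radius)
        # conservative window: Guinier truncation bias is ~1% already at qRg=1
        rg_fit, _, _, _ = guinier_rg(prof, qrg_max=0.8)
        assert rg_fit == pytest.approx(math.sqrt(3.0 / 5.0) * radius, rel=0.01)

    def test_low_q_upturn_excluded_or_error(self):
        rg = 1.9
        q = np.linspace(0.03, 1.2, 150)
        clean = 100.0 * np.exp(-(q**2) * rg**2 / 3.0)
        upturn = 400.0 * np.exp(-(q**2) * 25.0**2 / 3.0)  # aggregate term
        prof = ScatteringProfile(q=q, I=clean + upturn)
        try:
            rg_fit, _, window, _ = guinier_rg(prof)
        except NoGuinierRegionError:
            return
        # if a window is found it must sit beyond the aggregation spike
        assert window[0] > q[0]
        assert rg_fit < 5.0


class TestInvariants:
    def test_gaussian_closed_forms(self):
        rg = 1.8
        a = rg**2 / 3.0
        q = np.linspace(0.02, 8.0 / rg, 4000)
        prof = ScatteringProfile(q=q, I=50.0 * np.exp(-a * q**2))
        g = guinier_rg(prof, auto_range=False)
        vc, vp = invariants_vc_vp(prof, g)
        # int q exp(-a q^2) = 1/(2a); int q^2 exp(-a q^2) = sqrt(pi)/(4 a^1.5)
        assert vc == pytest.approx(2.0 * a, rel=1e-3)
        assert vp == pytest.approx(
            2.0 * math.pi**2 / (math.sqrt(math.pi) / (4.0 * a**1.5)), rel=1e-3
        )

    def test_scale_invariance(self):
        q = np.linspace(0.02, 3.0, 500)
        prof = sphere_profile(q, 2.5, scale=1.0)
        scaled = sphere_profile(q, 2.5, scale=123.0)
        g1 = guinier_rg(prof, qrg_max=1.0)
        g2 = guinier_rg(scaled, qrg_max=1.0)
        v1 = invariants_vc_vp(prof, g1)
        v2 = invariants_vc_vp(scaled, g2)
        assert v1[0] == pytest.approx(v2[0], rel=1e-9)
        assert v1[1] == pytest.approx(v2[1], rel=1e-9)

    def test_vp_monotone_in_qmax(self):
        q = np.linspace(0.02, 3.0, 500)
        prof = sphere_profile(q, 2.5)
        g = guinier_rg(prof, qrg_max=1.0)
        _, vp_full = invariants_vc_vp(prof, g, q_max=3.0)
        _, vp_half = invariants_vc_vp(prof, g, q_max=1.5)
        assert vp_half > vp_full  # truncating the q^2 I integral raises V_P


class TestMetricCurve:
    def _series_of_copies(self, reference, n=5):
        pts = [TitrationPoint(float(r), reference.copy()) for r in range(n)]
        return TitrationSeries("L", 20e-6, pts)

    def test_copies_of_reference_give_zero_vr(self, smooth_profile):
        b = shannon_binning((0.2, 2.0), smooth_profile.q, 7.2)
        series = self._series_of_copies(smooth_profile)
        curve = metric_curve(series, smooth_profile, "V_R", binning=b)
        np.testing.assert_allclose(curve.values, 0.0, atol=1e-13)

    def test_vr_monotone_in_bound_fraction(self, conformer_pair):
        from vrscreen.profiles import TitrationPoint, TitrationSeries

        ref = conformer_pair.profile_A
        b = shannon_binning((0.2, 2.0), ref.q, 7.2)
        fracs = [0.0, 0.2, 0.4, 0.6, 0.8, 1.0]
        pts = [
            TitrationPoint(f, mix_profiles(conformer_pair, f)) for f in fracs
        ]
        series = TitrationSeries("L", 20e-6, pts)
        curve = metric_curve(series, ref, "V_R", binning=b)
        assert np.all(np.diff(curve.values) >= -1e-12)

    def test_corrupt_point_flagged_not_fatal(self, smooth_profile):
        b = shannon_binning((0.2, 2.0), smooth_profile.q, 7.2)
        bad = smooth_profile.copy()
        bad.I = -np.abs(bad.I)  # all negative: degenerate ratio
        pts = [
            TitrationPoint(0.0, smooth_profile.copy()),
            TitrationPoint(1.0, bad),
            TitrationPoint(2.0, smooth_profile.copy()),
        ]
        series = TitrationSeries("L", 20e-6, pts)
        curve = metric_curve(series, smooth_profile, "V_R", binning=b)
        assert len(curve.values) == 2
        assert len(curve.excluded) == 1
        assert curve.excluded[0][0] == 1.0
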