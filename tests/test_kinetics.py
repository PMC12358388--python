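import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad, solve_ivp

from ldvdose.kinetics import (
    PURE_BLOOD,
    FrameSchedule,
    KineticParams,
    NonFiniteAUCError,
    auc_R,
    effective_half_life,
    integration_horizon,
    lambda_per_min_from_half_life_days,
    ldv,
    macro_rates,
    simulate_tissue_tac,
)

LU177_LAM = lambda_per_min_from_half_life_days(6.67)


def residue_ode(kp: KineticParams, t_grid: np.ndarray) -> np.ndarray:
    """Independent oracle: integrate the two-compartment ODE system with
    decay for an instantaneous unit arterial bolus and return C1 + C2."""

    def rhs(_t, y):
        c1, c2 = y
        dc1 = -(kp.k2 + kp.k3 + kp.lam) * c1 + kp.k4 * c2
        dc2 = kp.k3 * c1 - (kp.k4 + kp.lam) * c2
        return [dc1, dc2]

    sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]), [kp.K1, 0.0],
                    t_eval=t_grid, rtol=1e-11, atol=1e-14)
    return sol.y.sum(axis=0)


rate_st = st.floats(min_value=0.01, max_value=2.0)


class TestMacroRates:
    def test_no_efflux_no_decay_constant(self):
        mr = macro_rates(KineticParams(0.1, 0.0, 0.0, 0.0, 0.0))
        assert mr.G + mr.H == pytest.approx(0.1)
        assert mr.alpha == 0.0 and mr.beta == 0.0
        t = np.linspace(0, 100, 7)
        assert np.allclose(mr.residue(t), 0.1)

    def test_one_compartment_reduction(self):
        mr = macro_rates(KineticParams(0.2, 0.3, 0.0, 0.0, 0.0))
        t = np.linspace(0, 30, 50)
        assert np.allclose(mr.residue(t), 0.2 * np.exp(-0.3 * t), rtol=1e-12)

    def test_against_ode_oracle(self):
        kp = KineticParams(0.15, 0.4, 0.05, 0.02, 0.0)
        t = np.linspace(0, 60, 200)
        assert np.allclose(macro_rates(kp).residue(t), residue_ode(kp, t),
                           rtol=1e-7, atol=1e-12)
        # numeric integral of R matches the closed-form LDV-limit AUC
        num = np.trapezoid(macro_rates(kp).residue(np.linspace(0, 4000, 400001)),
                           np.linspace(0, 4000, 400001))
        assert num == pytest.approx(kp.K1 * (kp.k3 + kp.k4) / (kp.k2 * kp.k4), rel=1e-4)

    def test_r0_equals_K1_and_auc_consistency(self):
        kp = KineticParams(0.5, 0.9, 0.3, 0.2, 0.001)
        mr = macro_rates(kp)
        assert mr.residue(0.0) == pytest.approx(kp.K1, rel=1e-12)
        analytic = mr.G / mr.alpha + mr.H / mr.beta
        assert analytic == pytest.approx(auc_R(kp), rel=1e-10)

    def test_degenerate_repeated_root(self):
        # k3 = 0, k2 == k4 gives a repeated eigenvalue
        kp = KineticParams(0.3, 0.5, 0.0, 0.5, 0.0)
        mr = macro_rates(kp)
        assert mr.alpha == mr.beta
        t = np.linspace(0, 40, 300)
        assert np.allclose(mr.residue(t), residue_ode(kp, t), rtol=1e-6, atol=1e-12)

    @given(K1=rate_st, k2=rate_st, k3=rate_st, k4=rate_st,
           lam=st.floats(min_value=0.0, max_value=0.1))
    @settings(max_examples=50, deadline=None)
    def test_invariants(self, K1, k2, k3, k4, lam):
        kp = KineticParams(K1, k2, k3, k4, lam)
        mr = macro_rates(kp)
        assert mr.alpha <= mr.beta
        assert mr.G >= -1e-12 and mr.H >= -1e-12
        assert mr.G + mr.H == pytest.approx(K1, rel=1e-9)
        assert mr.alpha >= lam - 1e-15 and mr.beta >= lam - 1e-15
        # R(t) >= 0 and non-increasing
        r = mr.residue(np.linspace(0, 50, 400))
        assert np.all(r >= -1e-12)
        assert np.all(np.diff(r) <= 1e-12)


class TestAucR:
    def test_lam_zero_is_ldv(self):
        kp = KineticParams(0.15, 0.4, 0.05, 0.02, 0.0)
        assert auc_R(kp) == pytest.approx(0.375 * 3.5)
        assert auc_R(kp) == pytest.approx(ldv(kp), rel=1e-12)

    def test_k3_zero(self):
        assert auc_R(KineticParams(0.2, 0.4, 0.0, 0.0, 0.0)) == pytest.approx(0.5)

    def test_quadrature_oracle_with_lu177_decay(self):
        kp = KineticParams(0.15, 0.4, 0.05, 0.02, LU177_LAM)
        mr = macro_rates(kp)
        num, _ = quad(mr.residue, 0.0, np.inf, limit=500)
        assert auc_R(kp) == pytest.approx(num, rel=1e-8)

    def test_infinite_auc_raises(self):
        with pytest.raises(NonFiniteAUCError):
            auc_R(KineticParams(0.2, 0.4, 0.1, 0.0, 0.0))

    @given(K1=rate_st, k2=rate_st, k3=rate_st, k4=rate_st,
           lam=st.floats(min_value=1e-5, max_value=0.05))
    @settings(max_examples=40, deadline=None)
    def test_monotonicity(self, K1, k2, k3, k4, lam):
        kp = KineticParams(K1, k2, k3, k4, lam)
        base = auc_R(kp)
        assert auc_R(KineticParams(K1 * 1.1, k2, k3, k4, lam)) >= base
        assert auc_R(KineticParams(K1, k2, k3 * 1.1, k4, lam)) >= base - 1e-12
        assert auc_R(KineticParams(K1, k2 * 1.1, k3, k4, lam)) <= base + 1e-12
        assert auc_R(KineticParams(K1, k2, k3, k4, lam * 1.1)) <= base + 1e-12


class TestLdv:
    def test_direct_arithmetic(self):
        assert ldv(KineticParams(0.15, 0.4, 0.05, 0.02)) == pytest.approx(1.3125)

    def test_k3_zero(self):
        assert ldv(KineticParams(0.15, 0.4, 0.0, 0.0)) == pytest.approx(0.375)

    def test_k2_zero_raises(self):
        with pytest.raises(ValueError):
            ldv(KineticParams(0.15, 0.0, 0.05, 0.02))

    def test_small_decay_approximation_under_1pct(self):
        kp0 = KineticParams(0.15, 0.4, 0.05, 0.02)
        kp_lu = KineticParams(0.15, 0.4, 0.05, 0.02, LU177_LAM)
        assert abs(ldv(kp0) - auc_R(kp_lu)) / auc_R(kp_lu) < 0.01

    def test_phantom_defaults_hit_calibration_ranges(self):
        from ldvdose.phantom import default_tissues

        got = {t.name: ldv(t.kp) for t in default_tissues()}
        assert 2.03 <= got["tumor"] <= 5.38
        assert 1.17 <= got["prostate"] <= 1.67
        assert 0.26 <= got["femur_r"] <= 0.36


class TestFrameSchedule:
    def test_default_protocol(self):
        from ldvdose.phantom import default_frame_schedule

        fs = default_frame_schedule()
        assert fs.n_frames == 28
        assert fs.span_s == pytest.approx(1330.0)
        assert fs.mid_s[0] == pytest.approx(5.0)

    def test_rejects_gaps(self):
        with pytest.raises(ValueError):
            FrameSchedule(np.array([0.0, 15.0]), np.array([10.0, 10.0]))

    def test_rejects_nonpositive_durations(self):
        with pytest.raises(ValueError):
            FrameSchedule(np.array([0.0, 10.0]), np.array([10.0, 0.0]))


class TestSimulateTissueTac:
    @pytest.fixture()
    def fs(self):
        from ldvdose.phantom import default_frame_schedule

        return default_frame_schedule()

    def test_zero_aif(self, fs):
        t = np.arange(0.0, 1331.0)
        out = simulate_tissue_tac(t, np.zeros_like(t), KineticParams(0.2, 0.3, 0.1, 0.05), fs)
        assert out.shape == (28,)
        assert np.allclose(out, 0.0)

    def test_impulse_aif_proportional_to_residue(self, fs):
        # 1-s bolus at t=1 s: TAC is the (shifted) residue function itself
        t = np.arange(0.0, 1331.0)
        aif = np.zeros_like(t)
        aif[1] = 1.0
        kp = KineticParams(0.2, 0.3, 0.1, 0.05)
        out = simulate_tissue_tac(t, aif, kp, fs)
        mr = macro_rates(kp)
        fine = mr.residue(np.maximum(t - 1.0, 0.0) / 60.0)
        expected = np.array([
            np.trapezoid(fine[int(s):int(s + d) + 1], t[int(s):int(s + d) + 1]) / d
            for s, d in zip(fs.start_s, fs.duration_s)
        ])
        assert np.allclose(out[1:], expected[1:] / 60.0, rtol=5e-3)

    def test_pure_blood_passthrough(self, fs):
        t = np.arange(0.0, 1331.0)
        aif = 100.0 * np.exp(-t / 300.0)
        out = simulate_tissue_tac(t, aif, PURE_BLOOD, fs)
        expected = np.array([
            np.trapezoid(aif[int(s):int(s + d) + 1], t[int(s):int(s + d) + 1]) / d
            for s, d in zip(fs.start_s, fs.duration_s)
        ])
        assert np.allclose(out, expected, rtol=1e-9)

    def test_short_aif_rejected(self, fs):
        t = np.arange(0.0, 600.0)
        with pytest.raises(ValueError):
            simulate_tissue_tac(t, np.ones_like(t), KineticParams(0.2, 0.3, 0.0, 0.0), fs)

    def test_fubini_factorization(self):
        # integral of TAC == integral of AIF times AUC of R, over >= 5 T_eff
        kp = KineticParams(0.3, 0.8, 0.4, 0.3, 0.002)
        horizon_s = 5 * 60.0 * np.log(2) / 0.002  # generous vs T_eff
        fs = FrameSchedule.from_durations(np.full(int(horizon_s // 60), 60.0))
        t = np.arange(0.0, fs.end_s[-1] + 1.0)
        aif = 50.0 * np.exp(-t / 120.0)
        tac = simulate_tissue_tac(t, aif, kp, fs)
        int_tac = float(np.sum(tac * fs.duration_s)) / 60.0
        int_aif = np.trapezoid(aif, t) / 60.0
        assert int_tac == pytest.approx(int_aif * auc_R(kp), rel=5e-3)


class TestEffectiveHalfLife:
    def test_harmonic_combination(self):
        assert effective_half_life(6.0, 3.0) == pytest.approx(2.0)

    def test_never_exceeds_either(self):
        for tp, tb in [(6.67, 0.5), (1.0, 100.0), (3.0, 3.0)]:
            te = effective_half_life(tp, tb)
            assert te <= min(tp, tb) + 1e-12

    def test_horizon_helper(self):
        assert integration_horizon(6.0, 3.0) == pytest.approx(10.0)


def test_params_roundtrip_serialization():
    kp = KineticParams(0.5, 0.9, 0.3, 0.2, 0.001)
    assert KineticParams.from_dict(kp.to_dict()) == kp


def test_params_reject_negative():
    with pytest.raises(ValueError):
        KineticParams(-0.1, 0.4, 0.05, 0.02)
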