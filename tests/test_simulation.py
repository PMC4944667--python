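"""ODE integration against independent oracles and trajectory analyses."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dmtpk
from dmtpk import (
    DoseEvent,
    DosingRegimen,
    NoPeakError,
    PKParameters,
    closed_form_linear_bolus,
    mass_balance_residual,
    breakthrough_window,
    peak,
    predict_plasma,
    simulate,
    threshold_window,
)


def _rk4_oracle(params, regimen, horizon, dt=1e-3):
    """Brute-force fixed-step 4th-order integrator, independent of the
    package's solver path; returns (t, Cc)."""
    Vc, Vp, Q12 = params.Vc, params.Vp, params.Q12

    def rhs(t, y):
        Cc, Cp = y
        u = regimen.rate_at(t)
        elim = (params.Vm * Cc / (params.Km + Cc) if params.is_saturable
                else params.CL * Cc)
        tr = Q12 * (Cc - Cp)
        return np.array([(u - elim - tr) / Vc, tr / Vp])

    n = int(round(horizon / dt))
    t = 0.0
    y = np.zeros(2)
    ts = np.empty(n + 1)
    cc = np.empty(n + 1)
    ts[0], cc[0] = 0.0, 0.0
    for i in range(n):
        k1 = rhs(t, y)
        k2 = rhs(t + dt / 2, y + dt / 2 * k1)
        k3 = rhs(t + dt / 2, y + dt / 2 * k2)
        k4 = rhs(t + dt, y + dt * k3)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += dt
        ts[i + 1], cc[i + 1] = t, y[0]
    return ts, cc


class TestSimulate:
    def test_zero_regimen_stays_zero(self, params04, tuned_effect):
        res = simulate(params04, tuned_effect, DosingRegimen(()), 10.0)
        assert np.all(res.Cc == 0) and np.all(res.Ce == 0)
        assert mass_balance_residual(res) == 0.0

    def test_against_fixed_step_oracle(self, params04, bolus04):
        """Adaptive solution of the 30 mg / 30 s scenario agrees with a
        brute-force RK4 integration at 1e-3 min steps within 0.1%."""
        res = simulate(params04, None, bolus04, 10.0)
        ts, cc = _rk4_oracle(params04, bolus04, 10.0)
        ours = res.cc_at(ts[::100])
        theirs = cc[::100]
        mask = theirs > 1e-6
        assert np.max(np.abs(ours[mask] - theirs[mask]) / theirs[mask]) < 1e-3
        # plasma peak sits at the end of the infusion ramp
        t_pk, _ = peak(res, "Cc")
        assert t_pk == pytest.approx(0.5, abs=0.01)

    def test_linear_limit_matches_closed_form(self, linear_params):
        """Saturable model with Km >> any concentration reduces to the
        bi-exponential disposition."""
        dose = 10.0
        cf = closed_form_linear_bolus(dose, linear_params)
        km = 1e6 * (dose / linear_params.Vc)
        mm = PKParameters(Vc=linear_params.Vc, Vp=linear_params.Vp,
                          Q12=linear_params.Q12, Vm=linear_params.CL * km, Km=km)
        reg = DosingRegimen((DoseEvent(0.0, 0.0, amount=dose),))
        res = simulate(mm, None, reg, 60.0, rtol=1e-10, atol=1e-13)
        t = res.t[res.t > 0]
        rel = np.abs(res.cc_at(t) - cf(t)) / cf(t)
        assert np.max(rel) < 1e-6

    def test_horizon_must_cover_dosing(self, params04, bolus04):
        with pytest.raises(ValueError):
            simulate(params04, None, bolus04, 0.25)

    def test_grid_refinement_converged(self, params04, tuned_effect):
        """Halving solver tolerances leaves the trajectory unchanged to 1e-4."""
        reg = DosingRegimen.bolus(22.0).with_infusion(2.0, 58.0, 2.0)
        a = simulate(params04, tuned_effect, reg, 60.0, rtol=1e-8, atol=1e-10)
        b = simulate(params04, tuned_effect, reg, 60.0, rtol=4e-9, atol=5e-11)
        t = np.linspace(0.1, 59.9, 400)
        ca, cb = a.cc_at(t), b.cc_at(t)
        assert np.max(np.abs(ca - cb) / np.maximum(cb, cb.max() * 1e-6)) < 1e-4

    @given(
        vc=st.floats(10.0, 200.0),
        vp=st.floats(50.0, 1000.0),
        q=st.floats(1.0, 100.0),
        vm=st.floats(0.5, 10.0),
        km_ng=st.floats(5.0, 100.0),
        dose=st.floats(5.0, 60.0),
        rate=st.floats(0.0, 5.0),
    )
    @settings(max_examples=25, deadline=None)
    def test_nonnegative_and_mass_conserving(self, vc, vp, q, vm, km_ng, dose, rate):
        p = PKParameters(Vc=vc, Vp=vp, Q12=q, Vm=vm, Km=km_ng / 1000.0)
        reg = DosingRegimen.bolus(dose).with_infusion(2.0, 20.0, rate)
        res = simulate(p, dmtpk.EffectSiteParams.linked(0.3), reg, 30.0)
        assert res.Cc.min() >= 0 and res.Cp.min() >= 0 and res.Ce.min() >= 0
        assert mass_balance_residual(res) < 1e-6


class TestClosedForm:
    def test_initial_dilution(self, linear_params):
        cf = closed_form_linear_bolus(9.0, linear_params)
        assert cf(0.0) == pytest.approx(9.0 / linear_params.Vc, rel=1e-12)

    def test_degenerate_one_compartment(self):
        p = PKParameters(Vc=100.0, Vp=1.0, Q12=0.0, CL=5.0)
        cf = closed_form_linear_bolus(10.0, p)
        t = np.array([0.0, 1.0, 10.0])
        expected = 0.1 * np.exp(-0.05 * t)
        assert cf(t) == pytest.approx(expected, rel=1e-12)

    def test_matches_ode(self, linear_params):
        cf = closed_form_linear_bolus(12.0, linear_params)
        reg = DosingRegimen((DoseEvent(0.0, 0.0, amount=12.0),))
        res = simulate(linear_params, None, reg, 60.0, rtol=1e-11, atol=1e-14)
        for t in (0.5, 5.0, 50.0):
            assert res.cc_at(t)[0] == pytest.approx(cf(t), rel=1e-8)

    def test_rejects_saturable(self, params04):
        with pytest.raises(ValueError, match="linear clearance"):
            closed_form_linear_bolus(10.0, params04)


class TestMassBalance:
    def test_shipped_scenario_tight(self, params04, tuned_effect):
        reg = DosingRegimen.per_kg_bolus(0.4, 75.0)
        res = simulate(params04, tuned_effect, reg, 60.0)
        assert mass_balance_residual(res) < 1e-6

    def test_coarse_tolerances_degrade_gracefully(self, params04):
        reg = DosingRegimen.per_kg_bolus(0.4, 75.0)
        res = simulate(params04, None, reg, 60.0, rtol=1e-4, atol=1e-6)
        r = mass_balance_residual(res)
        assert r < 1e-3


class TestThresholdAndPeak:
    def test_triangular_window(self):
        """Rise 0->120 over 2 min, fall to 0 over 4 min; 60-crossing at
        1.0 and 4.0 min by linear geometry."""
        t = np.array([0.0, 2.0, 6.0])
        y = np.array([0.0, 120.0, 0.0])
        win = threshold_window(t, y, 60.0)
        assert win.entry == pytest.approx(1.0)
        assert win.exit == pytest.approx(4.0)
        assert win.duration == pytest.approx(3.0)

    def test_below_threshold_is_empty(self, params04, tuned_effect):
        reg = DosingRegimen.bolus(0.5)  # sub-threshold dose
        res = simulate(params04, tuned_effect, reg, 20.0)
        assert breakthrough_window(res, threshold_ng_ml=60.0) is None

    def test_bolus_breakthrough_window_brackets_peak(self, params04, tuned_effect,
                                                     bolus04):
        res = simulate(params04, tuned_effect, bolus04, 20.0)
        win = breakthrough_window(res)
        t_pk, _ = peak(res, "Ce")
        assert win is not None and win.entry < t_pk < win.exit
        assert win.duration > 0

    def test_effect_site_peak_stationarity(self, params04, tuned_effect, bolus04):
        """At the effect-site peak dCe/dt = 0, so with k1e = ke0 the
        effect-site and plasma concentrations coincide."""
        res = simulate(params04, tuned_effect, bolus04, 20.0)
        t_pk, ce_pk = peak(res, "Ce")
        cc_pk = res.cc_at(t_pk)[0]
        assert ce_pk == pytest.approx(cc_pk, rel=0.01)

    def test_no_peak_on_zero_trajectory(self, params04, tuned_effect):
        res = simulate(params04, tuned_effect, DosingRegimen(()), 5.0)
        with pytest.raises(NoPeakError):
            peak(res, "Ce")


class TestDoseEvents:
    def test_amount_rate_consistency(self):
        e = DoseEvent(0.0, 0.5, rate=60.0)
        assert e.amount == 30.0
        e2 = DoseEvent(0.0, 0.5, amount=30.0)
        assert e2.rate == 60.0
        with pytest.raises(ValueError):
            DoseEvent(0.0, 0.5, rate=60.0, amount=10.0)

    def test_instantaneous_requires_amount(self):
        with pytest.raises(ValueError):
            DoseEvent(0.0, 0.0, rate=5.0)

    def test_events_sorted_and_overlap_additive(self, params04):
        reg = DosingRegimen((DoseEvent(5.0, 5.0, rate=1.0),
                             DoseEvent(0.0, 10.0, rate=2.0)))
        assert reg.events[0].start == 0.0
        assert reg.rate_at(6.0) == 3.0
        assert reg.rate_at(11.0) == 0.0

    def test_predict_plasma_matches_simulate(self, params04, bolus04, sampling_times):
        fast = predict_plasma(params04, bolus04, sampling_times)
        res = simulate(params04, None, bolus04, 61.0)
        ref = res.cc_at(sampling_times)
        assert fast == pytest.approx(ref, rel=1e-5)
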