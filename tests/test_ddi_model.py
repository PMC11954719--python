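"""Mechanistic model: enzyme turnover, disposition, and trial-design ratios."""

import math

import numpy as np
import pytest
from dataclasses import replace
from scipy.integrate import solve_ivp

from ritopk.ddi_model import (
    DDIModelParams,
    DoseEvent,
    TRIAL_SAMPLING_TIMES,
    day5_exposure_ratio,
    enzyme_trajectory,
    ritonavir_bid_events,
    simulate_concentrations,
)
from ritopk.exceptions import ValidationError


class TestEnzymeTrajectory:
    def test_no_ritonavir_stays_at_one(self, default_params):
        states = enzyme_trajectory(default_params, [], [0, 10, 100, 1000])
        assert all(s.e_gut == 1.0 and s.e_liver == 1.0 for s in states)

    def test_constant_presence_fixed_point(self, default_params):
        """Under permanent ritonavir coverage E converges to k_deg/(k_deg+k_inact)."""
        p = replace(default_params, rtv_coverage_h=1e5)
        events = [DoseEvent(0.0, "ritonavir", 1e8)]
        e_inf = p.k_deg / (p.k_deg + p.k_inact)
        state = enzyme_trajectory(p, events, [400.0])[0]
        assert state.e_gut == pytest.approx(e_inf, rel=1e-9)

    def test_recovery_matches_closed_form(self, default_params):
        """After the last dose's coverage ends, E(t) = 1 - (1-e0) exp(-k_deg (t-t0))."""
        events = ritonavir_bid_events()
        t0 = 120.0  # last dose at 108 h + 12 h coverage
        e0 = enzyme_trajectory(default_params, events, [t0])[0].e_gut
        for t in (130.0, 150.0, 200.0, 400.0):
            expected = 1.0 - (1.0 - e0) * math.exp(-default_params.k_deg * (t - t0))
            got = enzyme_trajectory(default_params, events, [t])[0].e_gut
            assert got == pytest.approx(expected, abs=1e-9)

    def test_matches_independent_ode_integration(self, default_params):
        """Piecewise-analytic solution vs direct solve_ivp of the turnover ODE."""
        events = ritonavir_bid_events()
        windows = [(e.time, e.time + default_params.rtv_coverage_h) for e in events]

        def R(t):
            return 1.0 if any(lo <= t < hi for lo, hi in windows) else 0.0

        def rhs(t, y):
            return [default_params.k_deg * (1 - y[0])
                    - default_params.k_inact * R(t) * y[0]]

        t_eval = np.array([0.0, 6.0, 12.0, 24.0, 96.0, 119.9, 150.0, 300.0])
        sol = solve_ivp(rhs, (0, 300), [1.0], t_eval=t_eval, method="LSODA",
                        rtol=1e-10, atol=1e-12, max_step=1.0)
        ours = [s.e_gut for s in enzyme_trajectory(default_params, events, t_eval)]
        assert np.allclose(ours, sol.y[0], atol=1e-6)

    def test_bounded_and_monotone_recovery(self, default_params):
        events = ritonavir_bid_events()
        t = np.linspace(0, 400, 300)
        e = np.array([s.e_gut for s in enzyme_trajectory(default_params, events, t)])
        assert np.all(e > 0) and np.all(e <= 1)
        post = e[t > 120.0]
        assert np.all(np.diff(post) >= -1e-12)


class TestSimulateConcentrations:
    def test_no_dose_gives_zero(self, default_params):
        conc = simulate_concentrations(default_params, [], [], [0, 1, 2])
        assert np.all(conc == 0)

    def test_analytic_matches_independent_ode(self, default_params):
        """Closed-form superposition vs a direct ODE integration written here."""
        p = default_params
        dose, dur = 1e7, p.d0
        rate = dose * p.f_rel_base / dur

        def rhs(t, y):
            inp = rate if 0 <= t < dur else 0.0
            ac, ap = y
            return [
                inp - (p.k10 + p.k12) * ac + p.k21 * ap,
                p.k12 * ac - p.k21 * ap,
            ]

        t_eval = np.array([0.5, 1.0, 1.5, 3.0, 8.0, 24.0, 49.0])
        pieces = []
        y = np.zeros(2)
        for lo, hi in ((0.0, dur), (dur, 49.0)):
            inside = t_eval[(t_eval > lo) & (t_eval <= hi)]
            sol = solve_ivp(rhs, (lo, hi), y,
                            t_eval=np.unique(np.append(inside, hi)),
                            method="LSODA", rtol=1e-11, atol=1e-13)
            lut = dict(zip(sol.t, sol.y[0]))
            pieces.extend(lut[t] for t in inside)
            y = sol.y[:, -1]
        oracle = np.array(pieces) / (p.vc_f * 1000.0)
        ours = simulate_concentrations(
            p, [DoseEvent(0.0, "statin", dose)], [], t_eval
        )
        assert np.allclose(ours, oracle, rtol=1e-6)

    def test_engines_agree(self, default_params):
        rtv = ritonavir_bid_events()
        statin = [DoseEvent(96.0, "statin", 1e7)]
        t = np.linspace(96, 145, 25)
        a = simulate_concentrations(default_params, statin, rtv, t, engine="analytic")
        o = simulate_concentrations(default_params, statin, rtv, t, engine="ode")
        assert np.allclose(a, o, rtol=1e-6)

    def test_superposition_of_doses(self, default_params):
        t = np.linspace(0, 72, 100)
        d1 = [DoseEvent(0.0, "statin", 1e7)]
        d2 = [DoseEvent(24.0, "statin", 5e6)]
        both = simulate_concentrations(default_params, d1 + d2, [], t)
        summed = (
            simulate_concentrations(default_params, d1, [], t)
            + simulate_concentrations(default_params, d2, [], t)
        )
        assert np.allclose(both, summed, atol=1e-8, rtol=1e-10)

    def test_mass_balance_auc(self, default_params):
        """AUC_inf x CL = F x dose for the baseline single dose."""
        t = np.arange(0.0, 400.0, 0.005)
        conc = simulate_concentrations(
            default_params, [DoseEvent(0.0, "statin", 1e7)], [], t
        )
        auc = float(np.trapezoid(conc, t))
        expected = default_params.f_rel_base * 1e7 / (default_params.cl_f_base * 1e3)
        assert auc == pytest.approx(expected, rel=1e-3)

    def test_terminal_half_life_matches_slow_eigenvalue(self, default_params):
        from ritopk.nca import fit_lambda_z
        from .conftest import make_profile

        sched = np.asarray(TRIAL_SAMPLING_TIMES)
        conc = simulate_concentrations(
            default_params, [DoseEvent(0.0, "statin", 1e7)], [], sched
        )
        fit = fit_lambda_z(make_profile(sched, conc))
        _, beta = default_params.eigenrates()
        assert fit.t_half == pytest.approx(math.log(2) / beta, rel=0.02)


class TestModulationMappings:
    def test_full_inhibition_factors(self, default_params):
        p = default_params
        assert p.bioavailability_factor(1.0) == pytest.approx(1.0)
        assert p.bioavailability_factor(0.0) == pytest.approx(1.0 / 0.57, rel=1e-12)
        assert p.absorption_duration(1.0) == pytest.approx(p.d0)
        assert p.absorption_duration(0.0) == pytest.approx(p.d0 * 1.71, rel=1e-12)

    def test_near_complete_inhibition_auc_ratio_approaches_ceiling(self, default_params):
        """With E_gut ~ 0 the AUC ratio tends to 1/theta_f = 1.75."""
        p = replace(default_params, k_inact=50.0)
        auc_ratio, _ = day5_exposure_ratio(p)
        assert auc_ratio == pytest.approx(1.0 / 0.57, rel=0.01)


class TestDay5ExposureRatio:
    def test_no_inactivation_gives_unity(self, default_params):
        p = replace(default_params, k_inact=0.0)
        auc_ratio, cmax_ratio = day5_exposure_ratio(p)
        assert auc_ratio == pytest.approx(1.0, abs=1e-9)
        assert cmax_ratio == pytest.approx(1.0, abs=1e-9)

    def test_default_interaction_raises_exposure(self, default_params):
        auc_ratio, cmax_ratio = day5_exposure_ratio(default_params)
        assert auc_ratio > 1.5
        assert cmax_ratio > 1.2


class TestValidationErrors:
    def test_bad_params(self):
        with pytest.raises(ValidationError):
            DDIModelParams(theta_f=1.5)
        with pytest.raises(ValidationError):
            DDIModelParams(theta_d=0.9)
        with pytest.raises(ValidationError):
            DDIModelParams(cl_f_base=-1)
        with pytest.raises(ValidationError):
            DDIModelParams(k_inact=-0.1)

    def test_bad_events(self):
        with pytest.raises(ValidationError):
            DoseEvent(-1.0, "statin", 1e6)
        with pytest.raises(ValidationError):
            DoseEvent(0.0, "statin", 0.0)
        with pytest.raises(ValidationError):
            DoseEvent(0.0, "aspirin", 1e6)
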