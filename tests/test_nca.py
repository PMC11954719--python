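"""Noncompartmental estimators against closed-form and brute-force oracles."""

import math

import numpy as np
import pytest
from scipy import stats

from ritopk.dataset_io import AnalyteSpec
from ritopk.ddi_model import DDIModelParams, DoseEvent, TRIAL_SAMPLING_TIMES, simulate_concentrations
from ritopk.exceptions import (
    EmptyProfileError,
    ExtrapolationError,
    InsufficientDataError,
    NoTerminalPhaseError,
    UnitError,
)
from ritopk.nca import (
    auc_linlog,
    dose_normalized_auc,
    fit_lambda_z,
    nca_summary,
    total_inhibitory_activity,
)
from .conftest import make_profile


class TestLambdaZ:
    def test_exact_exponential(self):
        t = np.array([4.0, 6.0, 8.0, 24.0])
        p = make_profile(t, 10.0 * np.exp(-0.0693 * t))
        fit = fit_lambda_z(p)
        assert fit.lambda_z == pytest.approx(0.0693, rel=1e-9)
        assert fit.t_half == pytest.approx(10.0, rel=1e-3)
        assert fit.t_half * fit.lambda_z == pytest.approx(math.log(2), rel=1e-15)

    def test_constant_profile_has_no_terminal_phase(self):
        p = make_profile([0, 1, 2, 3], [5, 5, 5, 5])
        with pytest.raises(NoTerminalPhaseError):
            fit_lambda_z(p)

    def test_too_few_points(self):
        p = make_profile([0, 1, 2], [1, 5, 3])
        with pytest.raises(InsufficientDataError):
            fit_lambda_z(p)

    def test_best_subset_matches_bruteforce_enumeration(self):
        """Adjusted-R2 selection equals exhaustive enumeration of terminal subsets."""
        rng = np.random.default_rng(42)
        for _ in range(10):
            t = np.array([0.5, 1, 2, 3, 4, 6, 8, 12, 24, 48])
            c = 20 * np.exp(-0.15 * t) * np.exp(0.1 * rng.standard_normal(len(t)))
            c[0] *= 0.3  # rising then falling
            p = make_profile(t, c)
            fit = fit_lambda_z(p)
            # oracle: scan every terminal suffix of >= 3 points strictly after Tmax
            i_max = int(np.argmax(c))
            tt, cc = t[i_max + 1:], c[i_max + 1:]
            best = None
            for start in range(len(tt) - 2):
                res = stats.linregress(tt[start:], np.log(cc[start:]))
                n = len(tt) - start
                adj = 1 - (1 - res.rvalue**2) * (n - 1) / (n - 2)
                if res.slope >= 0:
                    continue
                if best is None or adj > best[0] + 1e-12 or (
                    abs(adj - best[0]) <= 1e-12 and n > best[1]
                ):
                    best = (adj, n, -res.slope)
            assert fit.n_points == best[1]
            assert fit.lambda_z == pytest.approx(best[2], rel=1e-9)

    def test_manual_range(self):
        t = np.array([1.0, 4, 6, 8, 24])
        p = make_profile(t, np.concatenate([[1.0], 10 * np.exp(-0.1 * t[1:])]))
        fit = fit_lambda_z(p, selection="manual", time_range=(6, 24))
        assert fit.n_points == 3
        assert fit.lambda_z == pytest.approx(0.1, rel=1e-9)


class TestAucLinlog:
    def test_constant_rectangle(self):
        p = make_profile([0, 1, 2, 4], [2, 2, 2, 2])
        assert auc_linlog(p, 0, 4) == pytest.approx(8.0, rel=1e-12)

    def test_exact_log_segment(self):
        p = make_profile([0, 1], [10, 5])
        assert auc_linlog(p, 0, 1) == pytest.approx(5.0 / math.log(2), rel=1e-12)

    def test_linear_fallback_at_zero_endpoint(self):
        p = make_profile([0, 1], [4, 0])
        assert auc_linlog(p, 0, 1) == pytest.approx(2.0, rel=1e-12)

    def test_additivity_at_observation_points(self):
        rng = np.random.default_rng(7)
        t = np.sort(rng.uniform(0, 24, 12))
        c = np.abs(rng.lognormal(0, 1, 12))
        p = make_profile(t, c)
        whole = auc_linlog(p, t[0], t[-1])
        split = auc_linlog(p, t[0], t[5]) + auc_linlog(p, t[5], t[-1])
        assert whole == pytest.approx(split, rel=1e-12)

    def test_outside_range_raises(self):
        p = make_profile([1, 2], [3, 2])
        with pytest.raises(ExtrapolationError):
            auc_linlog(p, 0, 2)

    def test_against_dense_grid_oracle_trial_schedule(self, default_params):
        """Lin-up/log-down on the 17-point schedule vs 0.001-h numerical integral."""
        events = [DoseEvent(0.0, "statin", 1e7)]
        sched = np.asarray(TRIAL_SAMPLING_TIMES)
        conc = simulate_concentrations(default_params, events, [], sched)
        p = make_profile(sched, conc)
        coarse = auc_linlog(p, 0.0, 49.0)
        dense_t = np.arange(0.0, 49.0005, 0.001)
        dense = float(np.trapezoid(
            simulate_concentrations(default_params, events, [], dense_t), dense_t
        ))
        assert abs(coarse - dense) / dense < 0.05

    def test_against_dense_grid_oracle_dense_sampling(self, default_params):
        events = [DoseEvent(0.0, "statin", 1e7)]
        t = np.arange(0.0, 49.01, 0.25)
        conc = simulate_concentrations(default_params, events, [], t)
        p = make_profile(t, conc)
        coarse = auc_linlog(p, 0.0, 49.0)
        dense_t = np.arange(0.0, 49.0005, 0.001)
        dense = float(np.trapezoid(
            simulate_concentrations(default_params, events, [], dense_t), dense_t
        ))
        assert abs(coarse - dense) / dense < 0.001


class TestNCASummary:
    def test_monoexponential_auc_inf_analytic(self):
        """AUC_inf of an exact mono-exponential equals C0/lambda."""
        t = np.arange(0.0, 72.5, 0.5)
        p = make_profile(t, 8.0 * np.exp(-0.1 * t))
        res = nca_summary(p)
        assert res.auc_inf == pytest.approx(80.0, rel=1e-6)
        assert res.lambda_z_fit.lambda_z == pytest.approx(0.1, rel=1e-9)

    def test_cmax_tmax_tie_to_earliest(self):
        p = make_profile([0, 1, 2, 3, 4], [0, 7, 7, 3, 1])
        res = nca_summary(p)
        assert res.cmax == 7 and res.tmax == 1

    def test_clearance_volume_identities(self, default_params):
        """CL/F = dose/AUC_inf (mL/min) and Vz/F = CL/lambda_z (L) by construction."""
        events = [DoseEvent(0.0, "statin", 1e7)]
        sched = np.asarray(TRIAL_SAMPLING_TIMES)
        conc = simulate_concentrations(default_params, events, [], sched)
        res = nca_summary(make_profile(sched, conc))
        assert res.cl_f == pytest.approx(1e7 / res.auc_inf / 60.0, rel=1e-12)
        assert res.vz_f == pytest.approx(
            res.cl_f * 60.0 / res.lambda_z_fit.lambda_z / 1000.0, rel=1e-12
        )
        assert res.auc_inf >= res.auc_last >= 0
        assert 0 <= res.auc_extrap_pct < 100

    def test_cl_f_recovered_within_5pct_of_truth(self, default_params):
        """NCA CL/F on the trial schedule vs the generating model's CL/F."""
        events = [DoseEvent(0.0, "statin", 1e7)]
        sched = np.asarray(TRIAL_SAMPLING_TIMES)
        conc = simulate_concentrations(default_params, events, [], sched)
        res = nca_summary(make_profile(sched, conc))
        cl_true_ml_min = default_params.cl_f_base * 1000.0 / 60.0
        assert abs(res.cl_f - cl_true_ml_min) / cl_true_ml_min < 0.05

    def test_zero_profile_rejected(self):
        with pytest.raises(EmptyProfileError):
            nca_summary(make_profile([0, 1, 2], [0, 0, 0]))

    def test_lambda_z_failure_flags_result(self):
        res = nca_summary(make_profile([0, 1, 2, 3], [0, 5, 5, 5]))
        assert res.auc_inf is None and res.cl_f is None
        assert res.flags

    def test_auc_tau_and_partial(self):
        p = make_profile([0, 1, 2, 3, 4], [0, 4, 2, 1, 0.5])
        res = nca_summary(p, tau=3, partial_intervals=((2.0, 4.0),))
        assert res.auc_tau == pytest.approx(auc_linlog(p, 0, 3), rel=1e-12)
        assert res.partial_aucs[(2.0, 4.0)] == pytest.approx(
            auc_linlog(p, 2, 4), rel=1e-12
        )


class TestDoseNormalizedAuc:
    def _result(self, auc, dose_ng):
        p = make_profile([0, 2, 3, 4, 6], [0, 10, 8, 5, 2], dose_ng=dose_ng)
        res = nca_summary(p, partial_intervals=((2.0, 4.0),))
        res.partial_aucs[(2.0, 4.0)] = auc  # pin the value for arithmetic checks
        return res

    def test_scaling_examples(self):
        res = self._result(30.0, 30e3)  # 30 ug dose in ng
        assert dose_normalized_auc(res, (2.0, 4.0), 1e3) == pytest.approx(1.0)
        res2 = self._result(10.0, 10e3)
        assert dose_normalized_auc(res2, (2.0, 4.0), 1e3) == pytest.approx(1.0)

    def test_doubling_dose_and_conc_invariant(self):
        p1 = make_profile([0, 2, 3, 4, 6], [0, 10, 8, 5, 2], dose_ng=1e4)
        p2 = make_profile([0, 2, 3, 4, 6], [0, 20, 16, 10, 4], dose_ng=2e4)
        r1 = nca_summary(p1, partial_intervals=((2.0, 4.0),))
        r2 = nca_summary(p2, partial_intervals=((2.0, 4.0),))
        assert dose_normalized_auc(r1, (2.0, 4.0), 1e3) == pytest.approx(
            dose_normalized_auc(r2, (2.0, 4.0), 1e3), rel=1e-12
        )

    def test_missing_interval_key_error(self):
        res = self._result(30.0, 30e3)
        with pytest.raises(KeyError):
            dose_normalized_auc(res, (0.0, 1.0), 1e3)


class TestTotalInhibitoryActivity:
    A = AnalyteSpec("a", 500.0, 0.1, 1.0)
    B = AnalyteSpec("b", 520.0, 0.1, 1.0)
    H = AnalyteSpec("h", 540.0, 0.1, 0.5)

    def test_equal_weights_sum(self):
        assert total_inhibitory_activity([(self.A, 10.0), (self.B, 10.0)]) == 20.0

    def test_half_weight(self):
        assert total_inhibitory_activity([(self.A, 10.0), (self.H, 10.0)]) == 15.0

    def test_empty_sum(self):
        assert total_inhibitory_activity([]) == 0.0

    def test_unit_error(self):
        with pytest.raises(UnitError):
            total_inhibitory_activity([(self.A, 10.0)], unit="ng/mL")
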