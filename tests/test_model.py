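"""Core competition model: vector field, equilibria, dose windows."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dosewindow import (
    PatientParameters, TumorState, classify_dynamics, effective_dose_window,
    equilibria, jacobian, k0_from_lower_bound, simulate, vector_field,
)
from dosewindow.calibration import model_mean


def params_with(r=0.02, K=1000.0, delta=0.025, c=3.0):
    return PatientParameters(r=r, K=K, delta=delta, c=c)


class TestParameterValidation:
    @pytest.mark.parametrize("bad", [
        dict(r=-0.1), dict(K=0.0), dict(delta=-1e-9), dict(c=1.0),
        dict(c=0.5),
    ])
    def test_rejects_nonpositive_or_subunit_c(self, bad):
        with pytest.raises(ValueError):
            params_with(**bad)

    def test_negative_state_rejected(self):
        with pytest.raises(ValueError):
            TumorState(-1.0, 5.0)


class TestVectorField:
    def test_trivial_and_r_only_states_are_stationary(self, fig2_params):
        for state in [(0.0, 0.0), (0.0, fig2_params.K)]:
            for u in (0.0, 0.3, 1.0):
                dS, dR = vector_field(state, fig2_params, u)
                assert dS == 0.0 and dR == 0.0

    def test_s_only_equilibrium_is_stationary_under_mtd(self):
        p = params_with(delta=0.015)  # delta < r needed for existence
        S_eq = p.K * (1.0 - p.delta / p.r)
        dS, dR = vector_field((S_eq, 0.0), p, 1.0)
        assert abs(dS) < 1e-9 * p.r * p.K
        assert dR == 0.0

    def test_negative_state_rejected(self, fig2_params):
        with pytest.raises(ValueError):
            vector_field((-1.0, 10.0), fig2_params, 1.0)

    def test_dose_outside_unit_interval_rejected(self, fig2_params):
        with pytest.raises(ValueError):
            vector_field((1.0, 1.0), fig2_params, 1.5)


class TestEquilibria:
    def test_coexistence_closed_form(self):
        # delta_eff = 0.01 with r=0.02, c=3, K=1000 puts the saddle
        # at (250, 250): delta*K/(r(c-1)) and cK/(c-1)*(1-delta/r-1/c)
        p = params_with(delta=0.01)
        eq = equilibria(p, 1.0)
        assert eq.coexistence.exists
        assert eq.coexistence.S == pytest.approx(250.0, abs=1e-9)
        assert eq.coexistence.R == pytest.approx(250.0, abs=1e-9)

    def test_no_coexistence_at_or_above_case_ii(self):
        for delta in (0.015, 0.02, 0.03):  # >= r(c-1)/c = 0.01333
            eq = equilibria(params_with(delta=delta), 1.0)
            assert not eq.coexistence.exists

    def test_untreated_s_only_at_carrying_capacity(self, fig2_params):
        eq = equilibria(fig2_params, 0.0)
        assert eq.s_only.S == pytest.approx(fig2_params.K)
        assert eq.s_only.R == 0.0
        assert eq.s_only.stability == "stable"

    def test_vector_field_vanishes_at_every_existing_equilibrium(self):
        for delta, u in [(0.01, 1.0), (0.015, 1.0), (0.025, 1.0),
                         (0.025, 0.4)]:
            p = params_with(delta=delta)
            eqs = equilibria(p, u)
            for eq in eqs:
                if not eq.exists:
                    continue
                dS, dR = vector_field((eq.S, eq.R), p, u)
                assert np.hypot(dS, dR) < 1e-9 * p.r * p.K

    @pytest.mark.parametrize("r,c,delta_eff", [
        (0.02, 3.0, 0.025),   # Case I
        (0.02, 3.0, 0.015),   # Case II
        (0.02, 3.0, 0.010),   # Case III
        (0.15, 1.8, 0.2),     # Case I, reference-like scale
        (0.15, 1.8, 0.1),     # Case II
        (0.15, 1.8, 0.05),    # Case III
        (0.1, 2.5, 0.055),    # Case II near boundary
    ])
    def test_stability_labels_match_jacobian_eigenvalues(self, r, c,
                                                         delta_eff):
        p = PatientParameters(r=r, K=750.0, delta=delta_eff, c=c)
        eqs = equilibria(p, 1.0)
        for eq in eqs:
            if eq.stability in ("nonexistent", "degenerate"):
                continue
            ev = np.linalg.eigvals(jacobian((eq.S, eq.R), p, 1.0))
            numerically_stable = np.all(ev.real < 0)
            assert numerically_stable == (eq.stability == "stable"), \
                f"label {eq.stability} vs eigenvalues {ev} at ({eq.S},{eq.R})"


class TestClassifyDynamics:
    @pytest.mark.parametrize("delta_eff,label", [
        (0.025, "I"), (0.015, "II"), (0.010, "III"),
    ])
    def test_strict_inequality_cases(self, delta_eff, label):
        p = params_with(delta=delta_eff)
        assert classify_dynamics(p, 1.0).label == label

    def test_boundary_equalities_flagged_degenerate(self):
        r, c = 0.02, 3.0
        for delta in (r, r * (c - 1) / c):
            p = PatientParameters(r=r, K=1000.0, delta=delta, c=c)
            assert classify_dynamics(p, 1.0).label == "degenerate"

    def test_zero_dose_is_untreated(self, fig2_params):
        case = classify_dynamics(fig2_params, 0.0)
        assert case.label == "untreated"
        assert case.effective_delta == 0.0


class TestEffectiveDoseWindow:
    def test_reference_upper_bounds_to_4dp(self, records):
        expected = {2: 0.0743, 6: 0.1245, 7: 0.1055, 8: 0.0701}
        for pid, upper in expected.items():
            rec = records[pid]
            w = effective_dose_window(rec.params, rec.k0)
            assert round(w.upper, 4) == upper

    def test_emptiness_flips_at_k_over_c(self, fig2_params):
        p = fig2_params
        boundary = p.K / p.c
        assert not effective_dose_window(p, boundary * (1 - 1e-6)).nonempty
        assert effective_dose_window(p, boundary * (1 + 1e-6)).nonempty

    def test_window_empty_exactly_at_boundary(self, fig2_params):
        w = effective_dose_window(fig2_params, fig2_params.K / fig2_params.c)
        assert w.lower == pytest.approx(w.upper)
        assert not w.nonempty

    def test_k_tol_at_or_above_capacity_rejected(self, fig2_params):
        with pytest.raises(ValueError):
            effective_dose_window(fig2_params, fig2_params.K)

    def test_normalized_bounds_clamped_to_unit_interval(self, records):
        for rec in records.values():
            w = rec.edw()
            assert 0.0 <= w.lower_norm <= w.upper_norm <= 1.0


class TestK0Inversion:
    def test_round_trips_the_lower_bound(self, records):
        for rec in records.values():
            k0 = k0_from_lower_bound(rec.params, rec.printed_lower)
            recomputed = rec.params.r * (1.0 - k0 / rec.params.K)
            assert round(recomputed, 4) == round(rec.printed_lower, 4)

    def test_zero_lower_bound_gives_capacity(self, fig2_params):
        assert k0_from_lower_bound(fig2_params, 0.0) == fig2_params.K

    def test_lower_bound_at_growth_rate_rejected(self, fig2_params):
        with pytest.raises(ValueError):
            k0_from_lower_bound(fig2_params, fig2_params.r)


class TestSimulate:
    def test_untreated_single_species_logistic_growth(self, fig2_params):
        p = fig2_params
        traj = simulate(p, 0.0, (p.K / 2, 0.0), 600.0)
        assert np.all(np.diff(traj.S) >= -1e-9 * p.K)  # monotone approach
        assert traj.S[-1] == pytest.approx(p.K, rel=1e-3)
        assert np.all(traj.R == 0.0)

    def test_mtd_relapse_is_resistant_dominated(self, patient2):
        p = patient2.params
        k0 = patient2.k0
        traj = simulate(p, 1.0, (0.99 * k0, 0.01 * k0), 400.0)
        total = traj.total
        imin = int(np.argmin(total))
        assert 0 < imin < len(total) - 1          # interior nadir
        assert total[-1] > k0                     # relapse past baseline
        assert traj.R[-1] / total[-1] > 0.99      # resistant takeover

    def test_subwindow_dose_steers_to_sensitive_only(self, patient2):
        # 70% of MTD lies inside the patient's window at k_tol = K_0
        p = patient2.params
        k0 = patient2.k0
        traj = simulate(p, 0.7, (0.99 * k0, 0.01 * k0), 4000.0)
        s_eq = p.K * (1.0 - 0.7 * p.delta / p.r)
        assert traj.S[-1] == pytest.approx(s_eq, rel=1e-3)
        assert traj.R[-1] < 1e-6 * p.K

    def test_matches_fixed_step_kernel(self, patient2):
        # adaptive RK45 path vs the compiled fixed-step RK4 used in the
        # likelihood/sweep hot loops
        p = patient2.params
        k0 = patient2.k0
        times = np.linspace(0.0, 300.0, 61)
        y_fast = model_mean(p, times, (0.99 * k0, 0.01 * k0))
        traj = simulate(p, 1.0, (0.99 * k0, 0.01 * k0), 300.0,
                        t_eval=times)
        assert np.allclose(traj.total, y_fast, rtol=1e-5)

    def test_nonpositive_horizon_rejected(self, fig2_params):
        with pytest.raises(ValueError):
            simulate(fig2_params, 0.5, (10.0, 10.0), 0.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(s0=st.floats(0.0, 1.0), r0=st.floats(0.0, 1.0),
           u=st.floats(0.0, 1.0))
    def test_forward_invariance_of_nonnegative_orthant(self, s0, r0, u):
        p = params_with(r=0.1, K=500.0, delta=0.08, c=2.0)
        traj = simulate(p, u, (s0 * p.K, r0 * p.K), 200.0,
                        t_eval=np.linspace(0, 200, 101))
        assert traj.S.min() >= -1e-9 * p.K
        assert traj.R.min() >= -1e-9 * p.K
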