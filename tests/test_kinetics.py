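"""1:1 Langmuir model, global fitting, steady-state analysis and QC flags."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from sprscreen.exceptions import ValidationError
from sprscreen.io import load_panel_kinetics
from sprscreen.kinetics import (FitOptions, association_response, compute_kd,
                                cycle_model, dissociation_response,
                                fit_kinetics_global, fit_steady_state,
                                format_scientific, qc_flags,
                                steady_state_response, theoretical_rmax)
from sprscreen.pipeline import screen_cycle_set
from sprscreen.synthetic import SyntheticSpec, generate_cycle_set

CONTROL_KON, CONTROL_KOFF, CONTROL_RMAX = 1.099e5, 0.4947, 200.0


def ode_association(t, C, k_on, k_off, R_max, rtol=1e-12):
    """Independent numerical oracle for the association-phase response."""
    sol = solve_ivp(lambda _t, r: [k_on * C * (R_max - r[0]) - k_off * r[0]],
                    (0.0, t), [0.0], rtol=rtol, atol=1e-12, dense_output=True)
    return float(sol.sol(t)[0])


class TestClosedForms:
    def test_association_matches_ode_for_control_rates(self):
        closed = association_response(60.0, 1e-6, CONTROL_KON, CONTROL_KOFF,
                                      CONTROL_RMAX)
        numeric = ode_association(60.0, 1e-6, CONTROL_KON, CONTROL_KOFF,
                                  CONTROL_RMAX)
        assert abs(closed - numeric) < 1e-6

    @pytest.mark.parametrize("k_on", [1e3, 1e5, 1e7])
    @pytest.mark.parametrize("k_off", [1e-3, 0.05, 0.5])
    @pytest.mark.parametrize("C", [4e-7, 1e-5, 3e-4])
    def test_association_matches_ode_on_log_grid(self, k_on, k_off, C):
        closed = association_response(120.0, C, k_on, k_off, 180.0)
        numeric = ode_association(120.0, C, k_on, k_off, 180.0)
        assert abs(closed - numeric) < 1e-6

    def test_half_saturation_at_kd(self):
        kd = CONTROL_KOFF / CONTROL_KON
        r = association_response(1e6, kd, CONTROL_KON, CONTROL_KOFF, 200.0)
        assert r == pytest.approx(100.0, rel=1e-9)

    def test_zero_concentration_is_flat(self):
        t = np.linspace(0, 300, 50)
        assert np.all(association_response(t, 0.0, 1e5, 0.5, 200.0) == 0.0)

    def test_dissociation_initial_value_and_half_life(self):
        assert dissociation_response(0.0, 42.0, 0.1) == 42.0
        assert dissociation_response(math.log(2) / 0.1, 42.0, 0.1) == \
            pytest.approx(21.0, rel=1e-12)

    def test_piecewise_trace_continuous_at_phase_boundary(self):
        r_end = association_response(180.0, 1e-5, 1e5, 0.5, 200.0)
        assert dissociation_response(0.0, float(r_end), 0.5) == \
            pytest.approx(float(r_end), rel=1e-12)

    def test_steady_state_equals_association_limit(self):
        C, kd, rmax = 3e-6, 4.5e-6, 180.0
        limit = association_response(1e7, C, 0.5 / kd, 0.5, rmax)
        assert steady_state_response(C, kd, rmax) == pytest.approx(limit, rel=1e-12)

    def test_steady_state_monotone_and_bounded(self):
        C = np.geomspace(0.4e-6, 300e-6, 50)
        r = steady_state_response(C, 4.5e-6, 200.0)
        assert np.all(np.diff(r) > 0)
        assert np.all(r < 200.0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            association_response(-1.0, 1e-6, 1e5, 0.5, 200.0)
        with pytest.raises(ValueError):
            steady_state_response(1e-6, 0.0, 200.0)
        with pytest.raises(ValueError):
            dissociation_response(-1.0, 10.0, 0.1)


class TestComputeKd:
    def test_published_control_and_panel_rates(self):
        assert compute_kd(1.099e5, 0.4947) == pytest.approx(4.500e-6, rel=1e-3)
        assert compute_kd(1.922e4, 0.01998) == pytest.approx(1.039e-6, rel=1e-3)

    def test_every_published_row_is_internally_consistent(self):
        tbl = load_panel_kinetics()
        binders = tbl[tbl.KD_M != "n.d."]
        assert len(binders) == 15  # 2 controls + 13 binding cannabinoids
        for row in binders.itertuples():
            kd = compute_kd(float(row.k_on_1_per_Ms), float(row.k_off_1_per_s))
            assert kd == pytest.approx(float(row.KD_M), rel=1e-3), row.compound

    def test_irreversible_limit(self):
        assert compute_kd(1e5, 0.0) == 0.0
        with pytest.raises(ValueError):
            compute_kd(0.0, 0.1)


class TestGlobalFit:
    def test_noise_free_recovery_is_exact(self, noise_free_cycle_set):
        p = screen_cycle_set(noise_free_cycle_set)
        assert abs(p.k_on - 1e5) / 1e5 < 1e-6
        assert abs(p.k_off - 0.5) / 0.5 < 1e-6
        assert abs(p.R_max - 200.0) / 200.0 < 1e-6
        assert p.K_D == pytest.approx(p.k_off / p.k_on, rel=1e-9)

    def test_noisy_recovery_within_5pct(self):
        errs_on, errs_off = [], []
        for seed in range(5):
            cs = generate_cycle_set(SyntheticSpec(noise_sd=0.5, seed=100 + seed))
            p = screen_cycle_set(cs)
            errs_on.append(abs(p.k_on - 1e5) / 1e5)
            errs_off.append(abs(p.k_off - 0.5) / 0.5)
        assert np.median(errs_on) < 0.05
        assert np.median(errs_off) < 0.05

    def test_flat_responses_not_detectable(self):
        cs = generate_cycle_set(SyntheticSpec(R_max=1e-9, noise_sd=0.0, seed=0))
        p = fit_kinetics_global(cs)
        assert "not_detectable" in p.flags
        assert math.isnan(p.k_on)

    def test_pure_noise_not_detectable(self):
        cs = generate_cycle_set(SyntheticSpec(R_max=1e-9, noise_sd=0.5, seed=3))
        p = screen_cycle_set(cs)
        assert "not_detectable" in p.flags

    def test_single_concentration_not_detectable(self, noise_free_cycle_set):
        cs = noise_free_cycle_set
        cs.cycles = cs.cycles[:1]
        cs.reference_cycles = cs.reference_cycles[:1]
        p = fit_kinetics_global(cs)
        assert "not_detectable" in p.flags


class TestSteadyStateFit:
    def test_exact_isotherm_recovered(self):
        C = np.geomspace(0.4e-6, 300e-6, 8)
        req = steady_state_response(C, 1e-5, 180.0)
        fit = fit_steady_state(C, req)
        assert fit.K_D == pytest.approx(1e-5, rel=1e-9)
        assert fit.R_max == pytest.approx(180.0, rel=1e-9)
        assert fit.saturation_reached

    def test_noisy_isotherm_within_10pct(self, rng):
        C = np.geomspace(0.4e-6, 300e-6, 8)
        errs = []
        for _ in range(20):
            req = steady_state_response(C, 1e-5, 180.0)
            noisy = req * (1 + rng.normal(0, 0.02, len(C)))
            errs.append(abs(fit_steady_state(C, noisy).K_D - 1e-5) / 1e-5)
        assert np.median(errs) < 0.10

    def test_two_concentrations_rejected(self):
        with pytest.raises(ValidationError):
            fit_steady_state([1e-6, 1e-5], [10.0, 50.0])


class TestTheoreticalRmax:
    def test_identity_case(self):
        assert theoretical_rmax(300.0, 300.0, 17000.0) == 17000.0

    def test_homogeneity_in_immobilized(self):
        assert theoretical_rmax(314.5, 3e4, 18000.0) == \
            pytest.approx(2 * theoretical_rmax(314.5, 3e4, 9000.0))

    def test_cannabinoid_mws_consistent_with_published_span(self):
        """A single ligand-MW choice maps the cannabinoid MW range
        (~286-330 g/mol) and 16-18 kRU immobilization onto the published
        158-205 RU theoretical span."""
        implied = [mw * ru / rmax
                   for mw, ru, rmax in [(286.0, 16000.0, 158.0),
                                        (330.0, 18000.0, 205.0)]]
        lo, hi = max(286.0 * 16000.0 / 205.0, 0), min(330.0 * 18000.0 / 158.0, 1e9)
        mw_ligand = float(np.mean(implied))
        assert lo <= mw_ligand <= hi
        rmaxes = [theoretical_rmax(mw, mw_ligand, ru)
                  for mw in (286.0, 330.0) for ru in (16000.0, 18000.0)]
        assert min(rmaxes) > 100.0 and max(rmaxes) < 260.0

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            theoretical_rmax(0.0, 300.0, 17000.0)


class TestQcFlags:
    def test_matrix_binding_above_theoretical_rmax(self, noise_free_cycle_set):
        p = screen_cycle_set(noise_free_cycle_set)
        max_obs = max(float(s.responses.max()) for s in noise_free_cycle_set.cycles)
        flags = qc_flags(p, noise_free_cycle_set, rmax_theoretical=max_obs / 1.2)
        assert "matrix_binding" in flags
        flags = qc_flags(p, noise_free_cycle_set, rmax_theoretical=max_obs * 1.2)
        assert "matrix_binding" not in flags

    def test_slow_dissociation_from_closed_form_retention(self):
        # k_off = 1e-4 /s over 420 s retains exp(-0.042) = 96 % of the peak
        cs = generate_cycle_set(SyntheticSpec(k_on=1e3, k_off=1e-4, R_max=200.0,
                                              noise_sd=0.0, seed=0))
        p = fit_kinetics_global(cs, FitOptions(koff_bounds=(1e-6, 1.0)))
        flags = qc_flags(p, cs)
        assert "slow_dissociation" in flags

    def test_fast_dissociation_not_flagged(self, noise_free_cycle_set):
        p = screen_cycle_set(noise_free_cycle_set)
        assert "slow_dissociation" not in qc_flags(p, noise_free_cycle_set)


def test_format_scientific_matches_report_style():
    assert format_scientific(1.099e5) == "1.099E+5"
    assert format_scientific(4.5e-6) == "4.500E-6"
    assert format_scientific(float("nan")) == "n.d."
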