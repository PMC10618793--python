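"""Double referencing and DMSO solvent correction."""

import numpy as np
import pytest

from sprscreen.exceptions import ConfigurationError, ValidationError
from sprscreen.io import Sensorgram
from sprscreen.preprocess import (apply_solvent_correction, double_reference,
                                  fit_solvent_correction, plateau_response,
                                  report_point_response, subtract_blank,
                                  subtract_reference)
from sprscreen.synthetic import (SyntheticSpec, generate_cycle_set,
                                 generate_solvent_correction_cycles)


def _trace(responses, cycle_id="c", conc=1e-6):
    t = np.arange(len(responses), dtype=float)
    return Sensorgram(cycle_id, "active", "X", conc, t, responses,
                      t_assoc_start=0.0, t_assoc_end=t[-1] * 0.5,
                      t_diss_end=t[-1])


class TestReferenceSubtraction:
    def test_identical_traces_cancel(self):
        s = _trace(np.linspace(0, 10, 20))
        out = subtract_reference(s, s)
        assert np.allclose(out.responses, 0.0)

    def test_zero_reference_is_identity(self):
        s = _trace(np.linspace(0, 10, 20))
        z = s.with_responses(np.zeros(20))
        assert np.array_equal(subtract_reference(s, z).responses, s.responses)

    def test_mismatched_grids_rejected(self):
        s = _trace(np.zeros(20))
        r = _trace(np.zeros(21))
        with pytest.raises(ValidationError):
            subtract_reference(s, r)

    def test_shared_bulk_offset_removed(self, rng):
        ideal = np.linspace(0, 50, 100)
        noise_sd = 0.3
        active = _trace(ideal + 20.0 + rng.normal(0, noise_sd, 100))
        ref = active.with_responses(20.0 + rng.normal(0, noise_sd, 100))
        out = subtract_reference(active, ref)
        resid = out.responses - ideal
        assert abs(resid.mean()) < noise_sd

    def test_linearity(self, rng):
        a = _trace(rng.normal(size=30))
        b = rng.normal(size=30)
        r = a.with_responses(rng.normal(size=30))
        lhs = subtract_reference(a.with_responses(a.responses + b), r).responses
        rhs = subtract_reference(a, r).responses + b
        assert np.allclose(lhs, rhs)


class TestBlankSubtraction:
    def test_identical_blank_gives_zero(self):
        s = _trace(np.linspace(0, 5, 10))
        out = subtract_blank(s, [s.with_responses(s.responses.copy())])
        assert np.allclose(out.responses, 0.0)

    def test_opposite_blanks_cancel(self, rng):
        s = _trace(rng.normal(size=10))
        b = rng.normal(size=10)
        out = subtract_blank(s, [s.with_responses(b), s.with_responses(-b)])
        assert np.allclose(out.responses, s.responses)

    def test_blank_drift_removed(self):
        t = np.arange(100, dtype=float)
        slope = 0.05
        s = _trace(3.0 + slope * t)
        blank = s.with_responses(slope * t)
        out = subtract_blank(s, [blank])
        fitted_slope = np.polyfit(t, out.responses, 1)[0]
        assert abs(fitted_slope) < 1e-12

    def test_empty_blank_list_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            subtract_blank(_trace(np.zeros(10)), [])


class TestSolventCorrection:
    def test_exact_line_recovered(self):
        pairs = generate_solvent_correction_cycles([0.08, -2.0])
        curve = fit_solvent_correction(pairs, degree=2)
        quad, lin, const = curve.coefficients
        assert abs(quad) < 1e-9
        assert lin == pytest.approx(0.08, abs=1e-9)
        assert const == pytest.approx(-2.0, abs=1e-9)

    def test_noisy_quadratic_recovered(self):
        true = [2e-4, 0.05, -1.0]
        pairs = generate_solvent_correction_cycles(true, noise_sd=0.2, seed=4)
        curve = fit_solvent_correction(pairs, degree=2)
        # plateau medians average ~12 samples; coefficient error stays small
        ref = curve.reference_points
        pred = np.polyval(curve.coefficients, ref)
        truth = np.polyval(true, ref)
        assert np.max(np.abs(pred - truth)) < 3 * 0.2

    def test_seven_points_rejected(self):
        pairs = generate_solvent_correction_cycles([0.1, 0.0], n_points=7)
        with pytest.raises(ConfigurationError):
            fit_solvent_correction(pairs)

    def test_zero_curve_leaves_sample_unchanged(self):
        pairs = generate_solvent_correction_cycles([0.0, 0.0])
        curve = fit_solvent_correction(pairs)
        s = _trace(np.linspace(0, 5, 10))
        out = apply_solvent_correction(s, curve, curve, reference_bulk_ru=80.0)
        assert np.allclose(out.responses, s.responses, atol=1e-9)

    def test_midpoint_between_constant_curves(self):
        c1 = fit_solvent_correction(
            generate_solvent_correction_cycles([0.0, 2.0]), acquired_at_cycle=0)
        c2 = fit_solvent_correction(
            generate_solvent_correction_cycles([0.0, 6.0]), acquired_at_cycle=30)
        s = _trace(np.full(10, 10.0))
        out = apply_solvent_correction(s, c1, c2, reference_bulk_ru=80.0,
                                       cycle_index=15)
        assert np.allclose(out.responses, 10.0 - 4.0, atol=1e-9)

    def test_out_of_range_evaluation_flagged(self):
        curve = fit_solvent_correction(
            generate_solvent_correction_cycles([0.1, 0.0], bulk_range=(40, 120)))
        s = _trace(np.zeros(10))
        out = apply_solvent_correction(s, curve, curve, reference_bulk_ru=500.0)
        assert out.meta["solvent_correction_extrapolated"]

    def test_dmso_mismatch_corrected_within_2pct(self):
        """A sample whose active cell carries an uncorrected DMSO excluded-
        volume mismatch recovers its mismatch-free plateau after correction."""
        coeffs = [0.05, -1.5]
        curve = fit_solvent_correction(
            generate_solvent_correction_cycles(coeffs))
        bulk = 75.0
        mismatch = float(np.polyval(coeffs, bulk))
        ideal = np.linspace(0, 40, 200)
        contaminated = _trace(ideal + mismatch)
        corrected = apply_solvent_correction(contaminated, curve, curve,
                                             reference_bulk_ru=bulk)
        req_corrected = plateau_response(corrected)
        req_ideal = plateau_response(_trace(ideal))
        assert req_corrected == pytest.approx(req_ideal, rel=0.02)


def test_report_point_reads_sample_near_injection_end():
    t = np.arange(200, dtype=float)
    s = Sensorgram("c", "active", "X", 1e-6, t, t.copy(),
                   t_assoc_start=0.0, t_assoc_end=180.0, t_diss_end=199.0)
    assert report_point_response(s, offset=5.0) == 175.0
    with pytest.raises(ValidationError):
        report_point_response(s, offset=500.0)


def test_full_double_referencing_recovers_ideal_curve():
    """Noise-free data with drift and bulk artifacts reduce exactly to the
    ideal binding curves after reference + blank subtraction."""
    spec = SyntheticSpec(noise_sd=0.0, drift=0.02, bulk_shift=15.0, seed=0)
    cs = generate_cycle_set(spec)
    clean = generate_cycle_set(SyntheticSpec(noise_sd=0.0, seed=0))
    out = double_reference(cs)
    for got, ideal in zip(out.cycles, clean.cycles):
        assert np.max(np.abs(got.responses - ideal.responses)) < 1e-9
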