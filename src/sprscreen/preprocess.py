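"""Double referencing and DMSO solvent correction of sensorgrams.

The processing chain mirrors standard Biacore practice:

1. subtract the reference flow cell (removes bulk refractive-index jumps
   and baseline drift common to both cells),
2. apply the DMSO solvent correction (removes the residual excluded-volume
   mismatch between sample and running buffer),
3. subtract the mean of the zero-concentration blank cycles, themselves
   processed identically (removes systematic per-cycle disturbances).

Solvent correction is calibrated from dedicated DMSO-only cycles spanning
2.5-3.8 % DMSO, run periodically; the correction applied to a sample cycle
is interpolated linearly (in cycle index) between the calibration sets that
bracket it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, FitError, ValidationError
from .io import CycleSet, Sensorgram

N_CORRECTION_POINTS = 8


def plateau_response(s: Sensorgram, fraction: float = 0.2) -> float:
    """Median response over the final ``fraction`` of the association window.

    Used both as the steady-state read-out of a cycle and as the plateau of
    a DMSO calibration cycle; the median makes it robust to sampling noise.
    """
    mask = s.association_mask()
    t = s.times[mask]
    if len(t) == 0:
        raise ValidationError(f"cycle {s.cycle_id!r}: empty association window")
    t_cut = s.t_assoc_end - fraction * (s.t_assoc_end - s.t_assoc_start)
    tail = s.responses[mask][t >= t_cut]
    if len(tail) == 0:
        tail = s.responses[mask][-1:]
    return float(np.median(tail))


def report_point_response(s: Sensorgram, offset: float = 5.0) -> float:
    """Single-sample RU read at a report point ``offset`` s before the end
    of the association phase (the conventional late-binding report point)."""
    t_report = s.t_assoc_end - offset
    if t_report < s.t_assoc_start:
        raise ValidationError(
            f"cycle {s.cycle_id!r}: report point precedes association start"
        )
    idx = int(np.argmin(np.abs(s.times - t_report)))
    return float(s.responses[idx])


def subtract_reference(active: Sensorgram, reference: Sensorgram) -> Sensorgram:
    """Pointwise active − reference; metadata copied from the active cycle."""
    if not active.same_grid(reference):
        raise ValidationError(
            f"cycle {active.cycle_id!r}: active and reference time grids differ"
        )
    return active.with_responses(active.responses - reference.responses)


def subtract_blank(sample: Sensorgram, blanks) -> Sensorgram:
    """Subtract the pointwise mean of the blank (zero-concentration) cycles."""
    blanks = list(blanks)
    if not blanks:
        raise ConfigurationError("blank subtraction requires at least one blank cycle")
    for b in blanks:
        if not sample.same_grid(b):
            raise ValidationError(
                f"cycle {sample.cycle_id!r}: blank {b.cycle_id!r} is on a "
                "different time grid"
            )
    mean_blank = np.mean([b.responses for b in blanks], axis=0)
    return sample.with_responses(sample.responses - mean_blank)


@dataclass
class SolventCorrectionCurve:
    """Fitted DMSO correction-vs-reference-response calibration curve.

    ``coefficients`` are polynomial coefficients in :func:`numpy.polyval`
    order (highest degree first) mapping the reference-cell bulk response
    (RU) to the correction (RU) to subtract from a reference-subtracted
    sample response.
    """

    reference_points: np.ndarray   # reference-cell plateau responses (RU)
    corrections: np.ndarray        # active − reference plateau responses (RU)
    coefficients: np.ndarray
    valid_range: tuple
    acquired_at_cycle: int = 0

    def __call__(self, reference_ru: float) -> tuple:
        """Evaluate the curve; returns (correction_RU, extrapolated_flag)."""
        lo, hi = self.valid_range
        value = float(np.polyval(self.coefficients, reference_ru))
        if not np.isfinite(value):
            raise FitError("solvent correction curve evaluated to a non-finite value")
        return value, bool(reference_ru < lo or reference_ru > hi)


def fit_solvent_correction(correction_cycles, degree: int = 2,
                           plateau_fraction: float = 0.2,
                           acquired_at_cycle: int = 0) -> SolventCorrectionCurve:
    """Fit a correction curve from DMSO-only calibration cycle pairs.

    Parameters
    ----------
    correction_cycles : sequence of (reference, active) Sensorgram pairs
        The eight DMSO-only calibration cycles spanning the 2.5-3.8 % DMSO
        design.  For each pair the plateau of the reference cycle gives the
        abscissa and (active − reference) plateau the ordinate.
    degree : int
        Polynomial degree of the correction curve (quadratic by default).
    """
    pairs = list(correction_cycles)
    if len(pairs) < N_CORRECTION_POINTS:
        raise ConfigurationError(
            f"solvent correction requires {N_CORRECTION_POINTS} calibration "
            f"cycles, got {len(pairs)}"
        )
    ref = np.array([plateau_response(r, plateau_fraction) for r, _ in pairs])
    act = np.array([plateau_response(a, plateau_fraction) for _, a in pairs])
    if np.ptp(ref) == 0:
        raise FitError("degenerate solvent calibration: all reference plateaus equal")
    coeffs = np.polyfit(ref, act - ref, deg=degree)
    return SolventCorrectionCurve(
        reference_points=ref,
        corrections=act - ref,
        coefficients=coeffs,
        valid_range=(float(ref.min()), float(ref.max())),
        acquired_at_cycle=acquired_at_cycle,
    )


def apply_solvent_correction(s: Sensorgram, before: SolventCorrectionCurve,
                             after: SolventCorrectionCurve,
                             reference_bulk_ru: float,
                             cycle_index: int | None = None) -> Sensorgram:
    """Subtract the interpolated DMSO correction from a reference-subtracted cycle.

    The correction is evaluated on both bracketing calibration curves at the
    cycle's reference-cell bulk response and interpolated linearly in cycle
    index between them.  If the curves carry no ordering information (equal
    acquisition indices) the two are averaged.  Out-of-range evaluation sets
    ``meta["solvent_correction_extrapolated"]`` on the result.
    """
    if before is None or after is None:
        raise ConfigurationError("solvent correction requires bracketing curves")
    c_before, ex_b = before(reference_bulk_ru)
    c_after, ex_a = after(reference_bulk_ru)
    span = after.acquired_at_cycle - before.acquired_at_cycle
    if cycle_index is None or span <= 0:
        w = 0.5
    else:
        w = (cycle_index - before.acquired_at_cycle) / span
        w = float(np.clip(w, 0.0, 1.0))
    correction = (1.0 - w) * c_before + w * c_after
    out = s.with_responses(s.responses - correction)
    out.meta["solvent_correction_RU"] = correction
    out.meta["solvent_correction_extrapolated"] = bool(ex_b or ex_a)
    return out


def double_reference(cs: CycleSet, before: SolventCorrectionCurve | None = None,
                     after: SolventCorrectionCurve | None = None,
                     plateau_fraction: float = 0.2) -> CycleSet:
    """Full preprocessing of a cycle set: reference → solvent → blank.

    Blanks are processed identically to samples before being averaged and
    subtracted.  Solvent correction is skipped when no calibration curves
    are supplied (e.g. synthetic runs without DMSO mismatch).
    """
    def _process(cycle, reference, idx):
        out = subtract_reference(cycle, reference)
        if before is not None and after is not None:
            bulk = plateau_response(reference, plateau_fraction)
            out = apply_solvent_correction(out, before, after, bulk, idx)
        return out

    samples = [_process(c, r, i)
               for i, (c, r) in enumerate(zip(cs.cycles, cs.reference_cycles))]
    blanks = [_process(b, r, i)
              for i, (b, r) in enumerate(zip(cs.blank_cycles,
                                             cs.blank_reference_cycles))]
    if blanks:
        samples = [subtract_blank(s, blanks) for s in samples]
    return CycleSet(
        analyte_id=cs.analyte_id,
        cycles=samples,
        reference_cycles=[],
        blank_cycles=blanks,
        blank_reference_cycles=[],
    )
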