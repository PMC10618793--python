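"""1:1 Langmuir interaction model and global kinetic fitting.

The surface reaction A + L <-> AL at analyte concentration C obeys

    dR/dt = k_on * C * (R_max - R) - k_off * R ,   R(0) = 0 ,

whose association-phase solution is ``Req * (1 - exp(-(k_on*C + k_off)*t))``
with the steady state ``Req = C * R_max / (C + K_D)`` and ``K_D =
k_off / k_on``.  The dissociation phase decays as ``R0 * exp(-k_off * t)``.

:func:`fit_kinetics_global` fits one (k_on, k_off, R_max) triple jointly to
a full concentration series, in log-parameter space with bounds, and
attaches the QC flags used to report a screen: ``not_detectable``,
``matrix_binding``, ``slow_dissociation`` and ``at_bound``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .exceptions import FitError, ValidationError
from .io import CycleSet, Sensorgram
from .preprocess import plateau_response

KON_BOUNDS = (1e2, 1e9)      # 1/(M s)
KOFF_BOUNDS = (1e-5, 1.0)    # 1/s


def _require_positive(**kwargs):
    for name, value in kwargs.items():
        if value <= 0:
            raise ValueError(f"{name} must be positive, got {value}")


def _require_nonnegative(**kwargs):
    for name, value in kwargs.items():
        if value < 0:
            raise ValueError(f"{name} must be non-negative, got {value}")


def association_response(t, C, k_on, k_off, R_max):
    """Closed-form association-phase response of the 1:1 model (RU).

    Equals the analytic solution of ``dR/dt = k_on*C*(R_max − R) − k_off*R``
    with ``R(0) = 0``.
    """
    _require_positive(k_on=k_on, k_off=k_off, R_max=R_max)
    _require_nonnegative(C=C)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    k_obs = k_on * C + k_off
    req = k_on * C * R_max / k_obs
    return req * (1.0 - np.exp(-k_obs * t))


def dissociation_response(t, R0, k_off):
    """Dissociation-phase decay ``R0 * exp(-k_off * t)`` (RU)."""
    _require_positive(k_off=k_off)
    _require_nonnegative(R0=R0)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    return R0 * np.exp(-k_off * t)


def steady_state_response(C, K_D, R_max):
    """Equilibrium response ``C * R_max / (C + K_D)`` (RU)."""
    if K_D <= 0:
        raise ValueError(f"K_D must be positive, got {K_D}")
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("C must be non-negative")
    return C * R_max / (C + K_D)


def compute_kd(k_on: float, k_off: float) -> float:
    """Equilibrium dissociation constant ``K_D = k_off / k_on`` (M)."""
    if k_on <= 0:
        raise ValueError(f"k_on must be positive, got {k_on}")
    if k_off < 0:
        raise ValueError(f"k_off must be non-negative, got {k_off}")
    return k_off / k_on


def cycle_model(s: Sensorgram, C: float, k_on: float, k_off: float,
                R_max: float) -> np.ndarray:
    """Piecewise 1:1 model evaluated on a cycle's time grid.

    Baseline samples are zero; association runs from ``t_assoc_start`` and
    dissociation decays from the response reached at ``t_assoc_end``.
    """
    out = np.zeros(s.n_points)
    am = s.association_mask()
    dm = s.dissociation_mask()
    out[am] = association_response(s.times[am] - s.t_assoc_start, C,
                                  k_on, k_off, R_max)
    r_end = association_response(s.t_assoc_end - s.t_assoc_start, C,
                                 k_on, k_off, R_max)
    out[dm] = dissociation_response(s.times[dm] - s.t_assoc_end, float(r_end),
                                    k_off)
    return out


def theoretical_rmax(mw_analyte: float, mw_ligand: float,
                     immobilized: float, stoichiometry: float = 1.0) -> float:
    """Theoretical saturation response (RU).

    ``(MW_analyte / MW_ligand) * immobilized_RU * stoichiometry`` — the
    standard mass-ratio scaling of the immobilization level.
    """
    _require_positive(mw_analyte=mw_analyte, mw_ligand=mw_ligand,
                      immobilized=immobilized, stoichiometry=stoichiometry)
    return mw_analyte / mw_ligand * immobilized * stoichiometry


def estimate_noise_sd(s: Sensorgram) -> float:
    """Short-term noise sd estimated from first differences of the trace.

    For a smooth signal plus i.i.d. Gaussian noise, successive differences
    have variance ``2 * sd**2``; the median absolute deviation makes the
    estimate robust to the phase-boundary jumps.
    """
    d = np.diff(s.responses)
    if len(d) == 0:
        return 0.0
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / math.sqrt(2.0))


@dataclass
class KineticParameters:
    """Fitted 1:1 binding parameters for one analyte (one screen-report row)."""

    k_on: float = math.nan         # 1/(M s)
    k_off: float = math.nan        # 1/s
    K_D: float = math.nan          # M
    R_max: float = math.nan        # RU
    ssr: float = math.nan          # RU^2
    se_k_on: float = math.nan
    se_k_off: float = math.nan
    flags: frozenset = frozenset()
    n_cycles_used: int = 0

    @property
    def is_detectable(self) -> bool:
        return "not_detectable" not in self.flags

    def __post_init__(self) -> None:
        if self.is_detectable:
            if not (self.k_on > 0 and self.k_off > 0 and self.R_max > 0):
                raise ValidationError(
                    "detectable kinetic parameters require positive rates and R_max"
                )
            if not math.isclose(self.K_D, self.k_off / self.k_on, rel_tol=1e-9):
                raise ValidationError("K_D inconsistent with k_off / k_on")


@dataclass
class FitOptions:
    """Tuning knobs for the global kinetic fit."""

    kon_bounds: tuple = KON_BOUNDS
    koff_bounds: tuple = KOFF_BOUNDS
    rmax_max_factor: float = 10.0     # upper R_max bound = factor x theoretical
    rmax_theoretical: float | None = None
    tolerance: float = 1e-12          # ftol/xtol/gtol of the least-squares solve
    noise_multiplier: float = 3.0     # n.d. threshold in noise sd units
    min_detectable_response: float = 0.1  # RU, absolute instrument floor
    slow_dissociation_retention: float = 0.5
    plateau_fraction: float = 0.2


@dataclass
class SteadyStateFit:
    K_D: float
    R_max: float
    ssr: float
    saturation_reached: bool


def fit_steady_state(concentrations, plateaus) -> SteadyStateFit:
    """Least-squares fit of the binding isotherm Req(C) = C*R_max/(C+K_D).

    Requires plateau responses at >=3 distinct concentrations.  Fitted in
    log-parameter space; flags when the series tops out far below K_D.
    """
    C = np.asarray(concentrations, dtype=float)
    R = np.asarray(plateaus, dtype=float)
    if len(np.unique(C)) < 3:
        raise ValidationError("steady-state fit requires >=3 distinct concentrations")
    if np.any(C <= 0):
        raise ValidationError("steady-state fit requires positive concentrations")
    rmax0 = max(R.max(), 1e-6) * 1.2
    # concentration at half the apparent maximum as a K_D seed
    half = rmax0 / 2
    above = C[R >= half]
    kd0 = float(above.min()) if len(above) else float(C.max())

    def resid(x):
        kd, rmax = 10.0 ** x
        return steady_state_response(C, kd, rmax) - R

    sol = least_squares(
        resid, x0=np.log10([kd0, rmax0]),
        bounds=(np.log10([1e-12, 1e-6]), np.log10([1.0, 1e7])),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    kd, rmax = 10.0 ** sol.x
    return SteadyStateFit(
        K_D=float(kd), R_max=float(rmax), ssr=float(2 * sol.cost),
        saturation_reached=bool(C.max() >= kd / 10.0),
    )


def _initial_guess(cycles, concs, opts: FitOptions):
    """Deterministic start: k_off from the dissociation tail at the highest
    concentration; K_D, R_max from a steady-state prefit; k_on = k_off/K_D."""
    plateaus = np.array([plateau_response(s, opts.plateau_fraction) for s in cycles])
    i_hi = int(np.argmax(concs))
    s = cycles[i_hi]
    dm = s.dissociation_mask()
    t, r = s.times[dm], s.responses[dm]
    floor = max(0.05 * max(r[0], 1e-9), 1e-9)
    keep = r > floor
    if keep.sum() >= 3:
        slope = np.polyfit(t[keep], np.log(r[keep]), 1)[0]
        koff0 = float(np.clip(-slope, *KOFF_BOUNDS))
    else:
        koff0 = 0.01
    if len(np.unique(concs)) >= 3:
        ss = fit_steady_state(concs, plateaus)
        kd0, rmax0 = ss.K_D, ss.R_max
    else:
        kd0 = float(np.median(concs))
        rmax0 = float(2.0 * plateaus.max())
    kon0 = float(np.clip(koff0 / max(kd0, 1e-12), *opts.kon_bounds))
    return kon0, koff0, max(rmax0, 1e-3)


def fit_kinetics_global(cs: CycleSet, options: FitOptions | None = None) -> KineticParameters:
    """Global 1:1 kinetic fit of a preprocessed cycle set.

    One (k_on, k_off, R_max) triple is fitted jointly to all non-zero
    concentration cycles over their association and dissociation windows,
    in log10-parameter space with bounds.  Degenerate inputs yield a
    ``not_detectable`` result rather than an exception.
    """
    opts = options or FitOptions()
    cycles = [s for s in cs.cycles if s.concentration > 0]
    concs = np.array([s.concentration for s in cycles])
    nd = KineticParameters(flags=frozenset({"not_detectable"}),
                           n_cycles_used=len(cycles))
    if len(np.unique(concs)) < 2:
        return nd
    noise_sd = float(np.median([estimate_noise_sd(s) for s in cycles]))
    plateaus = np.array([plateau_response(s, opts.plateau_fraction) for s in cycles])
    floor = max(opts.noise_multiplier * noise_sd, opts.min_detectable_response)
    if plateaus.max() < floor:
        return nd

    kon0, koff0, rmax0 = _initial_guess(cycles, concs, opts)
    rmax_hi = (opts.rmax_max_factor * opts.rmax_theoretical
               if opts.rmax_theoretical else max(10.0 * rmax0, 1e3))
    lo = np.log10([opts.kon_bounds[0], opts.koff_bounds[0], 1e-3])
    hi = np.log10([opts.kon_bounds[1], opts.koff_bounds[1], rmax_hi])
    x0 = np.clip(np.log10([kon0, koff0, rmax0]), lo, hi)

    masks = [s.association_mask() | s.dissociation_mask() for s in cycles]

    def resid(x):
        kon, koff, rmax = 10.0 ** x
        parts = [cycle_model(s, c, kon, koff, rmax)[m] - s.responses[m]
                 for s, c, m in zip(cycles, concs, masks)]
        return np.concatenate(parts)

    try:
        sol = least_squares(resid, x0=x0, bounds=(lo, hi),
                            xtol=opts.tolerance, ftol=opts.tolerance,
                            gtol=opts.tolerance)
    except Exception:
        return nd
    if not sol.success and not np.all(np.isfinite(sol.x)):
        return nd

    kon, koff, rmax = (float(v) for v in 10.0 ** sol.x)
    ssr = float(2 * sol.cost)
    n_res = sum(int(m.sum()) for m in masks)
    dof = max(n_res - 3, 1)
    se_kon = se_koff = math.nan
    try:
        jtj = sol.jac.T @ sol.jac
        cov = np.linalg.inv(jtj) * ssr / dof
        se_log = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
        ln10 = math.log(10.0)
        se_kon = kon * ln10 * float(se_log[0])
        se_koff = koff * ln10 * float(se_log[1])
    except np.linalg.LinAlgError:
        pass

    flags = set()
    # at-bound detection in log space, including SE overlap with the bound
    se_log_kon = se_kon / (kon * math.log(10.0)) if np.isfinite(se_kon) else 0.0
    se_log_koff = se_koff / (koff * math.log(10.0)) if np.isfinite(se_koff) else 0.0
    for xi, lo_i, hi_i, se_i in ((sol.x[0], lo[0], hi[0], se_log_kon),
                                 (sol.x[1], lo[1], hi[1], se_log_koff)):
        if min(xi - lo_i, hi_i - xi) < max(1e-6, se_i):
            flags.add("at_bound")

    params = KineticParameters(
        k_on=kon, k_off=koff, K_D=compute_kd(kon, koff), R_max=rmax,
        ssr=ssr, se_k_on=se_kon, se_k_off=se_koff,
        flags=frozenset(flags), n_cycles_used=len(cycles),
    )
    all_flags = qc_flags(params, cs, rmax_theoretical=opts.rmax_theoretical,
                         noise_sd=noise_sd, options=opts)
    return KineticParameters(
        k_on=kon, k_off=koff, K_D=params.K_D, R_max=rmax, ssr=ssr,
        se_k_on=se_kon, se_k_off=se_koff,
        flags=frozenset(flags | all_flags), n_cycles_used=len(cycles),
    )


def qc_flags(params: KineticParameters, cs: CycleSet,
             rmax_theoretical: float | None = None,
             noise_sd: float | None = None,
             options: FitOptions | None = None) -> set:
    """Quality-control flags for a fitted cycle set.

    - ``matrix_binding``: any observed response exceeds the theoretical
      saturation response (non-specific accumulation in the dextran matrix).
    - ``slow_dissociation``: the highest-concentration cycle retains more
      than the configured fraction (default 50 %) of its peak response at
      the end of the dissociation window.
    - ``not_detectable``: no cycle's plateau rises above the noise floor
      (``noise_multiplier`` x noise sd).
    """
    opts = options or FitOptions()
    flags = set()
    cycles = [s for s in cs.cycles if s.concentration > 0]
    if not cycles:
        return {"not_detectable"}
    if noise_sd is None:
        noise_sd = float(np.median([estimate_noise_sd(s) for s in cycles]))
    plateaus = np.array([plateau_response(s, opts.plateau_fraction) for s in cycles])
    floor = max(opts.noise_multiplier * noise_sd, opts.min_detectable_response)
    if plateaus.max() < floor:
        flags.add("not_detectable")
    if rmax_theoretical is not None:
        max_obs = max(float(s.responses.max()) for s in cycles)
        if max_obs > rmax_theoretical:
            flags.add("matrix_binding")
    s_hi = cycles[int(np.argmax([s.concentration for s in cycles]))]
    peak = float(s_hi.responses[s_hi.association_mask()].max(initial=0.0))
    if peak > opts.noise_multiplier * max(noise_sd, 1e-12):
        dm = s_hi.dissociation_mask()
        end_resp = float(s_hi.responses[dm][-1]) if dm.any() else 0.0
        if end_resp > opts.slow_dissociation_retention * peak:
            flags.add("slow_dissociation")
    return flags


def format_scientific(x: float, sig: int = 4) -> str:
    """Scientific notation with ``sig`` significant digits, e.g. ``1.099E+5``."""
    if x is None or not np.isfinite(x):
        return "n.d."
    mant, exp = f"{x:.{sig - 1}E}".split("E")
    sign = exp[0]
    digits = exp[1:].lstrip("0") or "0"
    return f"{mant}E{sign}{digits}"
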