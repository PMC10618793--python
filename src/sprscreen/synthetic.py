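"""Synthetic Biacore-style data: sensorgram cycle sets, DMSO calibration
cycles, competition experiments under known mechanisms, and screening panels.

The generator emulates the structure of a small-molecule SPR screen: for
each analyte an 8-point dilution series spanning 0.4-300 uM (geometric,
~3-fold steps) is injected over association/dissociation phases of 180/420 s
sampled at 1 Hz, alongside matched reference-cell cycles and two
zero-concentration blanks.  Traces are the closed-form 1:1 model plus an
optional linear drift, an association-phase bulk refractive-index shift
(present in both flow cells) and i.i.d. Gaussian noise.  Identical
(spec, seed) pairs produce bit-identical output.

The two-analyte shared-site occupancy ODE integrated here is deliberately
independent of the closed-form occupancy expressions in
:mod:`sprscreen.competition`; the two serve as mutual cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .exceptions import ValidationError
from .io import CycleSet, PanelRecord, Sensorgram
from .competition import CompetitionMeasurement

DEFAULT_CONCENTRATIONS = tuple(np.geomspace(0.4e-6, 300e-6, 8))

MECHANISMS = ("competitive_shared_site", "noncompetitive_independent_sites")


@dataclass
class SyntheticSpec:
    """Ground truth and noise model for one simulated cycle set."""

    k_on: float = 1e5            # 1/(M s)
    k_off: float = 0.5           # 1/s
    R_max: float = 200.0         # RU
    concentrations: tuple = DEFAULT_CONCENTRATIONS  # M
    t_assoc: float = 180.0       # s
    t_diss: float = 420.0        # s
    noise_sd: float = 0.5        # RU
    drift: float = 0.0           # RU/s
    bulk_shift: float = 0.0      # RU, during association, both flow cells
    sample_rate: float = 1.0     # Hz
    seed: int = 0
    analyte_id: str = "analyte"

    def __post_init__(self) -> None:
        if min(self.k_on, self.k_off, self.R_max) <= 0:
            raise ValidationError("rates and R_max must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if self.sample_rate <= 0 or self.t_assoc <= 0 or self.t_diss <= 0:
            raise ValidationError("sample_rate and phase durations must be positive")
        if any(c <= 0 for c in self.concentrations):
            raise ValidationError("concentrations must be positive")


def _time_grid(spec: SyntheticSpec) -> np.ndarray:
    n = int(round((spec.t_assoc + spec.t_diss) * spec.sample_rate)) + 1
    return np.arange(n) / spec.sample_rate


def _clean_trace(spec: SyntheticSpec, C: float, times: np.ndarray) -> np.ndarray:
    # local import avoids a module cycle (kinetics imports preprocess only)
    from .kinetics import association_response, dissociation_response
    out = np.zeros_like(times)
    am = times < spec.t_assoc
    out[am] = association_response(times[am], C, spec.k_on, spec.k_off, spec.R_max)
    r_end = float(association_response(spec.t_assoc, C, spec.k_on, spec.k_off,
                                       spec.R_max))
    out[~am] = dissociation_response(times[~am] - spec.t_assoc, r_end, spec.k_off)
    return out


def _artifacts(spec: SyntheticSpec, times: np.ndarray,
               rng: np.random.Generator) -> np.ndarray:
    bulk = np.where(times < spec.t_assoc, spec.bulk_shift, 0.0)
    noise = rng.normal(0.0, spec.noise_sd, size=len(times)) if spec.noise_sd else 0.0
    return spec.drift * times + bulk + noise


def generate_cycle_set(spec: SyntheticSpec) -> CycleSet:
    """Simulate one analyte's full concentration series with references and blanks."""
    rng = np.random.default_rng(spec.seed)
    times = _time_grid(spec)
    t_end = float(times[-1])

    def make(cycle_id, flow_cell, conc, signal):
        return Sensorgram(
            cycle_id=cycle_id, flow_cell=flow_cell, analyte_id=spec.analyte_id,
            concentration=conc, times=times,
            responses=signal + _artifacts(spec, times, rng),
            t_assoc_start=0.0, t_assoc_end=spec.t_assoc, t_diss_end=t_end,
        )

    cycles, refs = [], []
    zero = np.zeros_like(times)
    for i, C in enumerate(spec.concentrations):
        cid = f"{spec.analyte_id}-c{i + 1}"
        cycles.append(make(cid, "active", float(C), _clean_trace(spec, float(C), times)))
        refs.append(make(cid, "reference", float(C), zero))
    blanks, blank_refs = [], []
    for i in range(2):
        cid = f"{spec.analyte_id}-blank{i + 1}"
        blanks.append(make(cid, "active", 0.0, zero))
        blank_refs.append(make(cid, "reference", 0.0, zero))
    return CycleSet(
        analyte_id=spec.analyte_id, cycles=cycles, reference_cycles=refs,
        blank_cycles=blanks, blank_reference_cycles=blank_refs,
    )


def generate_solvent_correction_cycles(coefficients, n_points: int = 8,
                                       bulk_range: tuple = (40.0, 120.0),
                                       noise_sd: float = 0.0, seed: int = 0,
                                       t_assoc: float = 60.0, t_diss: float = 30.0):
    """DMSO-only calibration cycle pairs whose excluded-volume mismatch
    follows a known polynomial of the reference bulk response.

    Emulates the eight correction points of the 2.5-3.8 % DMSO design:
    reference plateaus span ``bulk_range`` and the active cell reads
    ``bulk + polyval(coefficients, bulk)``.  Returns a list of
    (reference, active) pairs.
    """
    rng = np.random.default_rng(seed)
    times = np.arange(int(t_assoc + t_diss) + 1, dtype=float)
    pairs = []
    bulks = np.linspace(*bulk_range, n_points)
    for i, bulk in enumerate(bulks):
        step = np.where(times < t_assoc, bulk, 0.0)
        noise_r = rng.normal(0.0, noise_sd, len(times)) if noise_sd else 0.0
        noise_a = rng.normal(0.0, noise_sd, len(times)) if noise_sd else 0.0
        ref = Sensorgram(
            cycle_id=f"dmso{i + 1}", flow_cell="reference", analyte_id="DMSO",
            concentration=0.0, times=times, responses=step + noise_r,
            t_assoc_start=0.0, t_assoc_end=t_assoc, t_diss_end=times[-1],
        )
        mismatch = np.where(times < t_assoc,
                            float(np.polyval(coefficients, bulk)), 0.0)
        act = Sensorgram(
            cycle_id=f"dmso{i + 1}", flow_cell="active", analyte_id="DMSO",
            concentration=0.0, times=times, responses=step + mismatch + noise_a,
            t_assoc_start=0.0, t_assoc_end=t_assoc, t_diss_end=times[-1],
        )
        pairs.append((ref, act))
    return pairs


# ----------------------------------------------------------------------
# Competition mechanisms


@dataclass
class CompetitionMechanism:
    """Generating mechanism of a two-analyte experiment.

    ``params_a`` / ``params_b`` are (k_on, k_off, R_max) triples.
    """

    kind: str
    params_a: tuple
    params_b: tuple

    def __post_init__(self) -> None:
        if self.kind not in MECHANISMS:
            raise ValidationError(f"unknown mechanism kind {self.kind!r}")
        for p in (self.params_a, self.params_b):
            if len(p) != 3 or min(p) <= 0:
                raise ValidationError("mechanism params must be positive triples")


def simulate_competitive_odes(mech: CompetitionMechanism, C_a: float, C_b: float,
                              t_end: float, n_eval: int = 200,
                              rtol: float = 1e-10):
    """Integrate the shared-site occupancy dynamics of two competing analytes.

        d theta_a / dt = k_on,a * C_a * (1 - theta_a - theta_b) - k_off,a * theta_a

    (and symmetrically for B) from empty surface.  Returns ``(t, theta_a,
    theta_b)`` trajectories.  Serves as the oracle-grade truth for the
    closed-form equilibrium occupancies.
    """
    if mech.kind != "competitive_shared_site":
        raise ValidationError(
            "simulate_competitive_odes requires a competitive_shared_site mechanism"
        )
    kon_a, koff_a, _ = mech.params_a
    kon_b, koff_b, _ = mech.params_b

    def rhs(_t, y):
        free = 1.0 - y[0] - y[1]
        return [kon_a * C_a * free - koff_a * y[0],
                kon_b * C_b * free - koff_b * y[1]]

    t_eval = np.linspace(0.0, t_end, n_eval)
    sol = solve_ivp(rhs, (0.0, t_end), [0.0, 0.0], method="LSODA",
                    t_eval=t_eval, rtol=rtol, atol=1e-14)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.t, sol.y[0], sol.y[1]


def _single_site_occupancy(C: float, kon: float, koff: float) -> float:
    return kon * C / (kon * C + koff)


def generate_competition_experiment(mech: CompetitionMechanism, C_a: float,
                                    C_b: float, noise_sd: float = 0.5,
                                    seed: int = 0) -> CompetitionMeasurement:
    """Simulate single and combined injections under a known mechanism.

    Single-analyte responses are equilibrium occupancies times R_max plus
    noise.  The combined response is the shared-site ODE steady state for a
    competitive mechanism, or the exact sum of independent occupancies for
    a non-competitive one.  K_D and R_max fields are filled from truth.
    """
    rng = np.random.default_rng(seed)
    kon_a, koff_a, rmax_a = mech.params_a
    kon_b, koff_b, rmax_b = mech.params_b
    ru_a = _single_site_occupancy(C_a, kon_a, koff_a) * rmax_a
    ru_b = _single_site_occupancy(C_b, kon_b, koff_b) * rmax_b
    if mech.kind == "competitive_shared_site":
        # integrate long enough for the slowest relaxation to equilibrate
        t_end = 30.0 / min(koff_a, koff_b)
        _, th_a, th_b = simulate_competitive_odes(mech, C_a, C_b, t_end, n_eval=2)
        ru_ab = th_a[-1] * rmax_a + th_b[-1] * rmax_b
    else:
        ru_ab = ru_a + ru_b
    noise = rng.normal(0.0, noise_sd, 3) if noise_sd else np.zeros(3)
    return CompetitionMeasurement(
        analyte_a="A", analyte_b="B", C_a=C_a, C_b=C_b,
        K_Da=koff_a / kon_a, K_Db=koff_b / kon_b,
        R_max_a=rmax_a, R_max_b=rmax_b,
        RU_a=max(ru_a + noise[0], 0.0),
        RU_b=max(ru_b + noise[1], 0.0),
        RU_ab=max(ru_ab + noise[2], 0.0),
    )


# ----------------------------------------------------------------------
# Panel generation


def generate_panel(n_compounds: int = 28, n_binders: int = 13,
                   kd_range: tuple = (1e-6, 3.4e-4), seed: int = 0,
                   noise_sd: float = 0.5, molecular_weight_range: tuple = (286.0, 330.0)):
    """Simulate a screening panel: binders with log-uniform K_D, plus
    noise-only non-binders.

    Binder off-rates are drawn log-uniformly from 0.05-0.5 1/s (the range
    typical of small-molecule screens) and on-rates follow from K_D;
    saturation responses are drawn from the theoretical 158-205 RU span.

    Returns ``(cycle_sets, panel_records, truth)`` where ``cycle_sets`` maps
    compound name to a simulated :class:`CycleSet` and ``truth`` is a
    DataFrame of the generating parameters.
    """
    if n_binders > n_compounds:
        raise ValidationError("n_binders cannot exceed n_compounds")
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    names = [f"CPD{i + 1:02d}" for i in range(n_compounds)]
    binder_idx = set(rng.choice(n_compounds, size=n_binders, replace=False).tolist())
    cycle_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n_compounds)]

    cycle_sets, records, rows = {}, [], []
    for i, name in enumerate(names):
        is_binder = i in binder_idx
        mw = float(rng.uniform(*molecular_weight_range))
        records.append(PanelRecord(name, mw, "cannabinoid"))
        if is_binder:
            kd = float(np.exp(rng.uniform(np.log(kd_range[0]), np.log(kd_range[1]))))
            koff = float(np.exp(rng.uniform(np.log(0.05), np.log(0.5))))
            kon = koff / kd
            rmax = float(rng.uniform(158.0, 205.0))
        else:
            kd, koff, kon, rmax = np.nan, np.nan, np.nan, np.nan
        spec = SyntheticSpec(
            k_on=kon if is_binder else 1e5,
            k_off=koff if is_binder else 0.5,
            R_max=rmax if is_binder else 1e-9,
            noise_sd=noise_sd, seed=cycle_seeds[i], analyte_id=name,
        )
        cycle_sets[name] = generate_cycle_set(spec)
        rows.append({"compound": name, "is_binder": is_binder,
                     "k_on": kon, "k_off": koff, "KD": kd, "R_max": rmax})
    truth = pd.DataFrame(rows)
    return cycle_sets, records, truth
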