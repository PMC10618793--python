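"""Competitive-SPR statistics: fractional occupancy, theoretical combined
responses, and the competitive / non-competitive classifier.

Two analytes A and B competing for one site at equilibrium occupy fractions

    FO_A = 1 / (1 + (K_DA / C_A) * (1 + C_B / K_DB))        (and symmetrically)

of the surface.  If both compete for the same site the combined response is

    RU_comp = FO_A * R_max,A + FO_B * R_max,B ,

whereas independent (non-competitive) binding predicts the simple sum of the
single-analyte responses, ``RU_noncomp = RU_A + RU_B``.  The measured
combined response is compared against both predictions; the nearer one (by
a configurable relative margin) names the binding mode.

A small thermodynamic helper converts docking binding free energies to
inhibition constants, ``Ki = exp(dG / (R*T))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .exceptions import ValidationError

GAS_CONSTANT_KCAL = 1.98720e-3  # kcal / (mol K)

DEFAULT_MARGIN = 0.1

COMPETITION_COLUMNS = [
    "analyte_a", "analyte_b", "C_a_M", "C_b_M", "KD_a_M", "KD_b_M",
    "Rmax_a_RU", "Rmax_b_RU", "RU_a", "RU_b", "RU_ab",
]


def fractional_occupancy_competitive(C_a: float, C_b: float,
                                     K_Da: float, K_Db: float) -> tuple:
    """Equilibrium fractional occupancies of two analytes sharing one site.

    Computed in the ratio form ``FO_A = (C_A/K_DA) / (1 + C_A/K_DA +
    C_B/K_DB)``, algebraically identical to the reciprocal form above but
    regular at zero concentration, where the occupancy limit is 0.
    """
    if K_Da <= 0 or K_Db <= 0:
        raise ValueError("dissociation constants must be positive")
    if C_a < 0 or C_b < 0:
        raise ValueError("concentrations must be non-negative")
    ra, rb = C_a / K_Da, C_b / K_Db
    denom = 1.0 + ra + rb
    return ra / denom, rb / denom


def theoretical_competitive_ru(FO_a: float, FO_b: float,
                               R_max_a: float, R_max_b: float) -> float:
    """Predicted combined response under shared-site competition (RU)."""
    for name, fo in (("FO_a", FO_a), ("FO_b", FO_b)):
        if not 0.0 <= fo <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {fo}")
    if R_max_a <= 0 or R_max_b <= 0:
        raise ValueError("R_max values must be positive")
    return FO_a * R_max_a + FO_b * R_max_b


def theoretical_noncompetitive_ru(RU_a: float, RU_b: float) -> float:
    """Predicted combined response under independent binding: the exact sum."""
    if RU_a < 0 or RU_b < 0:
        raise ValueError("RU values must be non-negative")
    return RU_a + RU_b


@dataclass
class CompetitionMeasurement:
    """Inputs of one competition experiment (single + combined injections)."""

    analyte_a: str
    analyte_b: str
    C_a: float       # M, per-component concentration in the mixture
    C_b: float       # M
    K_Da: float      # M
    K_Db: float      # M
    R_max_a: float   # RU
    R_max_b: float   # RU
    RU_a: float      # single-analyte experimental response (RU)
    RU_b: float
    RU_ab: float     # combined-injection experimental response (RU)

    def __post_init__(self) -> None:
        if min(self.C_a, self.C_b, self.K_Da, self.K_Db,
               self.R_max_a, self.R_max_b) <= 0:
            raise ValidationError(
                f"{self.analyte_a}+{self.analyte_b}: concentrations, K_D and "
                "R_max values must be positive"
            )
        if min(self.RU_a, self.RU_b, self.RU_ab) < 0 or not all(
            math.isfinite(v) for v in (self.RU_a, self.RU_b, self.RU_ab)
        ):
            raise ValidationError(
                f"{self.analyte_a}+{self.analyte_b}: RU values must be "
                "finite and non-negative"
            )


@dataclass
class CompetitionVerdict:
    """Classification of one competition experiment."""

    theoretical_competitive: float
    theoretical_noncompetitive: float
    experimental_combined: float
    distance_competitive: float
    distance_noncompetitive: float
    label: str            # competitive | non_competitive | inconclusive
    margin: float


def classify_competition(m: CompetitionMeasurement,
                         theoretical_competitive: float | None = None,
                         margin: float = DEFAULT_MARGIN) -> CompetitionVerdict:
    """Label an experiment competitive or non-competitive by nearest prediction.

    The non-competitive prediction is always the sum of the single-analyte
    responses.  The competitive prediction defaults to the occupancy model
    evaluated from the measurement's K_D and R_max fields but may be
    supplied explicitly (e.g. a published value).  With distances
    ``d_c = |RU_ab − RU_comp|`` and ``d_n = |RU_ab − RU_noncomp|`` the label
    is ``competitive`` if ``d_c < d_n * (1 − margin)``, ``non_competitive``
    if ``d_n < d_c * (1 − margin)``, else ``inconclusive``.
    """
    if not 0.0 <= margin < 1.0:
        raise ValueError(f"margin must lie in [0, 1), got {margin}")
    if theoretical_competitive is None:
        fo_a, fo_b = fractional_occupancy_competitive(m.C_a, m.C_b,
                                                      m.K_Da, m.K_Db)
        theoretical_competitive = theoretical_competitive_ru(
            fo_a, fo_b, m.R_max_a, m.R_max_b)
    theo_noncomp = theoretical_noncompetitive_ru(m.RU_a, m.RU_b)
    d_c = abs(m.RU_ab - theoretical_competitive)
    d_n = abs(m.RU_ab - theo_noncomp)
    if d_c < d_n * (1.0 - margin):
        label = "competitive"
    elif d_n < d_c * (1.0 - margin):
        label = "non_competitive"
    else:
        label = "inconclusive"
    return CompetitionVerdict(
        theoretical_competitive=float(theoretical_competitive),
        theoretical_noncompetitive=float(theo_noncomp),
        experimental_combined=float(m.RU_ab),
        distance_competitive=float(d_c),
        distance_noncompetitive=float(d_n),
        label=label,
        margin=float(margin),
    )


# ----------------------------------------------------------------------
# Thermodynamic conversion (docking energies <-> inhibition constants)


def inhibition_constant_from_energy(dG: float, T: float = 298.15) -> float:
    """Inhibition constant Ki (M) from a binding free energy dG (kcal/mol)."""
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    return math.exp(dG / (GAS_CONSTANT_KCAL * T))


def energy_from_inhibition_constant(Ki: float, T: float = 298.15) -> float:
    """Binding free energy (kcal/mol) from an inhibition constant Ki (M)."""
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    if Ki <= 0:
        raise ValueError(f"Ki must be positive, got {Ki}")
    return GAS_CONSTANT_KCAL * T * math.log(Ki)


# ----------------------------------------------------------------------
# Tabular interface


def read_competition_table(path) -> list:
    """Read a competition input TSV into :class:`CompetitionMeasurement` rows."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in COMPETITION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    return [
        CompetitionMeasurement(
            analyte_a=str(r.analyte_a), analyte_b=str(r.analyte_b),
            C_a=float(r.C_a_M), C_b=float(r.C_b_M),
            K_Da=float(r.KD_a_M), K_Db=float(r.KD_b_M),
            R_max_a=float(r.Rmax_a_RU), R_max_b=float(r.Rmax_b_RU),
            RU_a=float(r.RU_a), RU_b=float(r.RU_b), RU_ab=float(r.RU_ab),
        )
        for r in df.itertuples()
    ]


def write_verdict_table(measurements, verdicts, path,
                        margin: float = DEFAULT_MARGIN) -> None:
    """Write verdicts alongside their inputs; margin echoed in a header comment."""
    cols = COMPETITION_COLUMNS + [
        "theoretical_competitive_RU", "theoretical_noncompetitive_RU",
        "distance_competitive", "distance_noncompetitive", "label",
    ]
    lines = [f"# margin={margin!r}", "\t".join(cols)]
    for m, v in zip(measurements, verdicts):
        lines.append("\t".join([
            m.analyte_a, m.analyte_b,
            repr(m.C_a), repr(m.C_b), repr(m.K_Da), repr(m.K_Db),
            repr(m.R_max_a), repr(m.R_max_b),
            repr(m.RU_a), repr(m.RU_b), repr(m.RU_ab),
            f"{v.theoretical_competitive:.6g}",
            f"{v.theoretical_noncompetitive:.6g}",
            f"{v.distance_competitive:.6g}",
            f"{v.distance_noncompetitive:.6g}",
            v.label,
        ]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
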