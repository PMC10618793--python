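"""Data model and tabular I/O for SPR sensorgrams and compound panels.

A *sensorgram* is the response-unit (RU) versus time trace recorded for one
injection cycle on one flow cell.  Cycles are stored on a per-cycle clock
(time zero at cycle start) so that cycles are directly comparable.  The
on-disk representation is a tab-separated table with one row per sample and
a categorical ``phase`` column (``baseline`` | ``association`` |
``dissociation``) encoding the phase boundaries losslessly.

Numeric fields are written with Python's shortest round-tripping float
representation, so a write → read cycle reproduces every value bit-exactly.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

FLOW_CELLS = ("reference", "active")
PHASES = ("baseline", "association", "dissociation")
PANEL_ROLES = ("control", "cannabinoid")

SENSORGRAM_COLUMNS = [
    "cycle_id",
    "flow_cell",
    "analyte_id",
    "concentration_M",
    "phase",
    "time_s",
    "response_RU",
]

PANEL_COLUMNS = ["compound_name", "molecular_weight_gmol", "role"]


@dataclass
class Sensorgram:
    """One injection cycle's RU-vs-time trace on a single flow cell.

    Parameters
    ----------
    cycle_id : str
        Instrument cycle identifier; unique per (cycle, flow cell).
    flow_cell : {"reference", "active"}
        ``active`` carries the immobilized receptor; ``reference`` is the
        untreated cell used for bulk-artifact subtraction.
    analyte_id : str
        Compound injected during the association phase.
    concentration : float
        Analyte concentration in M.  Zero marks a blank (buffer-only) cycle.
    times, responses : ndarray
        Sample times (s, strictly increasing, from cycle start) and
        responses (RU).
    t_assoc_start, t_assoc_end, t_diss_end : float
        Phase boundaries in seconds; must satisfy
        ``t_assoc_start < t_assoc_end < t_diss_end`` and lie within the
        sampled time span.
    """

    cycle_id: str
    flow_cell: str
    analyte_id: str
    concentration: float
    times: np.ndarray
    responses: np.ndarray
    t_assoc_start: float
    t_assoc_end: float
    t_diss_end: float
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.flow_cell not in FLOW_CELLS:
            raise ValidationError(
                f"cycle {self.cycle_id!r}: flow_cell must be one of {FLOW_CELLS}, "
                f"got {self.flow_cell!r}"
            )
        if self.times.ndim != 1 or self.responses.ndim != 1:
            raise ValidationError(f"cycle {self.cycle_id!r}: times/responses must be 1-D")
        if len(self.times) != len(self.responses):
            raise ValidationError(
                f"cycle {self.cycle_id!r}: times and responses differ in length"
            )
        if len(self.times) == 0:
            raise ValidationError(f"cycle {self.cycle_id!r}: empty trace")
        if not np.all(np.isfinite(self.times)) or not np.all(np.isfinite(self.responses)):
            raise ValidationError(f"cycle {self.cycle_id!r}: non-finite sample values")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError(
                f"cycle {self.cycle_id!r}: times must be strictly increasing"
            )
        if self.concentration < 0:
            raise ValidationError(f"cycle {self.cycle_id!r}: negative concentration")
        if not (self.t_assoc_start < self.t_assoc_end < self.t_diss_end):
            raise ValidationError(
                f"cycle {self.cycle_id!r}: phase boundaries must satisfy "
                "t_assoc_start < t_assoc_end < t_diss_end"
            )
        if self.t_assoc_start < self.times[0] or self.t_diss_end > self.times[-1]:
            raise ValidationError(
                f"cycle {self.cycle_id!r}: phase boundaries outside sampled span"
            )

    # -- derived views -------------------------------------------------

    @property
    def n_points(self) -> int:
        return len(self.times)

    @property
    def is_blank(self) -> bool:
        return self.concentration == 0.0

    def phases(self) -> np.ndarray:
        """Per-sample phase labels implied by the boundaries."""
        out = np.full(self.n_points, "dissociation", dtype=object)
        out[self.times < self.t_assoc_end] = "association"
        out[self.times < self.t_assoc_start] = "baseline"
        return out

    def association_mask(self) -> np.ndarray:
        return (self.times >= self.t_assoc_start) & (self.times < self.t_assoc_end)

    def dissociation_mask(self) -> np.ndarray:
        return (self.times >= self.t_assoc_end) & (self.times <= self.t_diss_end)

    def with_responses(self, responses: np.ndarray) -> "Sensorgram":
        """Copy of this sensorgram with ``responses`` replaced."""
        return replace(self, responses=np.asarray(responses, dtype=float),
                       meta=dict(self.meta))

    def same_grid(self, other: "Sensorgram") -> bool:
        return (self.n_points == other.n_points
                and np.array_equal(self.times, other.times))


@dataclass
class CycleSet:
    """All cycles for one analyte: the unit of kinetic fitting.

    ``cycles`` are active-channel sample cycles, each matched (by position)
    with a ``reference_cycles`` entry on an identical time grid.
    ``blank_cycles`` are zero-concentration active-channel cycles with
    matching ``blank_reference_cycles``, carried so blanks can be
    double-referenced exactly like samples.
    """

    analyte_id: str
    cycles: list
    reference_cycles: list
    blank_cycles: list = field(default_factory=list)
    blank_reference_cycles: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.reference_cycles) not in (0, len(self.cycles)):
            raise ValidationError(
                f"{self.analyte_id}: reference cycles must match sample cycles 1:1"
            )
        for s, r in zip(self.cycles, self.reference_cycles):
            if not s.same_grid(r):
                raise ValidationError(
                    f"{self.analyte_id}: cycle {s.cycle_id!r} and its reference "
                    "are on different time grids"
                )

    @property
    def concentrations(self) -> np.ndarray:
        """Sorted distinct non-zero analyte concentrations (M)."""
        c = sorted({s.concentration for s in self.cycles if s.concentration > 0})
        return np.array(c)

    @property
    def is_fittable(self) -> bool:
        """At least two distinct non-zero concentrations present."""
        return len(self.concentrations) >= 2


@dataclass(frozen=True)
class PanelRecord:
    """One compound in the screened panel."""

    compound_name: str
    molecular_weight: float  # g/mol
    role: str  # "control" | "cannabinoid"

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValidationError(
                f"{self.compound_name}: molecular weight must be positive"
            )
        if self.role not in PANEL_ROLES:
            raise ValidationError(
                f"{self.compound_name}: role must be one of {PANEL_ROLES}"
            )


# ----------------------------------------------------------------------
# Sensorgram tables


def _fmt(x: float) -> str:
    """Shortest round-tripping decimal representation of a float."""
    return repr(float(x))


def read_sensorgram_table(path) -> list:
    """Read a sensorgram TSV into a list of :class:`Sensorgram`.

    One sensorgram is produced per (cycle_id, flow_cell) group, in file
    order.  Phase boundaries are taken from the transitions of the
    ``phase`` column; rows within a cycle must be time-ordered (the reader
    never reorders samples).
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip",
                     dtype={"cycle_id": str, "flow_cell": str,
                            "analyte_id": str, "phase": str})
    for col in SENSORGRAM_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    out = []
    for (cycle_id, flow_cell), g in df.groupby(["cycle_id", "flow_cell"], sort=False):
        times = g["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ValidationError(
                f"{path}: non-monotone time within cycle {cycle_id!r}"
            )
        phases = g["phase"].to_numpy()
        bad = set(phases) - set(PHASES)
        if bad:
            raise FormatError(f"{path}: unknown phase value(s) {sorted(bad)}")
        order = {p: i for i, p in enumerate(PHASES)}
        codes = np.array([order[p] for p in phases])
        if np.any(np.diff(codes) < 0):
            raise ValidationError(
                f"{path}: phases out of order within cycle {cycle_id!r}"
            )
        assoc = times[phases == "association"]
        diss = times[phases == "dissociation"]
        if len(assoc) == 0 or len(diss) == 0:
            raise ValidationError(
                f"{path}: cycle {cycle_id!r} lacks an association or "
                "dissociation phase"
            )
        conc = g["concentration_M"].to_numpy(dtype=float)
        if np.ptp(conc) != 0:
            raise ValidationError(
                f"{path}: concentration varies within cycle {cycle_id!r}"
            )
        analyte = g["analyte_id"].iloc[0]
        out.append(Sensorgram(
            cycle_id=cycle_id,
            flow_cell=flow_cell,
            analyte_id=analyte,
            concentration=float(conc[0]),
            times=times,
            responses=g["response_RU"].to_numpy(dtype=float),
            t_assoc_start=float(assoc[0]),
            t_assoc_end=float(diss[0]),
            t_diss_end=float(times[-1]),
        ))
    return out


def write_sensorgram_table(sensorgrams: Iterable[Sensorgram], path) -> None:
    """Write sensorgrams as a TSV that :func:`read_sensorgram_table` inverts.

    Column order is fixed, numbers use shortest round-trip formatting, and
    the file ends with a trailing newline.  An empty input produces a
    header-only file.
    """
    lines = ["\t".join(SENSORGRAM_COLUMNS)]
    for s in sensorgrams:
        phases = s.phases()
        for t, r, ph in zip(s.times, s.responses, phases):
            lines.append("\t".join([
                s.cycle_id, s.flow_cell, s.analyte_id,
                _fmt(s.concentration), ph, _fmt(t), _fmt(r),
            ]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ----------------------------------------------------------------------
# Panel metadata


def read_panel_table(path) -> list:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip",
                     dtype={"compound_name": str, "role": str})
    for col in PANEL_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return [
        PanelRecord(row.compound_name, float(row.molecular_weight_gmol), row.role)
        for row in df.itertuples()
    ]


def write_panel_table(records: Sequence[PanelRecord], path) -> None:
    lines = ["\t".join(PANEL_COLUMNS)]
    for r in records:
        lines.append("\t".join([r.compound_name, _fmt(r.molecular_weight), r.role]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ----------------------------------------------------------------------
# Bundled reference tables


def _data_path(name: str):
    return importlib.resources.files("sprscreen.data").joinpath(name)


def load_panel_kinetics() -> pd.DataFrame:
    """Published kinetic screening results for the P2X4 cannabinoid panel.

    Columns: ``compound``, ``role``, ``k_on_1_per_Ms``, ``k_off_1_per_s``,
    ``KD_M``; non-binders carry the literal string ``"n.d."`` in all three
    numeric columns.
    """
    with importlib.resources.as_file(_data_path("p2x4_panel_kinetics.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype=str)


def load_competition_measurements() -> pd.DataFrame:
    """Published single/combined RU measurements for the P2X4 competition assays."""
    with importlib.resources.as_file(
        _data_path("p2x4_competition_measurements.tsv")
    ) as p:
        df = pd.read_csv(p, sep="\t")
    return df
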