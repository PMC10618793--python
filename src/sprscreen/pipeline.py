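"""End-to-end orchestration: screening runs and competition runs.

This module contains the logic behind the command-line interface: building
cycle sets from a sensorgram table, preprocessing, fitting every compound,
assembling a screen report, and batch-classifying competition experiments.
Per-compound failures degrade to ``n.d.`` rows with an explicit reason;
rows are never silently dropped.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .competition import (DEFAULT_MARGIN, classify_competition,
                          read_competition_table, write_verdict_table)
from .exceptions import SprScreenError
from .io import (CycleSet, read_panel_table, read_sensorgram_table,
                 write_panel_table, write_sensorgram_table)
from .kinetics import (FitOptions, KineticParameters, fit_kinetics_global,
                       format_scientific, theoretical_rmax)
from .preprocess import double_reference
from .synthetic import SyntheticSpec, generate_cycle_set, generate_panel

log = logging.getLogger("sprscreen")

SCREEN_REPORT_COLUMNS = ["compound", "k_on_1_per_Ms", "k_off_1_per_s",
                         "KD_M", "Rmax_RU", "flags", "n_cycles_used"]


@dataclass
class ScreenReport:
    """Per-compound fit results plus summary counts for one screening run."""

    rows: list = field(default_factory=list)   # (compound, KineticParameters)
    summary: dict = field(default_factory=dict)

    def finalize(self) -> None:
        n_binder = sum(1 for _, p in self.rows if p.is_detectable)
        n_nd = sum(1 for _, p in self.rows if not p.is_detectable)
        n_flagged = sum(1 for _, p in self.rows
                        if p.flags - {"not_detectable"})
        self.summary = {"n_compounds": len(self.rows), "n_binders": n_binder,
                        "n_not_detectable": n_nd, "n_flagged": n_flagged}


def build_cycle_sets(sensorgrams) -> dict:
    """Group a flat sensorgram list into per-analyte cycle sets.

    Active/reference pairs are matched by cycle_id; zero-concentration
    cycles become blanks.
    """
    by_analyte: dict = {}
    for s in sensorgrams:
        by_analyte.setdefault(s.analyte_id, []).append(s)
    sets = {}
    for analyte, group in by_analyte.items():
        actives = {s.cycle_id: s for s in group if s.flow_cell == "active"}
        refs = {s.cycle_id: s for s in group if s.flow_cell == "reference"}
        cycles, references, blanks, blank_refs = [], [], [], []
        for cid, s in actives.items():
            r = refs.get(cid)
            if r is None:
                raise SprScreenError(
                    f"{analyte}: cycle {cid!r} has no matching reference cycle"
                )
            if s.is_blank:
                blanks.append(s)
                blank_refs.append(r)
            else:
                cycles.append(s)
                references.append(r)
        sets[analyte] = CycleSet(
            analyte_id=analyte, cycles=cycles, reference_cycles=references,
            blank_cycles=blanks, blank_reference_cycles=blank_refs,
        )
    return sets


def screen_cycle_set(cs: CycleSet, options: FitOptions | None = None) -> KineticParameters:
    """Preprocess and globally fit one compound's cycle set."""
    processed = double_reference(cs)
    return fit_kinetics_global(processed, options)


def run_screen(sensorgram_path, panel_path=None, out_dir=None,
               config: dict | None = None) -> ScreenReport:
    """Full screening run: read, preprocess, fit and report every compound.

    Per-compound fit failures are logged and reported as ``n.d.``; the run
    never aborts on a single compound.
    """
    config = config or {}
    sensorgrams = read_sensorgram_table(sensorgram_path)
    sets = build_cycle_sets(sensorgrams)
    panel = read_panel_table(panel_path) if panel_path else []
    panel_names = [p.compound_name for p in panel] or sorted(sets)

    ligand_mw = config.get("ligand_mw_gmol")
    immobilized = config.get("immobilized_RU")
    mw_by_name = {p.compound_name: p.molecular_weight for p in panel}

    report = ScreenReport()
    for name in panel_names:
        cs = sets.get(name)
        if cs is None:
            log.warning("screen: %s has no cycles; reported n.d.", name)
            report.rows.append((name, KineticParameters(
                flags=frozenset({"not_detectable"}))))
            continue
        rmax_theo = None
        if ligand_mw and immobilized and name in mw_by_name:
            rmax_theo = theoretical_rmax(mw_by_name[name], ligand_mw, immobilized)
        opts = FitOptions(rmax_theoretical=rmax_theo,
                          **config.get("fit_options", {}))
        try:
            params = screen_cycle_set(cs, opts)
        except SprScreenError as exc:
            log.warning("screen: fit failed for %s (%s); reported n.d.", name, exc)
            params = KineticParameters(flags=frozenset({"not_detectable"}))
        if not params.is_detectable:
            log.info("screen: %s not detectable (max plateau below noise floor "
                     "or <2 usable concentrations)", name)
        report.rows.append((name, params))
    report.finalize()
    if out_dir is not None:
        write_screen_report(report, Path(out_dir) / "screen_report.tsv")
    return report


def write_screen_report(report: ScreenReport, path) -> None:
    """Screen report TSV; non-binders carry the literal ``n.d.`` in all
    numeric columns, and numbers use 4-significant-digit scientific notation."""
    lines = ["\t".join(SCREEN_REPORT_COLUMNS)]
    for name, p in report.rows:
        if p.is_detectable:
            vals = [format_scientific(p.k_on), format_scientific(p.k_off),
                    format_scientific(p.K_D), format_scientific(p.R_max)]
        else:
            vals = ["n.d."] * 4
        lines.append("\t".join([name, *vals,
                                ",".join(sorted(p.flags)) or "-",
                                str(p.n_cycles_used)]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def run_compete(input_path, out_dir=None, margin: float = DEFAULT_MARGIN,
                use_reported_theoretical: bool = True):
    """Classify every competition row; returns (measurements, verdicts).

    If the input carries a ``theoretical_competitive_RU`` column (published
    predictions) it is used directly; otherwise the occupancy model is
    evaluated from the K_D / R_max columns.
    """
    import pandas as pd

    from .competition import CompetitionMeasurement

    df = pd.read_csv(input_path, sep="\t", comment="#")
    has_theo = use_reported_theoretical and "theoretical_competitive_RU" in df.columns
    if "Rmax_a_RU" not in df.columns:
        # published tables omit R_max; a placeholder keeps validation happy
        # when an explicit theoretical prediction is provided instead
        df = df.assign(Rmax_a_RU=100.0, Rmax_b_RU=100.0)
    measurements, verdicts = [], []
    for i, r in enumerate(df.itertuples()):
        m = CompetitionMeasurement(
            analyte_a=str(r.analyte_a), analyte_b=str(r.analyte_b),
            C_a=float(r.C_a_M), C_b=float(r.C_b_M),
            K_Da=float(r.KD_a_M), K_Db=float(r.KD_b_M),
            R_max_a=float(r.Rmax_a_RU), R_max_b=float(r.Rmax_b_RU),
            RU_a=float(r.RU_a), RU_b=float(r.RU_b), RU_ab=float(r.RU_ab),
        )
        theo = float(df["theoretical_competitive_RU"].iloc[i]) if has_theo else None
        measurements.append(m)
        verdicts.append(classify_competition(m, theoretical_competitive=theo,
                                             margin=margin))
    if out_dir is not None:
        write_verdict_table(measurements, verdicts,
                            Path(out_dir) / "compete_report.tsv", margin=margin)
    return measurements, verdicts


def run_simulate(config: dict, out_dir, seed: int = 0) -> dict:
    """Simulate a panel (or a single analyte) and write sensorgram + truth TSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    panel_cfg = config.get("panel")
    if panel_cfg is not None:
        cycle_sets, records, truth = generate_panel(
            n_compounds=int(panel_cfg.get("n_compounds", 28)),
            n_binders=int(panel_cfg.get("n_binders", 13)),
            kd_range=tuple(panel_cfg.get("kd_range", (1e-6, 3.4e-4))),
            noise_sd=float(config.get("noise_sd", 0.5)),
            seed=seed,
        )
        all_cycles = []
        for cs in cycle_sets.values():
            all_cycles += cs.cycles + cs.reference_cycles
            all_cycles += cs.blank_cycles + cs.blank_reference_cycles
        write_sensorgram_table(all_cycles, out_dir / "sensorgrams.tsv")
        write_panel_table(records, out_dir / "panel.tsv")
        truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
        return {"n_compounds": len(cycle_sets)}
    spec_kwargs = {k: v for k, v in config.items()
                   if k in SyntheticSpec.__dataclass_fields__ and k != "seed"}
    spec = SyntheticSpec(seed=seed, **spec_kwargs)
    cs = generate_cycle_set(spec)
    write_sensorgram_table(
        cs.cycles + cs.reference_cycles + cs.blank_cycles + cs.blank_reference_cycles,
        out_dir / "sensorgrams.tsv")
    return {"n_compounds": 1}


def config_digest(config: dict) -> str:
    """Stable hash of a config mapping, for run provenance logging."""
    blob = repr(sorted((str(k), str(v)) for k, v in (config or {}).items()))
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def log_provenance(config: dict, seed=None) -> None:
    log.info("sprscreen %s | config sha %s | seed %s",
             __version__, config_digest(config), seed)
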