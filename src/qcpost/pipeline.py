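"""End-to-end characterization over a set of compound records.

Runs every analysis a record has inputs for — global reactivity
descriptors, condensed Fukui tables, RRHO thermodynamic profiles, and
formula/mass/energetic descriptors — and collects the results into a
:class:`CharacterizationReport` whose sections mirror the tables of a
computational-characterization write-up. Sections are computed only
where inputs exist; everything is deterministic given the records and
settings.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .constants import MASS_TABLE_VERSION
from .formula import (
    DEFAULT_TABLES,
    average_molar_mass,
    elemental_percentages,
    format_formula,
    monoisotopic_mass,
    nitrogen_percent,
    oxygen_balance,
    round_half_even,
)
from .fukui import FukuiTable, condensed_fukui, rank_sites
from .reactivity import global_descriptors, series_ranking
from .records import CompoundRecord, write_report
from .thermochem import ThermoProfile, default_grid, thermo_profile

__all__ = ["Settings", "CharacterizationReport", "run_characterization", "write_bundle"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Settings:
    """Pipeline settings; defaults reproduce the reference analysis."""

    ob_convention: str = "CHNO-classic"
    fukui_labeling: str = "paper"  # or "standard"
    tmin: float = 10.0
    tmax: float = 500.0
    tstep: float = 10.0
    include_zpe: bool = True
    qrrho: bool = False
    round_descriptors: int | None = None  # None: raw doubles in tables


@dataclass(frozen=True)
class CharacterizationReport:
    """All computed sections plus run metadata."""

    descriptors: pd.DataFrame | None
    fukui: dict[str, FukuiTable]
    thermo: dict[str, ThermoProfile]
    formula_table: pd.DataFrame | None
    rankings: dict
    metadata: dict = field(default_factory=dict)


def _descriptor_row(cid: str, g, ndigits: int | None) -> dict:
    row = {
        "compound": cid,
        "I": g.ionization_potential,
        "A": g.electron_affinity,
        "gap": g.gap,
        "chi": g.electronegativity,
        "mu_abs": g.mu_abs,
        "eta": g.hardness,
        "softness": g.softness,
        "omega": g.electrophilicity,
    }
    if ndigits is not None:
        row = {
            k: (round_half_even(v, ndigits) if isinstance(v, float) else v)
            for k, v in row.items()
        }
    return row


def _formula_row(record: CompoundRecord, settings: Settings) -> dict:
    f = record.formula
    pct = elemental_percentages(f, DEFAULT_TABLES)
    row = {
        "compound": record.id,
        "formula": format_formula(f),
        "molar_mass": round_half_even(average_molar_mass(f, DEFAULT_TABLES), 2),
        "monoisotopic_mass": round_half_even(monoisotopic_mass(f, DEFAULT_TABLES), 4),
        "nitrogen_percent": round_half_even(nitrogen_percent(f, DEFAULT_TABLES), 2),
        "oxygen_balance": round_half_even(
            oxygen_balance(f, DEFAULT_TABLES, settings.ob_convention), 2
        ),
        "ob_convention": settings.ob_convention,
        "mass_table_version": DEFAULT_TABLES.version,
    }
    for sym in sorted(pct):
        row[f"pct_{sym}"] = round_half_even(pct[sym], 2)
    return row


def run_characterization(
    records: list[CompoundRecord], settings: Settings | None = None
) -> CharacterizationReport:
    """Run the full analysis over *records*.

    Raises ValueError on an empty record list; records lacking an
    input type are simply absent from that section (logged notice).
    """
    if not records:
        raise ValueError("no records to characterize")
    settings = settings or Settings()
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate record ids: {ids}")

    desc_rows, glob = [], []
    fukui_tables: dict[str, FukuiTable] = {}
    thermo: dict[str, ThermoProfile] = {}
    formula_rows = []
    grid = default_grid(settings.tmin, settings.tmax, settings.tstep)

    for r in records:
        formula_rows.append(_formula_row(r, settings))
        if r.orbitals is not None:
            g = global_descriptors(r.orbitals)
            glob.append((r.id, g))
            desc_rows.append(_descriptor_row(r.id, g, settings.round_descriptors))
        else:
            log.info("record %s: no orbitals; descriptor section skipped", r.id)
        if r.charges is not None:
            fukui_tables[r.id] = condensed_fukui(list(r.charges))
        else:
            log.info("record %s: no charges; Fukui section skipped", r.id)
        if r.vibrations is not None and r.body is not None:
            thermo[r.id] = thermo_profile(
                r.vibrations, r.body, grid,
                include_zpe=settings.include_zpe, qrrho=settings.qrrho,
            )
        else:
            log.info("record %s: no vibrations/body; thermo section skipped", r.id)

    rankings: dict = {}
    if glob:
        rankings["reactivity"] = series_ranking(glob)
    if formula_rows:
        by_n = sorted(formula_rows, key=lambda r: (-r["nitrogen_percent"], r["compound"]))
        by_ob = sorted(
            formula_rows, key=lambda r: (abs(r["oxygen_balance"]), r["compound"])
        )
        rankings["highest_nitrogen_percent"] = [r["compound"] for r in by_n]
        rankings["smallest_oxygen_balance_magnitude"] = [r["compound"] for r in by_ob]
    if fukui_tables:
        rankings["fukui_top_sites"] = {
            cid: {
                mode: rank_sites(t, mode, settings.fukui_labeling)[0]
                for mode in ("nucleophilic_attack", "electrophilic_attack", "radical")
            }
            for cid, t in sorted(fukui_tables.items())
        }

    metadata = {
        "qcpost_version": __version__,
        "mass_table_version": MASS_TABLE_VERSION,
        "constants": "CODATA 2018 (SI-exact)",
        "settings": {
            "ob_convention": settings.ob_convention,
            "fukui_labeling": settings.fukui_labeling,
            "temperature_grid_K": [settings.tmin, settings.tmax, settings.tstep],
            "include_zpe": settings.include_zpe,
            "qrrho": settings.qrrho,
            "round_descriptors": settings.round_descriptors,
        },
        "n_records": len(records),
    }
    return CharacterizationReport(
        descriptors=pd.DataFrame(desc_rows) if desc_rows else None,
        fukui=fukui_tables,
        thermo=thermo,
        formula_table=pd.DataFrame(formula_rows) if formula_rows else None,
        rankings=rankings,
        metadata=metadata,
    )


def write_bundle(report: CharacterizationReport, outdir, fmt: str = "csv") -> Path:
    """Write the report as a directory of CSV/JSON files + metadata.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = report.metadata
    if report.descriptors is not None:
        write_report(report.descriptors, outdir / f"descriptors.{fmt}", fmt, meta)
    if report.formula_table is not None:
        write_report(report.formula_table, outdir / f"formula.{fmt}", fmt, meta)
    for cid, table in sorted(report.fukui.items()):
        write_report(table.to_frame(), outdir / f"fukui_{cid}.{fmt}", fmt, meta)
    if report.thermo:
        frames = [p.to_frame(cid) for cid, p in sorted(report.thermo.items())]
        write_report(pd.concat(frames, ignore_index=True), outdir / f"thermo.{fmt}", fmt, meta)
    (outdir / "rankings.json").write_text(json.dumps(report.rankings, indent=1) + "\n")
    (outdir / "metadata.json").write_text(json.dumps(meta, indent=1) + "\n")
    return outdir
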