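"""Compound-record schema, readers/writers and report serialization.

A :class:`CompoundRecord` bundles everything downstream modules need
for one compound: molecular formula, frontier orbital energies,
optional per-atom charge triples, optional harmonic frequencies and
optional rigid-body data. Two on-disk formats are supported:

``record-json``
    A documented JSON schema (see :func:`record_to_dict`); the
    canonical interchange format. Lossless round-trip.

``log-dialect``
    A plain-text layout modeled on quantum-chemistry program logs:
    ``occ.``/``virt.`` eigenvalue runs in hartree, per-atom charge
    tables for the three electron states, ``Frequencies --`` triples
    and a rigid-body block. Unrecognized lines are ignored, so real
    log fragments can be interspersed; floats are emitted at full
    (shortest round-trip) precision so read(write(r)) == r exactly.

Missing optional sections stay absent — they are never filled with
defaults.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import constants as k
from .formula import MolecularFormula, format_formula, parse_formula
from .fukui import ChargeTriple
from .reactivity import OrbitalEnergies
from .thermochem import RigidBody, VibrationalSet

__all__ = [
    "RecordError",
    "CompoundRecord",
    "read_record",
    "write_record",
    "record_to_dict",
    "record_from_dict",
    "write_report",
]

FORMATS = ("record-json", "log-dialect")


class RecordError(ValueError):
    """Malformed record file or inconsistent record content."""


@dataclass(frozen=True)
class CompoundRecord:
    """One compound's complete computational input bundle."""

    id: str
    formula: MolecularFormula
    orbitals: OrbitalEnergies | None = None
    charges: tuple[ChargeTriple, ...] | None = None
    vibrations: VibrationalSet | None = None
    body: RigidBody | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise RecordError("record id must be nonempty")
        if self.charges is not None and len(self.charges) == 0:
            raise RecordError("charges present but empty")


# ---------------------------------------------------------------- JSON ----


def record_to_dict(record: CompoundRecord) -> dict:
    """Record as a plain dict following the record-json schema."""
    d: dict = {
        "id": record.id,
        "provenance": record.provenance,
        "formula": format_formula(record.formula),
    }
    if record.orbitals is not None:
        o = record.orbitals
        d["orbitals"] = {"e_homo": o.e_homo, "e_lumo": o.e_lumo, "unit": o.unit}
    if record.charges is not None:
        d["charges"] = {
            "scheme": record.charges[0].scheme_tag,
            "atoms": [
                [c.atom_index, c.atomic_number, c.q_cation, c.q_neutral, c.q_anion]
                for c in record.charges
            ],
        }
    if record.vibrations is not None:
        d["frequencies"] = {
            "values": list(record.vibrations.frequencies),
            "dropped_imaginary": record.vibrations.dropped_imaginary,
        }
    if record.body is not None:
        b = record.body
        d["body"] = {
            "molar_mass": b.molar_mass,
            "rotational_constants_ghz": list(b.rotational_constants),
            "symmetry_number": b.symmetry_number,
            "pressure_pa": b.pressure,
            "electronic_degeneracy": b.electronic_degeneracy,
            "linear": b.linear,
        }
    return d


def record_from_dict(d: dict) -> CompoundRecord:
    """Inverse of :func:`record_to_dict`, with validation."""
    try:
        rid = d["id"]
        formula = parse_formula(d["formula"])
    except KeyError as exc:
        raise RecordError(f"record-json missing required key: {exc}") from None

    orbitals = None
    if "orbitals" in d:
        o = d["orbitals"]
        if "e_homo" not in o or "e_lumo" not in o:
            raise RecordError("orbital section must carry both frontier energies")
        orbitals = OrbitalEnergies(
            e_homo=float(o["e_homo"]),
            e_lumo=float(o["e_lumo"]),
            unit=o.get("unit", "hartree"),
        )

    charges = None
    if "charges" in d:
        scheme = d["charges"].get("scheme", "unspecified")
        charges = tuple(
            ChargeTriple(
                atom_index=int(row[0]),
                atomic_number=int(row[1]),
                q_cation=float(row[2]),
                q_neutral=float(row[3]),
                q_anion=float(row[4]),
                scheme_tag=scheme,
            )
            for row in d["charges"]["atoms"]
        )

    vibrations = None
    if "frequencies" in d:
        f = d["frequencies"]
        vibrations = VibrationalSet(
            frequencies=tuple(float(v) for v in f["values"]),
            dropped_imaginary=int(f.get("dropped_imaginary", 0)),
        )

    body = None
    if "body" in d:
        b = d["body"]
        body = RigidBody(
            molar_mass=float(b["molar_mass"]),
            rotational_constants=tuple(float(x) for x in b.get("rotational_constants_ghz", [])),
            symmetry_number=int(b.get("symmetry_number", 1)),
            pressure=float(b.get("pressure_pa", k.ATM_PA)),
            electronic_degeneracy=int(b.get("electronic_degeneracy", 1)),
            linear=bool(b.get("linear", False)),
        )

    return CompoundRecord(
        id=rid,
        formula=formula,
        orbitals=orbitals,
        charges=charges,
        vibrations=vibrations,
        body=body,
        provenance=d.get("provenance", ""),
    )


# ---------------------------------------------------------- log dialect ----

_STATE_TAGS = ("N-1", "N", "N+1")


def _record_to_log(record: CompoundRecord) -> str:
    lines: list[str] = [f"Compound: {record.id}"]
    if record.provenance:
        lines.append(f"Provenance: {record.provenance}")
    lines.append(f"Formula: {format_formula(record.formula)}")
    if record.orbitals is not None:
        if record.orbitals.unit != "hartree":
            raise RecordError("log-dialect stores orbital energies in hartree only")
        lines.append(f" Alpha  occ. eigenvalues --  {float(record.orbitals.e_homo)!r}")
        lines.append(f" Alpha virt. eigenvalues --  {float(record.orbitals.e_lumo)!r}")
    if record.charges is not None:
        scheme = record.charges[0].scheme_tag
        for tag, attr in zip(_STATE_TAGS, ("q_cation", "q_neutral", "q_anion")):
            lines.append(f" {scheme} charges [{tag}]:")
            for c in record.charges:
                sym = k.SYMBOL_OF.get(c.atomic_number, f"Z{c.atomic_number}")
                lines.append(f" {c.atom_index:>6d}  {sym:<2s}  {float(getattr(c, attr))!r}")
    if record.vibrations is not None:
        freqs = record.vibrations.frequencies
        for i in range(0, len(freqs), 3):
            chunk = "   ".join(repr(float(v)) for v in freqs[i : i + 3])
            lines.append(f" Frequencies --   {chunk}")
        if record.vibrations.dropped_imaginary:
            lines.append(f" Dropped imaginary: {record.vibrations.dropped_imaginary}")
    if record.body is not None:
        b = record.body
        lines.append(f" Molecular mass:  {float(b.molar_mass)!r} amu")
        if b.rotational_constants:
            vals = "   ".join(repr(float(v)) for v in b.rotational_constants)
            lines.append(f" Rotational constants (GHZ):  {vals}")
        lines.append(f" Rotational symmetry number  {b.symmetry_number}")
        lines.append(f" Pressure (Pa):  {float(b.pressure)!r}")
        lines.append(f" Electronic degeneracy:  {b.electronic_degeneracy}")
        lines.append(f" Linear molecule:  {'yes' if b.linear else 'no'}")
    return "\n".join(lines) + "\n"


_RE_FLOAT = r"[-+]?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?"
_RE_EIG = re.compile(r"Alpha\s+(occ|virt)\. eigenvalues --\s+(.*)")
_RE_CHG_HDR = re.compile(r"^\s*(\S+) charges \[(N-1|N|N\+1)\]:\s*$")
_RE_CHG_ROW = re.compile(rf"^\s*(\d+)\s+([A-Z][a-z]?|Z\d+)\s+({_RE_FLOAT})\s*$")
_RE_FREQ = re.compile(r"Frequencies --\s+(.*)")


def _record_from_log(text: str, path: str = "<log>") -> CompoundRecord:
    if not text.strip():
        raise RecordError(f"{path}: empty log file")
    rid = ""
    provenance = ""
    formula: MolecularFormula | None = None
    occ: list[float] = []
    virt: list[float] = []
    freqs: list[float] = []
    dropped = 0
    charge_blocks: dict[str, list[tuple[int, int, float]]] = {}
    scheme = "unspecified"
    cur_state: str | None = None
    body_kv: dict = {}

    for line in text.splitlines():
        m = _RE_CHG_ROW.match(line)
        if m and cur_state is not None:
            sym = m.group(2)
            z = int(sym[1:]) if sym.startswith("Z") and sym[1:].isdigit() else k.ATOMIC_NUMBER.get(sym, 0)
            if z == 0:
                raise RecordError(f"{path}: unknown element {sym!r} in charge block")
            charge_blocks[cur_state].append((int(m.group(1)), z, float(m.group(3))))
            continue
        m = _RE_CHG_HDR.match(line)
        if m:
            scheme, cur_state = m.group(1), m.group(2)
            if cur_state in charge_blocks:
                raise RecordError(f"{path}: duplicate charge block for state {cur_state}")
            charge_blocks[cur_state] = []
            continue
        cur_state = None  # any non-row line terminates a charge block
        if line.startswith("Compound:"):
            rid = line.split(":", 1)[1].strip()
        elif line.startswith("Provenance:"):
            provenance = line.split(":", 1)[1].strip()
        elif line.startswith("Formula:"):
            formula = parse_formula(line.split(":", 1)[1].strip())
        elif (m := _RE_EIG.search(line)) is not None:
            target = occ if m.group(1) == "occ" else virt
            target.extend(float(v) for v in m.group(2).split())
        elif (m := _RE_FREQ.search(line)) is not None:
            freqs.extend(float(v) for v in m.group(1).split())
        elif line.strip().startswith("Dropped imaginary:"):
            dropped = int(line.split(":", 1)[1])
        elif line.strip().startswith("Molecular mass:"):
            body_kv["molar_mass"] = float(line.split(":", 1)[1].split()[0])
        elif "Rotational constants (GHZ):" in line:
            body_kv["rot"] = tuple(float(v) for v in line.split(":", 1)[1].split())
        elif "Rotational symmetry number" in line:
            body_kv["sigma"] = int(float(line.rsplit(None, 1)[1]))
        elif line.strip().startswith("Pressure (Pa):"):
            body_kv["pressure"] = float(line.split(":", 1)[1])
        elif line.strip().startswith("Electronic degeneracy:"):
            body_kv["g"] = int(line.split(":", 1)[1])
        elif line.strip().startswith("Linear molecule:"):
            body_kv["linear"] = line.split(":", 1)[1].strip() == "yes"
        # anything else: tolerated and ignored

    if formula is None:
        raise RecordError(f"{path}: malformed log (no Formula line)")

    orbitals = None
    if occ or virt:
        if not occ or not virt:
            raise RecordError(f"{path}: orbital section lacks occ. or virt. eigenvalues")
        orbitals = OrbitalEnergies(e_homo=max(occ), e_lumo=min(virt))

    charges = None
    if charge_blocks:
        missing = [s for s in _STATE_TAGS if s not in charge_blocks]
        if missing:
            raise RecordError(f"{path}: charge states missing: {missing}")
        cat, neu, an = (charge_blocks[s] for s in _STATE_TAGS)
        if not (len(cat) == len(neu) == len(an)):
            raise RecordError(f"{path}: charge states cover unequal atom counts")
        charges = []
        for (i1, z1, qc), (i2, z2, qn), (i3, z3, qa) in zip(cat, neu, an):
            if not (i1 == i2 == i3) or not (z1 == z2 == z3):
                raise RecordError(f"{path}: charge states disagree on atom {i1}")
            charges.append(
                ChargeTriple(
                    atom_index=i1, atomic_number=z1,
                    q_cation=qc, q_neutral=qn, q_anion=qa, scheme_tag=scheme,
                )
            )
        charges = tuple(charges)

    vibrations = None
    if freqs or dropped:
        vibrations = VibrationalSet(frequencies=tuple(freqs), dropped_imaginary=dropped)

    body = None
    if body_kv:
        if "molar_mass" not in body_kv:
            raise RecordError(f"{path}: rigid-body block lacks molecular mass")
        body = RigidBody(
            molar_mass=body_kv["molar_mass"],
            rotational_constants=body_kv.get("rot", ()),
            symmetry_number=body_kv.get("sigma", 1),
            pressure=body_kv.get("pressure", k.ATM_PA),
            electronic_degeneracy=body_kv.get("g", 1),
            linear=body_kv.get("linear", False),
        )

    return CompoundRecord(
        id=rid or "unnamed",
        formula=formula,
        orbitals=orbitals,
        charges=charges,
        vibrations=vibrations,
        body=body,
        provenance=provenance,
    )


# ------------------------------------------------------------ public API ----


def _check_format(fmt: str) -> None:
    if fmt not in FORMATS:
        raise RecordError(f"unknown format {fmt!r}; expected one of {FORMATS}")


def read_record(path, fmt: str = "record-json") -> CompoundRecord:
    """Read a validated CompoundRecord from *path* in the given format."""
    _check_format(fmt)
    path = Path(path)
    text = path.read_text()
    if fmt == "record-json":
        if not text.strip():
            raise RecordError(f"{path}: empty record file")
        try:
            d = json.loads(text)
        except json.JSONDecodeError as exc:
            raise RecordError(f"{path}: malformed JSON: {exc}") from None
        return record_from_dict(d)
    return _record_from_log(text, str(path))


def write_record(record: CompoundRecord, path, fmt: str = "record-json") -> Path:
    """Write *record* to *path*; read_record(write_record(r)) == r."""
    _check_format(fmt)
    path = Path(path)
    if fmt == "record-json":
        path.write_text(json.dumps(record_to_dict(record), indent=1) + "\n")
    else:
        path.write_text(_record_to_log(record))
    return path


# --------------------------------------------------------------- reports ----


def write_report(
    table: pd.DataFrame,
    path,
    fmt: str = "csv",
    metadata: dict | None = None,
) -> Path:
    """Serialize a result table to CSV (RFC 4180) or JSON.

    Column order is preserved as given (deterministic); a metadata
    mapping (constants versions, settings, rounding) is emitted as
    ``# key: value`` header comments in CSV and under a ``"metadata"``
    key in JSON. Values are written as-is — numeric rounding is the
    producing module's responsibility.
    """
    if fmt not in ("csv", "json"):
        raise RecordError(f"unknown report format {fmt!r}; expected 'csv' or 'json'")
    if table is None or len(table) == 0:
        raise RecordError("refusing to write an empty report table")
    path = Path(path)
    metadata = dict(metadata or {})
    if fmt == "csv":
        with open(path, "w", newline="") as fh:
            for key in sorted(metadata):
                fh.write(f"# {key}: {metadata[key]}\n")
            table.to_csv(fh, index=False)
    else:
        payload = {
            "metadata": metadata,
            "columns": list(table.columns),
            "rows": table.to_dict(orient="records"),
        }
        path.write_text(json.dumps(payload, indent=1, default=str) + "\n")
    return path


def read_report_values(path, fmt: str = "csv") -> pd.DataFrame:
    """Read back a report written by :func:`write_report` (values only)."""
    path = Path(path)
    if fmt == "csv":
        return pd.read_csv(path, comment="#")
    payload = json.loads(path.read_text())
    return pd.DataFrame(payload["rows"], columns=payload["columns"])
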