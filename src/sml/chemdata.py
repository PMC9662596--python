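"""Molecule and orbital-energy containers plus file I/O.

Energies are stored in electron-volts throughout the package; Hartree values
from quantum-chemistry output are converted once at ingest. Coordinates are
Cartesian ångström. Property tables associate a molecule id with HOMO, LUMO
and gap values at a named level of theory (e.g. "ZINDO", "GW", "B3LYP").
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

#: CODATA 2018 Hartree energy expressed in eV.
HARTREE_TO_EV = 27.211386245988

#: Tolerance (eV) for the gap = LUMO - HOMO identity of a PropertyRecord.
GAP_IDENTITY_TOL = 1e-6

_SYMBOL_TO_Z = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18, "K": 19, "Ca": 20, "Br": 35, "I": 53,
}
_Z_TO_SYMBOL = {z: s for s, z in _SYMBOL_TO_Z.items()}

#: Comment-line token layout used by :func:`write_extended_xyz`; pass this to
#: :func:`read_extended_xyz` to round-trip a dataset.
WRITER_PROPERTY_COLUMNS = {"id": 0, "homo": 1, "lumo": 2, "gap": 3}


class XYZParseError(ValueError):
    """Malformed XYZ/extended-XYZ input."""


def element_to_charge(symbol: str) -> int:
    try:
        return _SYMBOL_TO_Z[symbol]
    except KeyError as exc:
        raise ValueError(f"unknown element symbol: {symbol!r}") from exc


def hartree_to_ev(x):
    """Convert an energy (scalar or array) from Hartree to eV."""
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite energy passed to hartree_to_ev")
    out = arr * HARTREE_TO_EV
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


@dataclass
class Molecule:
    """A single structure: identity, optional SMILES, elements and geometry."""

    id: str
    smiles: str
    elements: list[str]
    coords: np.ndarray  # (N, 3) Å
    charges: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if not self.charges:
            self.charges = [element_to_charge(e) for e in self.elements]
        if not (len(self.elements) == len(self.coords) == len(self.charges)):
            raise ValueError(
                f"molecule {self.id!r}: elements/coords/charges lengths differ "
                f"({len(self.elements)}/{len(self.coords)}/{len(self.charges)})"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"molecule {self.id!r}: non-finite coordinates")
        for sym, z in zip(self.elements, self.charges):
            if element_to_charge(sym) != z:
                raise ValueError(
                    f"molecule {self.id!r}: charge {z} inconsistent with element {sym!r}"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.elements)


@dataclass
class PropertyRecord:
    """HOMO/LUMO/gap energies (eV) of one molecule at one level of theory."""

    molecule_id: str
    level: str
    homo: Optional[float] = None
    lumo: Optional[float] = None
    gap: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("homo", "lumo", "gap"):
            v = getattr(self, name)
            if v is not None:
                v = float(v)
                if not np.isfinite(v):
                    raise ValueError(
                        f"record {self.molecule_id!r}@{self.level}: non-finite {name}"
                    )
                setattr(self, name, v)
        if self.homo is not None and self.lumo is not None:
            if self.gap is None:
                self.gap = self.lumo - self.homo
            elif abs(self.gap - (self.lumo - self.homo)) > GAP_IDENTITY_TOL:
                raise ValueError(
                    f"record {self.molecule_id!r}@{self.level}: gap {self.gap} "
                    f"!= lumo - homo = {self.lumo - self.homo}"
                )
        if self.gap is None and (self.homo is None or self.lumo is None):
            raise ValueError(
                f"record {self.molecule_id!r}@{self.level}: needs a gap or both orbitals"
            )

    def get(self, prop: str) -> float:
        v = getattr(self, prop)
        if v is None:
            raise ValueError(
                f"record {self.molecule_id!r}@{self.level}: property {prop!r} absent"
            )
        return v


@dataclass
class Dataset:
    """Molecules plus property records keyed by (molecule id, level)."""

    molecules: list[Molecule] = field(default_factory=list)
    records: dict[tuple[str, str], PropertyRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [m.id for m in self.molecules]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate molecule ids: {dupes}")
        self._by_id = {m.id: m for m in self.molecules}
        for (mid, _level), rec in self.records.items():
            if mid not in self._by_id or rec.molecule_id != mid:
                raise ValueError(f"record for unknown molecule id {mid!r}")

    def __len__(self) -> int:
        return len(self.molecules)

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.molecules]

    def molecule(self, mid: str) -> Molecule:
        return self._by_id[mid]

    def add_molecule(self, mol: Molecule) -> None:
        if mol.id in self._by_id:
            raise ValueError(f"duplicate molecule id: {mol.id!r}")
        self.molecules.append(mol)
        self._by_id[mol.id] = mol

    def add_record(self, rec: PropertyRecord) -> None:
        if rec.molecule_id not in self._by_id:
            raise ValueError(f"record for unknown molecule id {rec.molecule_id!r}")
        self.records[(rec.molecule_id, rec.level)] = rec

    def levels(self) -> list[str]:
        return sorted({lvl for (_mid, lvl) in self.records})

    def record(self, mid: str, level: str) -> PropertyRecord:
        try:
            return self.records[(mid, level)]
        except KeyError as exc:
            raise KeyError(f"no record for molecule {mid!r} at level {level!r}") from exc

    def values(self, prop: str, level: str, ids: Optional[Sequence[str]] = None) -> np.ndarray:
        """Property values (eV) for the given ids (all molecules by default)."""
        ids = self.ids if ids is None else list(ids)
        return np.array([self.record(mid, level).get(prop) for mid in ids])


# ---------------------------------------------------------------------------
# XYZ / extended XYZ
# ---------------------------------------------------------------------------

def read_extended_xyz(
    path,
    property_columns: Optional[Mapping[str, int]] = None,
    level: Optional[str] = None,
    energy_unit: str = "eV",
) -> Dataset:
    """Read a multi-block (extended) XYZ file.

    Each block is an atom-count line, a comment line and one line per atom
    (``symbol x y z`` with extra columns ignored). ``property_columns`` maps
    names among {"id", "homo", "lumo", "gap"} to whitespace-token indices on
    the comment line, accommodating QM9-style dialects; energies are converted
    to eV when ``energy_unit="hartree"``. Molecules without an id column get
    ``"<filestem>_<block>"`` ids (0-based).
    """
    path = Path(path)
    if energy_unit not in ("eV", "hartree"):
        raise ValueError(f"unknown energy unit {energy_unit!r}")
    pc = dict(property_columns or {})
    want_props = [k for k in ("homo", "lumo", "gap") if k in pc]
    if want_props and level is None:
        raise ValueError("level must be given when property columns are mapped")

    lines = path.read_text().splitlines()
    ds = Dataset()
    i, block = 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError as exc:
            raise XYZParseError(
                f"{path.name}:{i + 1}: expected atom count, got {lines[i]!r}"
            ) from exc
        if i + 1 >= len(lines):
            raise XYZParseError(f"{path.name}:{i + 1}: truncated block (no comment line)")
        comment = lines[i + 1]
        atom_lines = lines[i + 2 : i + 2 + natoms]
        if len(atom_lines) < natoms:
            raise XYZParseError(
                f"{path.name}:{i + 1}: block declares {natoms} atoms but only "
                f"{len(atom_lines)} atom lines remain"
            )
        elements, coords = [], []
        for k, ln in enumerate(atom_lines):
            parts = ln.split()
            if len(parts) < 4:
                raise XYZParseError(
                    f"{path.name}:{i + 3 + k}: atom line needs symbol + 3 coordinates"
                )
            elements.append(parts[0])
            try:
                # QM9 files use Fortran-style exponents like 1.234*^-5
                coords.append([float(p.replace("*^", "e")) for p in parts[1:4]])
            except ValueError as exc:
                raise XYZParseError(
                    f"{path.name}:{i + 3 + k}: non-numeric coordinate in {ln!r}"
                ) from exc

        tokens = comment.split()
        if "id" in pc:
            mid = tokens[pc["id"]]
        else:
            mid = f"{path.stem}_{block}"
        mol = Molecule(id=mid, smiles="", elements=elements, coords=np.array(coords))
        ds.add_molecule(mol)

        if want_props:
            vals = {}
            for name in want_props:
                idx = pc[name]
                if idx >= len(tokens):
                    raise XYZParseError(
                        f"{path.name}:{i + 2}: comment line has no token {idx} for {name!r}"
                    )
                try:
                    v = float(tokens[idx].replace("*^", "e"))
                except ValueError as exc:
                    raise XYZParseError(
                        f"{path.name}:{i + 2}: non-numeric {name} field {tokens[idx]!r}"
                    ) from exc
                vals[name] = hartree_to_ev(v) if energy_unit == "hartree" else v
            ds.add_record(PropertyRecord(molecule_id=mid, level=level, **vals))
        i += 2 + natoms
        block += 1
    return ds


def write_extended_xyz(dataset: Dataset, path, level: Optional[str] = None) -> None:
    """Write a dataset as extended XYZ; comment line holds ``id homo lumo gap``
    (eV, blanks as ``nan``) when a record at ``level`` exists, else just the id.
    Round-trips with :func:`read_extended_xyz` and
    :data:`WRITER_PROPERTY_COLUMNS`.
    """
    path = Path(path)
    out = []
    for mol in dataset.molecules:
        out.append(str(mol.n_atoms))
        rec = dataset.records.get((mol.id, level)) if level is not None else None
        if rec is not None:
            fmt = lambda v: "nan" if v is None else f"{v:.12f}"
            out.append(f"{mol.id} {fmt(rec.homo)} {fmt(rec.lumo)} {fmt(rec.gap)}")
        else:
            out.append(mol.id)
        for sym, (x, y, z) in zip(mol.elements, mol.coords):
            out.append(f"{sym} {x:.10f} {y:.10f} {z:.10f}")
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Property tables (CSV / JSON lines)
# ---------------------------------------------------------------------------

def read_property_table(path, level: str, energy_unit: str = "eV") -> list[PropertyRecord]:
    """Read a property table (CSV, or JSON-lines for ``.json``/``.jsonl``).

    Requires an ``id`` column plus ``homo``+``lumo`` and/or ``gap``; the gap is
    filled in as LUMO − HOMO when absent. Duplicate ids and rows carrying
    neither a gap nor both orbitals are errors.
    """
    path = Path(path)
    if path.suffix.lower() in (".json", ".jsonl"):
        df = pd.read_json(path, lines=True)
    else:
        df = pd.read_csv(path)
    if "id" not in df.columns:
        raise ValueError(f"{path.name}: property table has no 'id' column")
    dupes = df["id"].astype(str)[df["id"].astype(str).duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"{path.name}: duplicate ids {dupes}")

    records = []
    for _, row in df.iterrows():
        vals = {}
        for name in ("homo", "lumo", "gap"):
            if name in df.columns and pd.notna(row[name]):
                v = float(row[name])
                vals[name] = hartree_to_ev(v) if energy_unit == "hartree" else v
        if "gap" not in vals and not ("homo" in vals and "lumo" in vals):
            raise ValueError(
                f"{path.name}: row {row['id']!r} has neither a gap nor both orbitals"
            )
        records.append(PropertyRecord(molecule_id=str(row["id"]), level=level, **vals))
    return records


def write_property_table(records: Iterable[PropertyRecord], path) -> None:
    """Write records as CSV with columns id, homo, lumo, gap (eV)."""
    rows = [
        {"id": r.molecule_id, "homo": r.homo, "lumo": r.lumo, "gap": r.gap}
        for r in records
    ]
    pd.DataFrame(rows, columns=["id", "homo", "lumo", "gap"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# SMILES lists
# ---------------------------------------------------------------------------

def read_smiles(path) -> list[tuple[str, str]]:
    """Read a SMILES list, one molecule per line as ``SMILES [id]``.

    Returns (smiles, id) pairs; missing ids become ``"<filestem>_<line>"``.
    """
    path = Path(path)
    out = []
    for i, line in enumerate(path.read_text().splitlines()):
        parts = line.split()
        if not parts or parts[0].startswith("#"):
            continue
        smi = parts[0]
        mid = parts[1] if len(parts) > 1 else f"{path.stem}_{i}"
        out.append((smi, mid))
    ids = [m for _, m in out]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path.name}: duplicate ids in SMILES list")
    return out


def write_smiles(pairs: Iterable[tuple[str, str]], path) -> None:
    Path(path).write_text("".join(f"{smi} {mid}\n" for smi, mid in pairs))
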