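"""Domain types and file I/O for complexes, trajectories and energy tables.

Structures travel as fixed-column PDB (3-decimal coordinates); trajectories as
multi-model PDB with one ``MODEL``/``ENDMDL`` block per frame and an optional
``REMARK TIME <ps>`` line per block; energy decompositions as tab-separated
tables with a header row. All writers emit a deterministic column and record
order so that regeneration from the same inputs is byte-identical.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal

import numpy as np
import pandas as pd

from .errors import (
    EnergyTableError,
    FrameError,
    PDBParseError,
    SelectionError,
    TopologyError,
)

log = logging.getLogger(__name__)

WATER_NAMES = {"HOH", "WAT"}
#: maximum covalent H-X distance used to attach hydrogens to heavy atoms
H_BOND_LINK_MAX = 1.2


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class Atom:
    """One atom; coordinates in Angstrom.

    ``parent_heavy`` links a hydrogen to its covalently bonded heavy atom
    (assigned by the nearest-neighbour rule, H-X <= 1.2 A, within the residue).
    """

    serial: int
    name: str
    element: str
    coords: np.ndarray
    is_hydrogen: bool = False
    parent_heavy: "Atom | None" = None
    formal_charge: int = 0
    residue: "Residue | None" = field(default=None, repr=False)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial} ({self.name}): bad coordinates")
        if self.is_hydrogen != (self.element.upper() == "H"):
            raise ValueError(
                f"atom {self.serial} ({self.name}): is_hydrogen inconsistent "
                f"with element {self.element!r}"
            )

    @property
    def residue_key(self) -> str:
        return self.residue.key if self.residue is not None else "?"


@dataclass(eq=False)
class Residue:
    chain_id: str
    seq_number: int
    name: str
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self):
        for a in self.atoms:
            a.residue = self

    def add(self, atom: Atom) -> Atom:
        atom.residue = self
        self.atoms.append(atom)
        return atom

    @property
    def key(self) -> str:
        """Display key, e.g. ``GLU917``; chain-qualified off the default chain."""
        base = f"{self.name}{self.seq_number}"
        return base if self.chain_id in ("", "A", " ") else f"{self.chain_id}:{base}"

    @property
    def is_water(self) -> bool:
        return self.name in WATER_NAMES

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]


class Complex:
    """An annotated protein + ligand + waters system.

    Canonical atom order (used by writers and trajectory frames) is: protein
    residues in input order, then the ligand, then waters.
    """

    def __init__(
        self,
        protein_residues: list[Residue],
        ligand: Residue,
        waters: list[Residue] | None = None,
    ):
        self.protein_residues = list(protein_residues)
        self.ligand = ligand
        self.waters = list(waters or [])
        self.annotations = None  # PerceivedChemistry, set by perception.perceive
        self.termini_ionized = False
        self._validate()

    def _validate(self) -> None:
        seen_keys: set[tuple[str, int]] = set()
        for res in self.residues():
            k = (res.chain_id, res.seq_number)
            if k in seen_keys:
                raise ValueError(f"duplicate residue (chain, seq) = {k}")
            seen_keys.add(k)
        serials = [a.serial for a in self.atoms()]
        if len(serials) != len(set(serials)):
            raise ValueError("atom serials not unique within complex")
        if self.ligand in self.protein_residues or self.ligand in self.waters:
            raise ValueError("ligand residue must be disjoint from protein/waters")

    def residues(self) -> Iterator[Residue]:
        yield from self.protein_residues
        yield self.ligand
        yield from self.waters

    def atoms(self) -> Iterator[Atom]:
        for res in self.residues():
            yield from res.atoms

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms()], dtype=float)

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError(f"expected coords of shape {(self.n_atoms, 3)}")
        for atom, row in zip(self.atoms(), coords):
            atom.coords = row.copy()

    def find_residue(self, key: str) -> Residue:
        for res in self.residues():
            if res.key == key:
                return res
        raise KeyError(f"unknown residue key {key!r}")

    def protein_chains(self) -> dict[str, list[Residue]]:
        chains: dict[str, list[Residue]] = {}
        for res in self.protein_residues:
            chains.setdefault(res.chain_id, []).append(res)
        return chains


@dataclass
class Trajectory:
    """Ordered coordinate frames over a fixed topology; times in ps."""

    topology: Complex
    frames: list[np.ndarray]
    times: list[float]

    def __post_init__(self):
        n = self.topology.n_atoms
        for i, f in enumerate(self.frames):
            f = np.asarray(f, dtype=float)
            if f.shape != (n, 3):
                raise FrameError(f"frame {i}: expected {n} atoms, got {f.shape[0]}")
            self.frames[i] = f
        if len(self.times) != len(self.frames):
            raise FrameError("times and frames length mismatch")
        if any(t2 <= t1 for t1, t2 in zip(self.times, self.times[1:])):
            raise FrameError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class SaptRecord:
    """Per ligand-residue SAPT0 components, kcal/mol.

    The four physically meaningful terms are electrostatics, exchange
    repulsion, induction and dispersion; an optional stored total is kept for
    consistency checking against the component sum.
    """

    ligand_id: str
    residue_key: str
    e_elst: float
    e_exch: float
    e_ind: float
    e_disp: float
    e_total: float | None = None

    COMPONENTS = ("e_elst", "e_exch", "e_ind", "e_disp")


@dataclass
class PiedaRecord:
    """Per ligand-residue PIEDA (FMO-EDA) components, kcal/mol.

    Components: electrostatic (E_es), exchange (E_ex), charge-transfer+mixed
    (E_CT+mix), dispersion (E_disp) and solvation free energy (G_sol).
    Stored-total consistency is report-only, never fatal.
    """

    ligand_id: str
    residue_key: str
    e_es: float
    e_ex: float
    e_ct_mix: float
    e_disp: float
    g_sol: float
    e_tot: float | None = None

    COMPONENTS = ("e_es", "e_ex", "e_ct_mix", "e_disp", "g_sol")


@dataclass
class EnthalpyRecord:
    """Heats of formation (kcal/mol) for the thermodynamic-cycle enthalpy."""

    ligand_id: str
    hf_complex: float
    hf_protein_in_complex: float
    hf_ligand_in_complex: float

    def __post_init__(self):
        for f in ("hf_complex", "hf_protein_in_complex", "hf_ligand_in_complex"):
            if not math.isfinite(getattr(self, f)):
                raise ValueError(f"{f} must be finite")


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

_ELEMENT_CHARGES = {"1+": 1, "2+": 2, "1-": -1, "2-": -2, "+1": 1, "-1": -1}


def _parse_atom_line(line: str, line_no: int):
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16:17].strip()
        resname = line[17:20].strip()
        chain = line[21:22].strip()
        seq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"unparsable ATOM/HETATM record: {exc}", line_no) from exc
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        stripped = "".join(ch for ch in name if ch.isalpha())
        element = stripped[:1].upper() if stripped else "X"
        # two-letter elements common in pockets
        if stripped[:2].upper() in ("CL", "BR", "FE", "ZN", "MG", "NA"):
            element = stripped[:2].capitalize()
    charge = 0
    if len(line) >= 80:
        charge = _ELEMENT_CHARGES.get(line[78:80].strip(), 0)
    return serial, name, altloc, resname, chain, seq, (x, y, z), element, charge


def _link_hydrogens(residue: Residue) -> None:
    heavies = residue.heavy_atoms()
    for h in residue.atoms:
        if not h.is_hydrogen:
            continue
        best, best_d = None, H_BOND_LINK_MAX
        for x in heavies:
            d = float(np.linalg.norm(h.coords - x.coords))
            if d <= best_d:
                best, best_d = x, d
        if best is None:
            raise TopologyError(
                f"hydrogen {h.name} (serial {h.serial}) in {residue.key} has no "
                f"heavy atom within {H_BOND_LINK_MAX} A"
            )
        h.parent_heavy = best


def _iter_pdb_atoms(lines: Iterable[str]):
    """Yield (line_no, parsed) for ATOM/HETATM records, applying altloc policy."""
    for i, line in enumerate(lines, start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        parsed = _parse_atom_line(line, i)
        altloc = parsed[2]
        if altloc not in ("", "A"):
            log.warning("dropping altloc %r at line %d", altloc, i)
            continue
        yield i, parsed


def _group_residues(parsed_atoms) -> list[Residue]:
    residues: list[Residue] = []
    index: dict[tuple[str, int, str], Residue] = {}
    for _line_no, p in parsed_atoms:
        serial, name, _alt, resname, chain, seq, xyz, element, charge = p
        key = (chain, seq, resname)
        res = index.get(key)
        if res is None:
            res = Residue(chain_id=chain, seq_number=seq, name=resname)
            index[key] = res
            residues.append(res)
        res.add(
            Atom(
                serial=serial,
                name=name,
                element=element,
                coords=np.array(xyz),
                is_hydrogen=element.upper() == "H",
                formal_charge=charge,
            )
        )
    return residues


def _match_selector(res: Residue, ligand_selector: str) -> bool:
    if ":" in ligand_selector:
        chain, seq = ligand_selector.split(":", 1)
        return res.chain_id == chain and str(res.seq_number) == seq
    return res.name == ligand_selector


def read_complex(path: str | Path, ligand_selector: str) -> Complex:
    """Read a PDB file and partition it into protein / ligand / waters.

    ``ligand_selector`` is either a residue name (``"LIG"``) or a
    chain-qualified sequence number (``"A:900"``) and must match exactly one
    non-water residue. Hydrogens are linked to their parent heavy atoms by the
    nearest-covalent-distance rule (H-X <= 1.2 A).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    residues = _group_residues(_iter_pdb_atoms(lines))
    n_in = sum(len(r.atoms) for r in residues)

    matches = [r for r in residues if _match_selector(r, ligand_selector)]
    if len(matches) != 1:
        raise SelectionError(
            f"ligand selector {ligand_selector!r} matched {len(matches)} residues"
        )
    ligand = matches[0]
    if ligand.is_water:
        raise SelectionError("ligand selector matched a water residue")

    protein = [r for r in residues if r is not ligand and not r.is_water]
    waters = [r for r in residues if r is not ligand and r.is_water]

    complex_ = Complex(protein_residues=protein, ligand=ligand, waters=waters)
    if complex_.n_atoms != n_in:
        raise PDBParseError(
            f"partitioning lost atoms: {n_in} read, {complex_.n_atoms} kept"
        )
    for res in complex_.residues():
        _link_hydrogens(res)
    return complex_


# ---------------------------------------------------------------------------
# PDB writing
# ---------------------------------------------------------------------------

def _format_atom_line(atom: Atom, serial: int, hetatm: bool) -> str:
    res = atom.residue
    name = atom.name
    # PDB name column convention: 1-letter elements start at column 14
    if len(name) < 4 and len(atom.element) == 1:
        name = f" {name}"
    record = "HETATM" if hetatm else "ATOM  "
    charge = ""
    if atom.formal_charge:
        charge = f"{abs(atom.formal_charge)}{'+' if atom.formal_charge > 0 else '-'}"
    return (
        f"{record}{serial:>5d} {name:<4s}{'':1s}{res.name:>3s} {res.chain_id or 'A':1s}"
        f"{res.seq_number:>4d}    "
        f"{atom.coords[0]:8.3f}{atom.coords[1]:8.3f}{atom.coords[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}{charge:<2s}"
    ).rstrip()


def _complex_atom_lines(complex_: Complex) -> list[str]:
    out, serial = [], 0
    for res in complex_.protein_residues:
        for atom in res.atoms:
            serial += 1
            out.append(_format_atom_line(atom, serial, hetatm=False))
    for res in [complex_.ligand, *complex_.waters]:
        for atom in res.atoms:
            serial += 1
            out.append(_format_atom_line(atom, serial, hetatm=True))
    return out


def write_complex(complex_: Complex, path: str | Path, remarks: list[str] | None = None) -> None:
    """Write a Complex as fixed-column PDB (deterministic, 3-decimal coords)."""
    lines = [f"REMARK   6 {r}" for r in (remarks or [])]
    lines += _complex_atom_lines(complex_)
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_trajectory(traj: Trajectory, path: str | Path, remarks: list[str] | None = None) -> None:
    lines = [f"REMARK   6 {r}" for r in (remarks or [])]
    base = traj.topology.coords_array()
    for i, (frame, t) in enumerate(zip(traj.frames, traj.times), start=1):
        lines.append(f"MODEL {i:>8d}")
        lines.append(f"REMARK   6 TIME {t:.3f}")
        traj.topology.set_coords(frame)
        lines += _complex_atom_lines(traj.topology)
        lines.append("ENDMDL")
    traj.topology.set_coords(base)
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_trajectory(path: str | Path, topology: Complex) -> Trajectory:
    """Read a multi-model PDB into a Trajectory over ``topology``.

    Each MODEL block must contain exactly the topology's atom count in the
    same order. Frame times come from a per-model ``REMARK ... TIME <ps>``
    line, defaulting to 0, 1, 2, ... ps.
    """
    n = topology.n_atoms
    frames: list[np.ndarray] = []
    times: list[float] = []
    in_model = False
    current: list[tuple[float, float, float]] = []
    current_time: float | None = None
    model_idx = 0
    saw_model = False

    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if line.startswith("MODEL"):
            saw_model = True
            in_model = True
            model_idx += 1
            current, current_time = [], None
        elif line.startswith("ENDMDL"):
            if len(current) != n:
                raise FrameError(
                    f"model {model_idx}: expected {n} atoms, got {len(current)}"
                )
            frames.append(np.array(current))
            times.append(current_time if current_time is not None else float(len(times)))
            in_model = False
        elif line.startswith("REMARK") and "TIME" in line and in_model:
            try:
                current_time = float(line.split("TIME", 1)[1].split()[0])
            except (ValueError, IndexError):
                raise PDBParseError("bad REMARK TIME record", line_no)
        elif line.startswith(("ATOM", "HETATM")):
            p = _parse_atom_line(line, line_no)
            if p[2] not in ("", "A"):
                continue
            current.append(p[6])

    if not saw_model:
        # single-frame file without MODEL records
        if len(current) != n:
            raise FrameError(f"model 1: expected {n} atoms, got {len(current)}")
        frames.append(np.array(current))
        times.append(0.0)
    return Trajectory(topology=topology, frames=frames, times=times)


# ---------------------------------------------------------------------------
# energy tables
# ---------------------------------------------------------------------------

Schema = Literal["sapt", "pieda", "enthalpy"]

_SCHEMAS = {
    "sapt": {
        "cls": SaptRecord,
        "key_cols": ("ligand", "residue"),
        "components": SaptRecord.COMPONENTS,
        "total": "e_total",
    },
    "pieda": {
        "cls": PiedaRecord,
        "key_cols": ("ligand", "residue"),
        "components": PiedaRecord.COMPONENTS,
        "total": "e_tot",
    },
    "enthalpy": {
        "cls": EnthalpyRecord,
        "key_cols": ("ligand",),
        "components": ("hf_complex", "hf_protein_in_complex", "hf_ligand_in_complex"),
        "total": None,
    },
}


def read_energy_table(path: str | Path, schema: str):
    """Read a tab-separated energy table into a list of records.

    Columns: key columns (``ligand`` and, except for enthalpy, ``residue``),
    the schema's component columns, and an optional total column. Rows with a
    non-numeric component raise :class:`EnergyTableError` naming the row.
    """
    if schema not in _SCHEMAS:
        raise EnergyTableError(f"unknown schema {schema!r}; expected sapt|pieda|enthalpy")
    spec = _SCHEMAS[schema]
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise EnergyTableError(f"{path}: empty file (no header)")
    missing = [c for c in (*spec["key_cols"], *spec["components"]) if c not in df.columns]
    if missing:
        raise EnergyTableError(f"{path}: missing columns {missing}")

    has_total = spec["total"] is not None and spec["total"] in df.columns
    records = []
    for i, row in df.iterrows():
        values = {}
        for col in spec["components"]:
            try:
                values[col] = float(row[col])
            except (TypeError, ValueError):
                raise EnergyTableError(
                    f"{path}: row {i}: non-numeric value {row[col]!r} in column {col}"
                )
        total = None
        if has_total:
            raw = row[spec["total"]]
            if raw is not None and not (isinstance(raw, float) and math.isnan(raw)) and str(raw).strip() not in ("", "nan"):
                try:
                    total = float(raw)
                except ValueError:
                    raise EnergyTableError(
                        f"{path}: row {i}: non-numeric total {raw!r}"
                    )
        kwargs = {"ligand_id": str(row["ligand"])}
        if "residue" in spec["key_cols"]:
            kwargs["residue_key"] = str(row["residue"])
        kwargs.update(values)
        if spec["total"] is not None:
            kwargs[spec["total"]] = total
        records.append(spec["cls"](**kwargs))
    return records


def write_energy_table(records, path: str | Path, schema: str) -> None:
    """Write records as a tab-separated table (deterministic column order)."""
    if schema not in _SCHEMAS:
        raise EnergyTableError(f"unknown schema {schema!r}")
    spec = _SCHEMAS[schema]
    cols = ["ligand"]
    if "residue" in spec["key_cols"]:
        cols.append("residue")
    cols += list(spec["components"])
    if spec["total"] is not None:
        cols.append(spec["total"])
    rows = []
    for rec in records:
        row = {"ligand": rec.ligand_id}
        if "residue" in spec["key_cols"]:
            row["residue"] = rec.residue_key
        for c in spec["components"]:
            row[c] = f"{getattr(rec, c):.3f}"
        if spec["total"] is not None:
            tot = getattr(rec, spec["total"])
            row[spec["total"]] = "" if tot is None else f"{tot:.3f}"
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
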