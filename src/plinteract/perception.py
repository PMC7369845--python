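"""Chemical-role perception: donors/acceptors, rings, charges, hydrophobics.

Protein roles come from a fixed per-residue lookup over the 20 standard amino
acids plus water. Ligand roles are derived from element and connectivity
heuristics on a distance-based bond graph:

* N/O/S bearing an explicit hydrogen -> H-bond donor;
* N with no hydrogen, <=2 heavy neighbours and no positive formal charge
  (pyridinic), any O (carbonyl, sulfonyl, hydroxyl, ether), and divalent
  H-free S -> acceptor;
* 5/6-membered planar rings of C/N/S -> aromatic (RMS out-of-plane <= 0.1 A);
* carbons bonded only to C/H/S -> hydrophobic.

These heuristics deliberately stop short of bond-order perception, tautomers
or pKa models; ligand formal charges are read from the input annotations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import yaml
from scipy.spatial import cKDTree

from .geometry import plane_fit
from .model_io import Atom, Complex, Residue

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# options
# ---------------------------------------------------------------------------

@dataclass
class PerceptionOptions:
    """Tunables for role perception.

    ``explicit_h``: donors require explicit hydrogens (the only supported
    donor mode; with no hydrogens on a polar atom a warning is logged).
    ``his_protonated``: treat histidine as a +1 charged group instead of a
    neutral ND1/NE2 acceptor.
    ``planarity_tol``: max RMS out-of-plane deviation (A) for a ligand ring
    to count as aromatic.
    ``bond_max``: heavy-heavy covalent cutoff (A) for the ligand bond graph;
    pairs involving S use ``bond_max_s``.
    """

    explicit_h: bool = True
    his_protonated: bool = False
    planarity_tol: float = 0.1
    bond_max: float = 1.75
    bond_max_s: float = 1.95

    @classmethod
    def from_file(cls, path: str | Path) -> "PerceptionOptions":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


# ---------------------------------------------------------------------------
# perceived-chemistry containers
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class AromaticRing:
    """A planar ring: ordered member cycle, centroid, unit normal."""

    member_atoms: list[Atom]
    centroid: np.ndarray = field(default=None)
    normal: np.ndarray = field(default=None)
    planarity_rms: float = 0.0

    def __post_init__(self):
        if len(self.member_atoms) < 5:
            raise ValueError("aromatic ring needs >=5 members")
        self.refresh()

    def refresh(self) -> None:
        coords = np.array([a.coords for a in self.member_atoms])
        self.centroid, self.normal, self.planarity_rms = plane_fit(coords)

    @property
    def residue(self) -> Residue:
        return self.member_atoms[0].residue

    @property
    def label(self) -> str:
        return "ring(" + "-".join(a.name for a in self.member_atoms) + ")"


@dataclass(eq=False)
class ChargedGroup:
    """A formally charged group; ``site`` is the representative position
    (single charged atom, or the O/N midpoint for carboxylate/guanidinium)."""

    atoms: list[Atom]
    sign: int
    site_atoms: list[Atom]

    def __post_init__(self):
        if self.sign not in (+1, -1):
            raise ValueError("sign must be +1 or -1")

    @property
    def site(self) -> np.ndarray:
        return np.mean([a.coords for a in self.site_atoms], axis=0)

    @property
    def residue(self) -> Residue:
        return self.atoms[0].residue

    @property
    def label(self) -> str:
        return "group(" + "-".join(a.name for a in self.atoms) + ")"


@dataclass
class PerceivedChemistry:
    """All roles the geometric interaction criteria consume."""

    donors: list[tuple[Atom, Atom]] = field(default_factory=list)
    acceptors: dict[Atom, list[Atom]] = field(default_factory=dict)
    rings: list[AromaticRing] = field(default_factory=list)
    pos_charges: list[ChargedGroup] = field(default_factory=list)
    neg_charges: list[ChargedGroup] = field(default_factory=list)
    hydrophobic_atoms: set[Atom] = field(default_factory=set)

    def charges(self, sign: int) -> list[ChargedGroup]:
        return self.pos_charges if sign > 0 else self.neg_charges

    def refresh_geometry(self) -> None:
        """Recompute coordinate-derived quantities (ring planes) in place.

        Role membership is topological and survives coordinate updates;
        centroids/normals do not. Charged-group sites are computed lazily
        from current coordinates and need no refresh.
        """
        for ring in self.rings:
            ring.refresh()


# ---------------------------------------------------------------------------
# protein role lookup
# ---------------------------------------------------------------------------

# sidechain acceptor atom -> its bonded heavy neighbour(s) X (for the
# acceptor-angle test H...A-X)
_SIDECHAIN_ACCEPTORS: dict[str, dict[str, tuple[str, ...]]] = {
    "ASP": {"OD1": ("CG",), "OD2": ("CG",)},
    "GLU": {"OE1": ("CD",), "OE2": ("CD",)},
    "SER": {"OG": ("CB",)},
    "THR": {"OG1": ("CB",)},
    "TYR": {"OH": ("CZ",)},
    "ASN": {"OD1": ("CG",)},
    "GLN": {"OE1": ("CD",)},
    "HIS": {"ND1": ("CG", "CE1"), "NE2": ("CD2", "CE1")},
    "MET": {"SD": ("CG", "CE")},
}

_RING_DEFS: dict[str, list[tuple[str, ...]]] = {
    "PHE": [("CG", "CD1", "CE1", "CZ", "CE2", "CD2")],
    "TYR": [("CG", "CD1", "CE1", "CZ", "CE2", "CD2")],
    "HIS": [("CG", "ND1", "CE1", "NE2", "CD2")],
    "TRP": [
        ("CG", "CD1", "NE1", "CE2", "CD2"),
        ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"),
    ],
}

# charged sidechains: (sign, site atom names)
_CHARGE_DEFS: dict[str, tuple[int, tuple[str, ...]]] = {
    "LYS": (+1, ("NZ",)),
    "ARG": (+1, ("NH1", "NH2")),
    "ASP": (-1, ("OD1", "OD2")),
    "GLU": (-1, ("OE1", "OE2")),
}

# hydrophobic sidechain atoms: C/S in apolar contexts
_HYDROPHOBIC_DEFS: dict[str, tuple[str, ...]] = {
    "ALA": ("CB",),
    "VAL": ("CB", "CG1", "CG2"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "PRO": ("CB", "CG", "CD"),
    "MET": ("CB", "CG", "SD", "CE"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CB", "CG", "CD1", "CD2", "CE3", "CZ2", "CZ3", "CH2", "CE2"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2"),
    "CYS": ("SG",),
}

_STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def _perceive_protein_residue(res: Residue, chem: PerceivedChemistry,
                              options: PerceptionOptions) -> None:
    name = res.name
    # donors: any H whose parent is N/O/S (covers backbone NH and sidechains)
    for a in res.atoms:
        if a.is_hydrogen and a.parent_heavy is not None and \
                a.parent_heavy.element.upper() in ("N", "O", "S"):
            chem.donors.append((a.parent_heavy, a))
    # backbone carbonyl + terminal carboxylate oxygens accept
    for oname in ("O", "OXT"):
        o = res.atom(oname)
        c = res.atom("C")
        if o is not None:
            chem.acceptors[o] = [c] if c is not None else []
    # sidechain acceptors
    for aname, xnames in _SIDECHAIN_ACCEPTORS.get(name, {}).items():
        if name == "HIS" and options.his_protonated:
            continue
        a = res.atom(aname)
        if a is not None:
            chem.acceptors[a] = [x for x in (res.atom(n) for n in xnames) if x is not None]
    # rings
    for ring_names in _RING_DEFS.get(name, []):
        atoms = [res.atom(n) for n in ring_names]
        if all(a is not None for a in atoms):
            chem.rings.append(AromaticRing(member_atoms=atoms))
    # charges
    charge_defs = dict(_CHARGE_DEFS)
    if options.his_protonated:
        charge_defs["HIS"] = (+1, ("ND1", "NE2"))
    if name in charge_defs:
        sign, site_names = charge_defs[name]
        site_atoms = [a for a in (res.atom(n) for n in site_names) if a is not None]
        if site_atoms:
            chem.charges(sign).append(
                ChargedGroup(atoms=site_atoms, sign=sign, site_atoms=site_atoms)
            )
    # hydrophobics
    for aname in _HYDROPHOBIC_DEFS.get(name, ()):
        a = res.atom(aname)
        if a is not None:
            chem.hydrophobic_atoms.add(a)


# ---------------------------------------------------------------------------
# ligand perception
# ---------------------------------------------------------------------------

def ligand_bond_graph(res: Residue, options: PerceptionOptions) -> nx.Graph:
    """Distance-based heavy-atom bond graph for a ligand residue."""
    heavies = res.heavy_atoms()
    g = nx.Graph()
    g.add_nodes_from(heavies)
    if len(heavies) < 2:
        return g
    coords = np.array([a.coords for a in heavies])
    tree = cKDTree(coords)
    for i, j in tree.query_pairs(max(options.bond_max, options.bond_max_s)):
        a, b = heavies[i], heavies[j]
        cutoff = options.bond_max_s if "S" in (a.element.upper(), b.element.upper()) \
            else options.bond_max
        if float(np.linalg.norm(a.coords - b.coords)) <= cutoff:
            g.add_edge(a, b)
    return g


def _ordered_cycle(g: nx.Graph, nodes: list[Atom]) -> list[Atom]:
    """Canonically order a cycle-basis node set: start at the lowest-serial
    member and walk toward its lower-serial ring neighbour (deterministic
    regardless of set iteration order)."""
    sub = g.subgraph(nodes)
    start = min(nodes, key=lambda a: a.serial)
    first_neighbours = sorted(sub.neighbors(start), key=lambda a: a.serial)
    if not first_neighbours:
        return sorted(nodes, key=lambda a: a.serial)
    order = [start, first_neighbours[0]]
    while len(order) < len(nodes):
        neighbours = [n for n in sub.neighbors(order[-1]) if n is not order[-2]]
        if not neighbours:
            return sorted(nodes, key=lambda a: a.serial)  # not a simple cycle
        order.append(min(neighbours, key=lambda a: a.serial))
    return order


def _perceive_ligand(res: Residue, chem: PerceivedChemistry,
                     options: PerceptionOptions) -> None:
    g = ligand_bond_graph(res, options)
    h_count = {a: 0 for a in res.heavy_atoms()}
    for a in res.atoms:
        if a.is_hydrogen and a.parent_heavy is not None:
            h_count[a.parent_heavy] = h_count.get(a.parent_heavy, 0) + 1
            if a.parent_heavy.element.upper() in ("N", "O", "S"):
                chem.donors.append((a.parent_heavy, a))
    polar_unprotonated = [
        a for a in res.heavy_atoms()
        if a.element.upper() in ("N", "O") and h_count.get(a, 0) == 0
    ]
    if options.explicit_h and not any(a.is_hydrogen for a in res.atoms) and polar_unprotonated:
        log.warning(
            "ligand %s has polar atoms but no explicit hydrogens; "
            "no ligand donors will be perceived", res.key,
        )
    for a in res.heavy_atoms():
        el = a.element.upper()
        neighbours = list(g.neighbors(a))
        if el == "O":
            chem.acceptors[a] = neighbours
        elif el == "N" and h_count.get(a, 0) == 0 and len(neighbours) <= 2 \
                and a.formal_charge <= 0:
            chem.acceptors[a] = neighbours
        elif el == "S" and h_count.get(a, 0) == 0 and len(neighbours) <= 2:
            chem.acceptors[a] = neighbours
        if el == "C" and all(n.element.upper() in ("C", "S") for n in neighbours):
            chem.hydrophobic_atoms.add(a)
        if a.formal_charge != 0:
            sign = 1 if a.formal_charge > 0 else -1
            chem.charges(sign).append(ChargedGroup(atoms=[a], sign=sign, site_atoms=[a]))
    # planar 5/6-membered rings of C/N/S (deterministic member/ring order)
    candidates = []
    for cyc in nx.minimum_cycle_basis(g):
        if len(cyc) not in (5, 6):
            continue
        if any(a.element.upper() not in ("C", "N", "S") for a in cyc):
            continue
        ordered = _ordered_cycle(g, list(cyc))
        ring = AromaticRing(member_atoms=ordered)
        if ring.planarity_rms <= options.planarity_tol:
            candidates.append(ring)
    candidates.sort(key=lambda r: tuple(sorted(a.serial for a in r.member_atoms)))
    chem.rings.extend(candidates)


def _perceive_water(res: Residue, chem: PerceivedChemistry) -> None:
    o = next((a for a in res.atoms if a.element.upper() == "O"), None)
    if o is None:
        return
    for a in res.atoms:
        if a.is_hydrogen and a.parent_heavy is o:
            chem.donors.append((o, a))
    chem.acceptors[o] = []  # no heavy neighbour: acceptor-angle test is vacuous


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def perceive(complex_: Complex, options: PerceptionOptions | None = None) -> Complex:
    """Annotate ``complex_`` with a :class:`PerceivedChemistry` (idempotent)."""
    options = options or PerceptionOptions()
    chem = PerceivedChemistry()
    for res in complex_.protein_residues:
        if res.name in _STANDARD_AA:
            _perceive_protein_residue(res, chem, options)
        else:
            _perceive_ligand(res, chem, options)  # non-standard: heuristics
    _perceive_ligand(complex_.ligand, chem, options)
    for res in complex_.waters:
        _perceive_water(res, chem)
    if complex_.termini_ionized:
        _add_termini_charges(complex_, chem)
    complex_.annotations = chem
    return complex_


def _add_termini_charges(complex_: Complex, chem: PerceivedChemistry) -> None:
    for _chain, residues in complex_.protein_chains().items():
        first, last = residues[0], residues[-1]
        n = first.atom("N")
        if n is not None:
            chem.pos_charges.append(ChargedGroup(atoms=[n], sign=+1, site_atoms=[n]))
        site = [a for a in (last.atom("OXT"), last.atom("O")) if a is not None]
        if site:
            chem.neg_charges.append(
                ChargedGroup(atoms=site, sign=-1, site_atoms=site)
            )


def ionize_termini(complex_: Complex) -> Complex:
    """Ionise chain termini: first residue gains NH3+ at the backbone N, last
    gains COO- at the carboxylate (O/OXT midpoint). Idempotent; a
    single-residue chain carries both charges."""
    if complex_.termini_ionized:
        return complex_
    complex_.termini_ionized = True
    if complex_.annotations is not None:
        _add_termini_charges(complex_, complex_.annotations)
    return complex_


def extract_pocket(complex_: Complex, radius: float) -> Complex:
    """Binding-sphere truncation: keep whole protein residues (and waters)
    with any atom within ``radius`` A of any ligand atom; the ligand is
    always kept. The returned Complex carries no annotations (re-perceive)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    lig_coords = np.array([a.coords for a in complex_.ligand.atoms])
    tree = cKDTree(lig_coords)

    def near(res: Residue) -> bool:
        d, _ = tree.query(np.array([a.coords for a in res.atoms]), k=1)
        return bool(np.min(d) <= radius)

    pocket = Complex(
        protein_residues=[r for r in complex_.protein_residues if near(r)],
        ligand=complex_.ligand,
        waters=[w for w in complex_.waters if near(w)],
    )
    return pocket
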