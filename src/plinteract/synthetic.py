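"""Ground-truth synthetic fixtures: toy pockets with interactions planted at
exact geometries, jittered multi-frame trajectories with prescribed
per-contact Bernoulli occupancy, and energy tables with known totals.

These scenes are the statistical stand-in for undeposited docked poses, MD
trajectories and quantum-chemical output tables: every detector can be scored
against an enumerable truth. Plants are constructed analytically (e.g. a
hydrogen bond is laid out with the exact requested donor-acceptor distance
and angles; a stack is two regular hexagons at the requested centroid offset
and tilt), spaced >= 8 A apart so classes cannot cross-talk, and a chemically
quiet decoy background can be added around them. Everything is a pure
function of (spec, seed): regeneration is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GenerationError, ParameterError
from .model_io import (
    Atom,
    Complex,
    EnthalpyRecord,
    PiedaRecord,
    Residue,
    SaptRecord,
    Trajectory,
)
from .geometry import rotation_matrix

#: spacing between consecutive plant sites along z (>= the 8 A exclusion)
PLANT_SPACING = 14.0
#: how far ligand-side atoms are pushed (away from the protein partner) in an
#: "off" frame; leaves every criterion broken by >= 1.5 A
OFF_DISPLACEMENT = 4.0
#: largest background jitter that still keeps planted geometries inside
#: their criteria with comfortable margin
JITTER_SD_MAX = 0.05

_X = np.array([1.0, 0.0, 0.0])
_Y = np.array([0.0, 1.0, 0.0])
_Z = np.array([0.0, 0.0, 1.0])

PLANT_KINDS = (
    "hbond",
    "hbond_contact_docking",
    "water_bridge",
    "pi_pi",
    "pi_cation",
    "hydrophobic",
    "ionic",
)

_DEFAULT_GEOMETRY: dict[str, dict[str, float]] = {
    "hbond": {"distance": 2.30, "donor_angle": 180.0, "acceptor_angle": 120.0},
    "hbond_contact_docking": {"distance": 2.80},
    "water_bridge": {"distance": 2.50, "distance2": 2.50},
    "pi_pi": {"distance": 3.70, "angle": 0.0},
    "pi_cation": {"distance": 4.00},
    "hydrophobic": {"distance": 3.40},
    "ionic": {"distance": 3.40},
}

_DEFAULT_RESIDUE: dict[str, str] = {
    "hbond": "GLU",
    "hbond_contact_docking": "GLU",
    "water_bridge": "GLU",
    "pi_pi": "PHE",
    "pi_cation": "LYS",
    "hydrophobic": "LEU",
    "ionic": "GLU",
}


@dataclass
class PlantSpec:
    """One interaction to plant.

    ``geometry_params`` override the kind's default exact geometry; with
    ``negate=True`` the primary distance is pushed 0.3 A past its criterion
    (unless explicitly overridden) and the plant is excluded from the truth.
    ``occupancy_p`` is the per-frame Bernoulli presence probability used by
    :func:`build_trajectory`.
    """

    kind: str
    residue_name: str | None = None
    seq_number: int | None = None
    geometry_params: dict[str, float] = field(default_factory=dict)
    jitter_sd: float = 0.0
    occupancy_p: float = 1.0
    negate: bool = False

    def __post_init__(self):
        if self.kind not in PLANT_KINDS:
            raise ValueError(f"unknown plant kind {self.kind!r}")
        if not (0.0 <= self.occupancy_p <= 1.0):
            raise ValueError("occupancy_p must be in [0, 1]")

    def resolved_geometry(self) -> dict[str, float]:
        geo = dict(_DEFAULT_GEOMETRY[self.kind])
        geo.update(self.geometry_params)
        if self.negate and "distance" not in self.geometry_params:
            geo["distance"] = geo["distance"] + _NEGATE_PUSH[self.kind]
        return geo


#: distance push that takes each kind's default past its inclusive criterion
_NEGATE_PUSH = {
    "hbond": 0.3,
    "hbond_contact_docking": 0.5,
    "water_bridge": 0.4,
    "pi_pi": 0.8,
    "pi_cation": 0.6,
    "hydrophobic": 0.3,
    "ionic": 0.4,
}


@dataclass
class BuiltPlant:
    spec: PlantSpec
    protein_residue: Residue | None
    ligand_atoms: list[Atom]
    water: Residue | None
    #: expected (kind, protein residue key) detections, empty when negated
    truth: list[tuple[str, str]]
    #: unit vector along which ligand atoms move in an "off" frame
    off_axis: np.ndarray


@dataclass
class SyntheticScene:
    complex: Complex
    plants: list[BuiltPlant]
    seed: int

    def truth_by_kind(self) -> dict[str, set[tuple[str, str]]]:
        out: dict[str, set] = {k: set() for k in PLANT_KINDS}
        for plant in self.plants:
            for kind, key in plant.truth:
                out[kind].add((key, kind))
        return out


# ---------------------------------------------------------------------------
# atom/residue helpers
# ---------------------------------------------------------------------------

def _atom(name: str, element: str, xyz, charge: int = 0) -> Atom:
    return Atom(
        serial=0, name=name, element=element, coords=np.asarray(xyz, float),
        is_hydrogen=element.upper() == "H", formal_charge=charge,
    )


def _renumber(protein: list[Residue], ligand: Residue,
              waters: list[Residue]) -> None:
    """Assign serials in canonical order before Complex validation."""
    serial = 0
    for res in (*protein, ligand, *waters):
        for atom in res.atoms:
            serial += 1
            atom.serial = serial


def _link_h(residue: Residue) -> None:
    heavies = residue.heavy_atoms()
    for h in residue.atoms:
        if h.is_hydrogen:
            h.parent_heavy = min(
                heavies, key=lambda x: np.linalg.norm(h.coords - x.coords)
            )


# ---------------------------------------------------------------------------
# plant builders (all local frames: ligand near the plant origin, protein
# partner along +x; the off-axis is therefore -x)
# ---------------------------------------------------------------------------

def _backbone_tail(start: np.ndarray) -> list[Atom]:
    """Inert CA/N tail behind a planted carbonyl, pointing away (+x)."""
    return [
        _atom("CA", "C", start + 1.52 * _X),
        _atom("N", "N", start + 1.52 * _X + 1.45 * _X),
    ]


def _build_hbond(spec: PlantSpec, origin: np.ndarray, seq: int) -> BuiltPlant:
    geo = spec.resolved_geometry()
    d = geo["distance"]
    donor_angle = geo["donor_angle"]
    acceptor_angle = geo["acceptor_angle"]
    n = _atom("N", "N", origin)
    h = _atom("H", "H", origin + 1.0 * _X)
    # acceptor placed so |D-A| = d and the D-H...A angle at H is as requested
    phi = np.radians(180.0 - donor_angle)
    c, s = np.cos(phi), np.sin(phi)
    r = -c + np.sqrt(c * c + d * d - 1.0)
    a_pos = h.coords + r * np.array([c, s, 0.0])
    o = _atom("O", "O", a_pos)
    # bonded neighbour C of the acceptor at the requested H...A-X angle
    w = (h.coords - a_pos) / np.linalg.norm(h.coords - a_pos)
    u = rotation_matrix(_Z, acceptor_angle) @ w
    cx = _atom("C", "C", a_pos + 1.23 * u)
    res = Residue(
        chain_id="A", seq_number=seq, name=spec.residue_name or _DEFAULT_RESIDUE["hbond"],
        atoms=[o, cx, *_backbone_tail(cx.coords)],
    )
    truth = [] if spec.negate else [("hbond", res.key)]
    h_a = float(np.linalg.norm(h.coords - a_pos))
    if h_a <= 3.2:  # the looser docking-stage criterion sees this plant too
        truth.append(("hbond_contact_docking", res.key))
    return BuiltPlant(spec, res, [n, h], None, truth, -_X)


def _build_docking(spec: PlantSpec, origin: np.ndarray, seq: int) -> BuiltPlant:
    geo = spec.resolved_geometry()
    n = _atom("N", "N", origin)
    h = _atom("H", "H", origin + 1.0 * _X)
    o = _atom("O", "O", h.coords + geo["distance"] * _X)
    cx = _atom("C", "C", o.coords + 1.23 * np.array([0.5, np.sqrt(3) / 2, 0.0]))
    res = Residue(
        chain_id="A", seq_number=seq,
        name=spec.residue_name or _DEFAULT_RESIDUE["hbond_contact_docking"],
        atoms=[o, cx, *_backbone_tail(cx.coords)],
    )
    truth = [] if spec.negate else [("hbond_contact_docking", res.key)]
    return BuiltPlant(spec, res, [n, h], None, truth, -_X)


def _build_water_bridge(spec: PlantSpec, origin: np.ndarray, seq: int) -> BuiltPlant:
    geo = spec.resolved_geometry()
    d1 = geo["distance"]
    d2 = geo.get("distance2", d1)
    n = _atom("N", "N", origin)
    h = _atom("H", "H", origin + 1.0 * _X)
    ow = _atom("O", "O", origin + d1 * _X)
    hw1 = _atom("H1", "H", ow.coords + 0.96 * _X)
    hw2 = _atom("H2", "H", ow.coords + 0.96 * np.array([-0.2588, 0.9659, 0.0]))
    op = _atom("O", "O", ow.coords + d2 * _X)
    cp = _atom("C", "C", op.coords + 1.23 * np.array([0.5, np.sqrt(3) / 2, 0.0]))
    water = Residue(chain_id="W", seq_number=seq + 400, name="HOH",
                    atoms=[ow, hw1, hw2])
    res = Residue(
        chain_id="A", seq_number=seq,
        name=spec.residue_name or _DEFAULT_RESIDUE["water_bridge"],
        atoms=[op, cp, *_backbone_tail(cp.coords)],
    )
    truth = [] if spec.negate else [("water_bridge", res.key)]
    return BuiltPlant(spec, res, [n, h], water, truth, -_X)


def _hexagon(center: np.ndarray, normal_rot: np.ndarray, radius: float = 1.39):
    """Vertices of a regular hexagon; the untilted ring lies in the yz-plane
    (normal +x), then the whole ring is rotated by ``normal_rot``."""
    pts = []
    for k in range(6):
        t = np.radians(60.0 * k)
        local = radius * (np.cos(t) * _Y + np.sin(t) * _Z)
        pts.append(center + normal_rot @ local)
    return pts


def _build_pi_pi(spec: PlantSpec, origin: np.ndarray, seq: int) -> BuiltPlant:
    geo = spec.resolved_geometry()
    lig_pts = _hexagon(origin, np.eye(3))
    lig_atoms = [_atom(f"C{i+1}", "C", p) for i, p in enumerate(lig_pts)]
    tilt = rotation_matrix(_Y, geo["angle"])
    center = origin + geo["distance"] * _X
    ring_names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
    ring_atoms = [
        _atom(nm, "C", p) for nm, p in zip(ring_names, _hexagon(center, tilt))
    ]
    cb = _atom("CB", "C", ring_atoms[0].coords + 1.52 * _X)
    ca = _atom("CA", "C", cb.coords + 1.53 * _X)
    res = Residue(
        chain_id="A", seq_number=seq, name=spec.residue_name or _DEFAULT_RESIDUE["pi_pi"],
        atoms=[*ring_atoms, cb, ca],
    )
    truth = [] if spec.negate else [("pi_pi", res.key)]
    return BuiltPlant(spec, res, lig_atoms, None, truth, -_X)


def _build_pi_cation(spec: PlantSpec, origin: np.ndarray, seq: int) -> BuiltPlant:
    geo = spec.resolved_geometry()
    lig_atoms = [_atom(f"C{i+1}", "C", p)
                 for i, p in enumerate(_hexagon(origin, np.eye(3)))]
    nz = _atom("NZ", "N", origin + geo["distance"] * _X)
    hzs = [
        _atom(f"HZ{i+1}", "H", nz.coords + 1.0 * (np.cos(a) * 0.5 * _Y
              + np.sin(a) * 0.5 * _Z + 0.866 * _X) / 1.0)
        for i, a in enumerate(np.radians([0.0, 120.0, 240.0]))
    ]
    ce = _atom("CE", "C", nz.coords + 1.49 * _X)
    cd = _atom("CD", "C", ce.coords + 1.53 * _X)
    res = Residue(
        chain_id="A", seq_number=seq,
        name=spec.residue_name or _DEFAULT_RESIDUE["pi_cation"],
        atoms=[nz, *hzs, ce, cd],
    )
    truth = [] if spec.negate else [("pi_cation", res.key)]
    return BuiltPlant(spec, res, lig_atoms, None, truth, -_X)


def _build_hydrophobic(spec: PlantSpec, origin: np.ndarray, seq: int) -> BuiltPlant:
    geo = spec.resolved_geometry()
    c0 = _atom("C01", "C", origin)
    cd1 = _atom("CD1", "C", origin + geo["distance"] * _X)
    cg = _atom("CG", "C", cd1.coords + 1.53 * _X)
    cd2 = _atom("CD2", "C", cg.coords + 1.53 * np.array([0.5, np.sqrt(3) / 2, 0.0]))
    cb = _atom("CB", "C", cg.coords + 1.53 * np.array([0.5, -np.sqrt(3) / 2, 0.0]))
    res = Residue(
        chain_id="A", seq_number=seq,
        name=spec.residue_name or _DEFAULT_RESIDUE["hydrophobic"],
        atoms=[cd1, cg, cd2, cb],
    )
    truth = [] if spec.negate else [("hydrophobic", res.key)]
    return BuiltPlant(spec, res, [c0], None, truth, -_X)


def _build_ionic(spec: PlantSpec, origin: np.ndarray, seq: int) -> BuiltPlant:
    geo = spec.resolved_geometry()
    npos = _atom("N01", "N", origin, charge=+1)
    mid = origin + geo["distance"] * _X
    oe1 = _atom("OE1", "O", mid + 1.1 * _Y)
    oe2 = _atom("OE2", "O", mid - 1.1 * _Y)
    cd = _atom("CD", "C", mid + 0.6 * _X)
    cg = _atom("CG", "C", cd.coords + 1.52 * _X)
    res = Residue(
        chain_id="A", seq_number=seq, name=spec.residue_name or _DEFAULT_RESIDUE["ionic"],
        atoms=[oe1, oe2, cd, cg],
    )
    truth = [] if spec.negate else [("ionic", res.key)]
    return BuiltPlant(spec, res, [npos], None, truth, -_X)


_BUILDERS = {
    "hbond": _build_hbond,
    "hbond_contact_docking": _build_docking,
    "water_bridge": _build_water_bridge,
    "pi_pi": _build_pi_pi,
    "pi_cation": _build_pi_cation,
    "hydrophobic": _build_hydrophobic,
    "ionic": _build_ionic,
}


# ---------------------------------------------------------------------------
# scaffold, decoys, scenes
# ---------------------------------------------------------------------------

def toy_indazole(center) -> list[Atom]:
    """An idealized arylsulphonyl-indazole-like scaffold: fused planar 6+5
    ring system with a pyrrolic N-H, a pyridinic N, and a sulfonyl group.

    Role inventory under default perception: two aromatic rings, one N-H
    donor, pyridinic N plus both sulfonyl O acceptors.
    """
    center = np.asarray(center, float)
    s6 = 1.39
    hexagon = []
    for k in range(6):
        t = np.radians(60.0 * k + 30.0)
        hexagon.append(center + s6 * 2 * 0.5 * np.array([np.cos(t), np.sin(t), 0.0]) / 1.0)
    names6 = ("C4", "C5", "C6", "C7", "C7A", "C3A")
    atoms = [_atom(nm, "C", p) for nm, p in zip(names6, hexagon)]
    c7a, c3a = atoms[4], atoms[5]
    edge_mid = (c7a.coords + c3a.coords) / 2.0
    u = edge_mid - center
    u = u / np.linalg.norm(u)
    apothem = s6 / (2.0 * np.tan(np.radians(36.0)))
    circum = s6 / (2.0 * np.sin(np.radians(36.0)))
    pc = edge_mid + apothem * u
    ang_p1 = np.arctan2(*(c7a.coords - pc)[[1, 0]])
    # walk the pentagon from C7A to C3A the long way round: N1, N2, C3
    ang_p2 = np.arctan2(*(c3a.coords - pc)[[1, 0]])
    step = (ang_p2 - ang_p1) % (2 * np.pi)
    if abs(step - np.radians(72.0)) < 1e-6:
        direction = -1.0  # short way from P1 to P2 is +; go the other way
    else:
        direction = 1.0
    penta_names = ("N1", "N2", "C3")
    penta_elements = ("N", "N", "C")
    for i, (nm, el) in enumerate(zip(penta_names, penta_elements), start=1):
        ang = ang_p1 + direction * i * np.radians(72.0)
        pos = pc + circum * np.array([np.cos(ang), np.sin(ang), 0.0])
        atoms.append(_atom(nm, el, pos))
    n1 = atoms[6]
    out1 = (n1.coords - pc) / np.linalg.norm(n1.coords - pc)
    atoms.append(_atom("H1", "H", n1.coords + 1.01 * out1))
    # sulfonyl on C5
    c5 = atoms[1]
    w = (c5.coords - center) / np.linalg.norm(c5.coords - center)
    s = _atom("S", "S", c5.coords + 1.77 * w)
    atoms.append(s)
    for sign, nm in ((1.0, "O1"), (-1.0, "O2")):
        d = 0.5 * w + sign * np.sin(np.radians(60.0)) * _Z
        d = d / np.linalg.norm(d)
        atoms.append(_atom(nm, "O", s.coords + 1.43 * d))
    return atoms


_DECOY_TEMPLATES: dict[str, list[tuple[str, str, tuple[float, float, float]]]] = {
    "GLY": [("N", "N", (0, 0, 0)), ("CA", "C", (1.46, 0, 0)),
            ("C", "C", (2.0, 1.4, 0)), ("O", "O", (1.4, 2.4, 0.3)),
            ("H", "H", (-0.9, 0.4, 0))],
    "ALA": [("N", "N", (0, 0, 0)), ("CA", "C", (1.46, 0, 0)),
            ("C", "C", (2.0, 1.4, 0)), ("O", "O", (1.4, 2.4, 0.3)),
            ("CB", "C", (2.1, -1.2, 0.6)), ("H", "H", (-0.9, 0.4, 0))],
    "SER": [("N", "N", (0, 0, 0)), ("CA", "C", (1.46, 0, 0)),
            ("C", "C", (2.0, 1.4, 0)), ("O", "O", (1.4, 2.4, 0.3)),
            ("CB", "C", (2.1, -1.2, 0.6)), ("OG", "O", (3.1, -1.9, -0.1)),
            ("HG", "H", (3.9, -1.5, 0.2)), ("H", "H", (-0.9, 0.4, 0))],
    "LEU": [("N", "N", (0, 0, 0)), ("CA", "C", (1.46, 0, 0)),
            ("C", "C", (2.0, 1.4, 0)), ("O", "O", (1.4, 2.4, 0.3)),
            ("CB", "C", (2.1, -1.2, 0.6)), ("CG", "C", (3.6, -1.3, 0.5)),
            ("CD1", "C", (4.2, -2.6, 1.0)), ("CD2", "C", (4.3, -0.1, 1.2)),
            ("H", "H", (-0.9, 0.4, 0))],
}

_DECOY_NAMES = ("ALA", "LEU", "SER", "GLY")


def _make_decoy(name: str, seq: int, position: np.ndarray,
                rot: np.ndarray) -> Residue:
    atoms = [
        _atom(nm, el, position + rot @ np.asarray(xyz, float))
        for nm, el, xyz in _DECOY_TEMPLATES[name]
    ]
    return Residue(chain_id="B", seq_number=seq, name=name, atoms=atoms)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    return rotation_matrix(axis, float(rng.uniform(0.0, 360.0)))


def build_pocket(
    plants: list[PlantSpec],
    n_decoy_residues: int = 0,
    seed: int = 0,
    max_retries: int = 2000,
) -> SyntheticScene:
    """Assemble a synthetic pocket with the requested plants plus decoys.

    Plant sites sit ``PLANT_SPACING`` apart along z (protein partner toward
    +x); an indazole-like scaffold anchors the ligand one spacing below the
    first site; decoys are rejection-placed >= 8 A from everything.
    """
    rng = np.random.default_rng(seed)
    built: list[BuiltPlant] = []
    for i, spec in enumerate(plants):
        origin = np.array([0.0, 0.0, PLANT_SPACING * i])
        seq = spec.seq_number if spec.seq_number is not None else 101 + i
        built.append(_BUILDERS[spec.kind](spec, origin, seq))

    ligand = Residue(chain_id="A", seq_number=900, name="LIG")
    for atom in toy_indazole(np.array([0.0, 0.0, -PLANT_SPACING])):
        ligand.add(atom)
    for plant in built:
        for atom in plant.ligand_atoms:
            ligand.add(atom)

    protein = [p.protein_residue for p in built if p.protein_residue is not None]
    waters = [p.water for p in built if p.water is not None]

    # decoy background, >= 8 A from every already-placed atom
    placed = np.array(
        [a.coords for r in (*protein, ligand, *waters) for a in r.atoms]
    )
    for j in range(n_decoy_residues):
        name = _DECOY_NAMES[j % len(_DECOY_NAMES)]
        for attempt in range(max_retries):
            pos = rng.uniform(-30.0, 30.0, size=3)
            decoy = _make_decoy(name, 201 + j, pos, _random_rotation(rng))
            coords = np.array([a.coords for a in decoy.atoms])
            d = np.linalg.norm(placed[:, None, :] - coords[None, :, :], axis=2)
            if d.min() >= 8.0:
                protein.append(decoy)
                placed = np.vstack([placed, coords])
                break
        else:
            raise GenerationError(
                f"could not place decoy {j} after {max_retries} retries"
            )

    _renumber(protein, ligand, waters)
    complex_ = Complex(protein_residues=protein, ligand=ligand, waters=waters)
    for res in complex_.residues():
        _link_h(res)
    return SyntheticScene(complex=complex_, plants=built, seed=seed)


def build_trajectory(
    scene: SyntheticScene,
    n_frames: int,
    jitter_sd: float = 0.0,
    seed: int = 0,
) -> tuple[Trajectory, list[set[tuple[str, str]]]]:
    """Jittered Bernoulli-occupancy trajectory over a scene.

    Per frame each plant is "on" with probability ``occupancy_p``; "off"
    frames displace the plant's ligand-side atoms ``OFF_DISPLACEMENT`` A away
    from the protein partner, breaking every criterion with >= 1.5 A margin.
    All atoms then receive isotropic Gaussian jitter. Returns the trajectory
    and, per frame, the set of (residue key, kind) contacts that are truly on.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if jitter_sd < 0 or jitter_sd > JITTER_SD_MAX:
        raise ParameterError(
            f"jitter_sd must be in [0, {JITTER_SD_MAX}] to preserve margins"
        )
    rng = np.random.default_rng(seed)
    complex_ = scene.complex
    base = complex_.coords_array()
    index_of = {a.serial: i for i, a in enumerate(complex_.atoms())}
    plant_rows = [
        np.array([index_of[a.serial] for a in p.ligand_atoms]) for p in scene.plants
    ]
    frames, frame_truth = [], []
    for _ in range(n_frames):
        coords = base.copy()
        on_set: set[tuple[str, str]] = set()
        for plant, rows in zip(scene.plants, plant_rows):
            on = bool(rng.random() < plant.spec.occupancy_p)
            if on:
                on_set.update((key, kind) for kind, key in plant.truth)
            else:
                coords[rows] += OFF_DISPLACEMENT * plant.off_axis
        if jitter_sd > 0:
            coords += rng.normal(0.0, jitter_sd, size=coords.shape)
        frames.append(coords)
        frame_truth.append(on_set)
    traj = Trajectory(topology=complex_, frames=frames,
                      times=[float(i) for i in range(n_frames)])
    return traj, frame_truth


def build_energy_tables(
    n_ligands: int,
    n_residues: int,
    corrupt_fraction: float = 0.0,
    seed: int = 0,
):
    """Random energy tables with exact stored totals, except for a chosen
    fraction of rows whose totals are perturbed past the consistency
    tolerance. Returns (sapt records, pieda records, enthalpy records,
    truth) where truth maps schema -> sorted corrupted row indices.
    """
    if not (0.0 <= corrupt_fraction < 1.0):
        raise ValueError("corrupt_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    residues = [f"RES{i+1}" for i in range(n_residues)]
    n_rows = n_ligands * n_residues

    def pick_corrupt():
        k = int(round(corrupt_fraction * n_rows))
        return set(rng.choice(n_rows, size=k, replace=False).tolist()) if k else set()

    def perturb():
        return float(rng.choice([-1.0, 1.0]) * rng.uniform(0.05, 0.5))

    sapt, pieda, enthalpy = [], [], []
    truth = {"sapt": [], "pieda": []}

    corrupt_sapt = pick_corrupt()
    row = 0
    for li in range(n_ligands):
        for res in residues:
            comp = {
                "e_elst": float(rng.uniform(-15.0, 5.0)),
                "e_exch": float(rng.uniform(0.0, 20.0)),
                "e_ind": float(rng.uniform(-8.0, 0.0)),
                "e_disp": float(rng.uniform(-15.0, 0.0)),
            }
            total = sum(comp.values())
            if row in corrupt_sapt:
                total += perturb()
                truth["sapt"].append(row)
            sapt.append(SaptRecord(ligand_id=str(li + 1), residue_key=res,
                                   e_total=total, **comp))
            row += 1

    corrupt_pieda = pick_corrupt()
    row = 0
    for li in range(n_ligands):
        for res in residues:
            comp = {
                "e_es": float(rng.uniform(-15.0, 5.0)),
                "e_ex": float(rng.uniform(0.0, 18.0)),
                "e_ct_mix": float(rng.uniform(-8.0, 0.0)),
                "e_disp": float(rng.uniform(-15.0, 0.0)),
                "g_sol": float(rng.uniform(-3.0, 5.0)),
            }
            total = sum(comp.values())
            if row in corrupt_pieda:
                total += perturb()
                truth["pieda"].append(row)
            pieda.append(PiedaRecord(ligand_id=str(li + 1), residue_key=res,
                                     e_tot=total, **comp))
            row += 1

    for li in range(n_ligands):
        hf_p = float(rng.uniform(-400.0, -80.0))
        hf_l = float(rng.uniform(-80.0, -10.0))
        hf_pl = hf_p + hf_l + float(rng.uniform(-30.0, 0.0))
        enthalpy.append(EnthalpyRecord(
            ligand_id=str(li + 1), hf_complex=hf_pl,
            hf_protein_in_complex=hf_p, hf_ligand_in_complex=hf_l,
        ))
    truth = {k: sorted(v) for k, v in truth.items()}
    return sapt, pieda, enthalpy, truth


# ---------------------------------------------------------------------------
# random scenes and simple chains (oracle and null-model fixtures)
# ---------------------------------------------------------------------------

_SCENE_TEMPLATES = dict(_DECOY_TEMPLATES)
_SCENE_TEMPLATES.update({
    "LYS": [("N", "N", (0, 0, 0)), ("CA", "C", (1.46, 0, 0)),
            ("C", "C", (2.0, 1.4, 0)), ("O", "O", (1.4, 2.4, 0.3)),
            ("CB", "C", (2.1, -1.2, 0.6)), ("CG", "C", (3.6, -1.3, 0.5)),
            ("CD", "C", (4.2, -2.6, 1.0)), ("CE", "C", (5.7, -2.7, 0.9)),
            ("NZ", "N", (6.3, -4.0, 1.3)), ("HZ1", "H", (7.3, -3.9, 1.3)),
            ("H", "H", (-0.9, 0.4, 0))],
    "GLU": [("N", "N", (0, 0, 0)), ("CA", "C", (1.46, 0, 0)),
            ("C", "C", (2.0, 1.4, 0)), ("O", "O", (1.4, 2.4, 0.3)),
            ("CB", "C", (2.1, -1.2, 0.6)), ("CG", "C", (3.6, -1.3, 0.5)),
            ("CD", "C", (4.2, -2.6, 1.0)), ("OE1", "O", (5.4, -2.7, 1.1)),
            ("OE2", "O", (3.5, -3.7, 1.2)), ("H", "H", (-0.9, 0.4, 0))],
})
# PHE with a proper hexagonal ring
_PHE_RING_CENTER = np.array([4.3, -1.9, 0.8])
_SCENE_TEMPLATES["PHE"] = [
    ("N", "N", (0, 0, 0)), ("CA", "C", (1.46, 0, 0)),
    ("C", "C", (2.0, 1.4, 0)), ("O", "O", (1.4, 2.4, 0.3)),
    ("CB", "C", (2.1, -1.2, 0.6)), ("H", "H", (-0.9, 0.4, 0)),
] + [
    (nm, "C", tuple(_PHE_RING_CENTER + 1.39 * (np.cos(np.radians(60 * k)) * _Y
                                               + np.sin(np.radians(60 * k)) * _Z)))
    for k, nm in enumerate(("CG", "CD1", "CE1", "CZ", "CE2", "CD2"))
]

_WATER_TEMPLATE = [("O", "O", (0, 0, 0)), ("H1", "H", (0.96, 0, 0)),
                   ("H2", "H", (-0.24, 0.93, 0))]


def random_scene(
    seed: int,
    n_protein: int = 12,
    n_waters: int = 4,
    n_extra_ligand_atoms: int = 8,
    box: float = 18.0,
) -> Complex:
    """A dense random scene for detector-vs-oracle equivalence checks.

    Residues with every role class (donor, acceptor, ring, +, -, apolar) are
    scattered with random orientations in a cubic box around an
    indazole-like ligand scaffold; extra ligand atoms (donor N-H pairs,
    pyridinic N, bare C, charged N+/O-) are sprinkled uniformly. No clash
    relaxation is attempted: these scenes are geometric test articles, not
    physical structures.
    """
    rng = np.random.default_rng(seed)
    names = ("SER", "LYS", "GLU", "LEU", "PHE", "ALA")
    protein = []
    for i in range(n_protein):
        name = names[int(rng.integers(len(names)))]
        pos = rng.uniform(-box / 2, box / 2, size=3)
        res = Residue(chain_id="A", seq_number=10 + i, name=name)
        rot = _random_rotation(rng)
        for nm, el, xyz in _SCENE_TEMPLATES[name]:
            res.add(_atom(nm, el, pos + rot @ np.asarray(xyz, float)))
        protein.append(res)

    ligand = Residue(chain_id="A", seq_number=900, name="LIG")
    for atom in toy_indazole(rng.uniform(-3.0, 3.0, size=3)):
        ligand.add(atom)
    serial_suffix = 0
    for i in range(n_extra_ligand_atoms):
        pos = rng.uniform(-box / 2, box / 2, size=3)
        serial_suffix += 1
        mode = i % 4
        if mode == 0:  # donor N-H
            ligand.add(_atom(f"N{serial_suffix}", "N", pos))
            u = rng.normal(size=3)
            ligand.add(_atom(f"HN{serial_suffix}", "H",
                             pos + u / np.linalg.norm(u)))
        elif mode == 1:  # pyridinic-style bare N acceptor
            ligand.add(_atom(f"N{serial_suffix}", "N", pos))
        elif mode == 2:  # apolar carbon
            ligand.add(_atom(f"C{serial_suffix}", "C", pos))
        else:  # charged site, alternating sign
            if (i // 4) % 2 == 0:
                ligand.add(_atom(f"N{serial_suffix}", "N", pos, charge=+1))
            else:
                ligand.add(_atom(f"O{serial_suffix}", "O", pos, charge=-1))

    waters = []
    for i in range(n_waters):
        pos = rng.uniform(-box / 2, box / 2, size=3)
        rot = _random_rotation(rng)
        res = Residue(chain_id="W", seq_number=500 + i, name="HOH")
        for nm, el, xyz in _WATER_TEMPLATE:
            res.add(_atom(nm, el, pos + rot @ np.asarray(xyz, float)))
        waters.append(res)

    _renumber(protein, ligand, waters)
    complex_ = Complex(protein_residues=protein, ligand=ligand, waters=waters)
    for res in complex_.residues():
        _link_h(res)
    return complex_


def make_chain_complex(n_residues: int = 21, spacing: float = 3.8) -> Complex:
    """A linear poly-alanine-like backbone with a far-away 3-carbon ligand;
    used as a null model for RMSD/RMSF checks."""
    protein = []
    for i in range(n_residues):
        x0 = spacing * i
        res = Residue(chain_id="A", seq_number=i + 1, name="ALA")
        res.add(_atom("N", "N", (x0, 0.0, 0.0)))
        res.add(_atom("CA", "C", (x0 + 1.2, 1.0, 0.3 * ((-1) ** i))))
        res.add(_atom("C", "C", (x0 + 2.4, 0.2, 0.0)))
        res.add(_atom("O", "O", (x0 + 2.6, -1.0, 0.2)))
        protein.append(res)
    ligand = Residue(chain_id="A", seq_number=900, name="LIG")
    ligand.add(_atom("C1", "C", (0.0, 20.0, 0.0)))
    ligand.add(_atom("C2", "C", (1.5, 20.0, 0.0)))
    ligand.add(_atom("C3", "C", (0.7, 21.3, 0.4)))
    _renumber(protein, ligand, [])
    complex_ = Complex(protein_residues=protein, ligand=ligand, waters=[])
    for res in complex_.residues():
        _link_h(res)
    return complex_
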