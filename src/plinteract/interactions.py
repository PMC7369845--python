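"""Geometric detection of protein-ligand interaction classes on one pose.

Seven detectors are provided:

* ``detect_hbond_contacts_docking`` - the loose docking-stage criterion: a
  polar hydrogen within 3.2 A of a heteroatom (N/O/S) of the other molecule.
* ``detect_hbonds`` - MD-style hydrogen bonds: donor-acceptor distance
  <= 2.5 A, donor angle (D-H...A, at H) >= 120 deg, acceptor angle
  (H...A-X, at A) >= 90 deg for the bonded neighbours X of the acceptor.
* ``detect_water_bridges`` - one water simultaneously hydrogen bonded (with
  relaxed criteria 2.8 A / 110 deg / 90 deg) to the ligand and the protein.
* ``detect_pi_pi`` - aromatic rings stacked face-to-face (interplanar angle
  <= 30 deg, centroids <= 4.4 A) or edge-to-face (60-90 deg unsigned,
  centroids <= 5.5 A).
* ``detect_pi_cation`` - ring centroid within 4.5 A of a positive charge
  site, in either direction.
* ``detect_hydrophobic`` - apolar ligand carbon within 3.6 A of a
  hydrophobic protein sidechain atom, aggregated per residue.
* ``detect_ionic`` - opposite charge sites within 3.7 A whose atoms are not
  already engaged in a hydrogen bond.

All thresholds are inclusive; comparisons carry a 1e-9 slack so analytically
constructed boundary geometries survive binary floating point.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.spatial import cKDTree

from .geometry import EPS, angle, distance, interplanar_angle, vector_angle
from .model_io import Atom, Complex, Residue
from .perception import AromaticRing, ChargedGroup, PerceivedChemistry

HETEROATOMS = ("N", "O", "S")

KINDS = (
    "hbond",
    "hbond_contact_docking",
    "water_bridge",
    "pi_pi",
    "pi_cation",
    "hydrophobic",
    "ionic",
)


@dataclass
class GeometricCriteria:
    """All distance (A) and angle (deg) thresholds, inclusive bounds."""

    docking_contact_max: float = 3.2
    hbond_da_max: float = 2.5
    hbond_donor_angle_min: float = 120.0
    hbond_acceptor_angle_min: float = 90.0
    wb_da_max: float = 2.8
    wb_donor_angle_min: float = 110.0
    wb_acceptor_angle_min: float = 90.0
    pication_max: float = 4.5
    hydrophobic_max: float = 3.6
    ionic_max: float = 3.7
    pipi_f2f_centroid_max: float = 4.4
    pipi_e2f_centroid_max: float = 5.5
    pipi_f2f_angle_max: float = 30.0
    pipi_e2f_angle_min: float = 60.0
    #: acceptor-angle quantifier over the bonded neighbours X of the acceptor:
    #: "every" (strict, default) or "any"
    acceptor_quantifier: str = "every"

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, float) and v <= 0:
                raise ValueError(f"{f.name} must be positive")
        if self.acceptor_quantifier not in ("every", "any"):
            raise ValueError("acceptor_quantifier must be 'every' or 'any'")

    @classmethod
    def from_file(cls, path: str | Path) -> "GeometricCriteria":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def updated(self, overrides: dict) -> "GeometricCriteria":
        return replace(self, **overrides) if overrides else self


@dataclass
class InteractionRecord:
    """One detected contact; ``geometry`` holds the measurements that were
    tested against the thresholds and is re-checkable via :func:`revalidate`."""

    kind: str
    ligand_part: object
    protein_part: object
    residue_key: str
    geometry: dict[str, float]
    water_key: str | None = None
    subtype: str | None = None
    frame_index: int | None = None

    def part_label(self, part) -> str:
        if isinstance(part, Atom):
            return part.name
        return part.label

    def to_row(self) -> dict:
        row = {
            "kind": self.kind,
            "residue": self.residue_key,
            "ligand_part": self.part_label(self.ligand_part),
            "protein_part": self.part_label(self.protein_part),
            "water": self.water_key or "",
            "subtype": self.subtype or "",
            "frame": "" if self.frame_index is None else self.frame_index,
        }
        row.update({k: round(v, 6) for k, v in sorted(self.geometry.items())})
        return row


# ---------------------------------------------------------------------------
# side classification helpers
# ---------------------------------------------------------------------------

def _side(residue: Residue, complex_: Complex) -> str:
    if residue is complex_.ligand:
        return "ligand"
    if residue.is_water:
        return "water"
    return "protein"


def _chem(complex_: Complex) -> PerceivedChemistry:
    if complex_.annotations is None:
        raise ValueError("complex has no perceived chemistry; run perceive() first")
    return complex_.annotations


def _split_by_side(items, complex_: Complex, residue_of):
    out = {"ligand": [], "protein": [], "water": []}
    for it in items:
        out[_side(residue_of(it), complex_)].append(it)
    return out


# ---------------------------------------------------------------------------
# detectors
# ---------------------------------------------------------------------------

def detect_hbond_contacts_docking(
    complex_: Complex, criteria: GeometricCriteria | None = None
) -> list[InteractionRecord]:
    """Docking-stage contact: polar H within 3.2 A of a heteroatom of the
    other molecule (waters excluded; both directions scanned)."""
    criteria = criteria or GeometricCriteria()
    chem = _chem(complex_)

    def polar_hydrogens(side):
        return [
            h for (d, h) in chem.donors
            if _side(d.residue, complex_) == side
        ]

    def heteroatoms(side):
        residues = [complex_.ligand] if side == "ligand" else complex_.protein_residues
        return [
            a for r in residues for a in r.atoms
            if not a.is_hydrogen and a.element.upper() in HETEROATOMS
        ]

    records = []
    for h_side, a_side in (("ligand", "protein"), ("protein", "ligand")):
        hs = polar_hydrogens(h_side)
        hets = heteroatoms(a_side)
        if not hs or not hets:
            continue
        tree = cKDTree(np.array([a.coords for a in hets]))
        for h in hs:
            for j in tree.query_ball_point(h.coords, criteria.docking_contact_max + EPS):
                het = hets[j]
                d = distance(h.coords, het.coords)
                lig_part, prot_part = (h, het) if h_side == "ligand" else (het, h)
                prot_res = het.residue if a_side == "protein" else h.residue
                records.append(
                    InteractionRecord(
                        kind="hbond_contact_docking",
                        ligand_part=lig_part,
                        protein_part=prot_part,
                        residue_key=prot_res.key,
                        geometry={"distance": d},
                        subtype=f"{h_side}_h",
                    )
                )
    return sorted(records, key=_record_sort_key)


def _hbond_geometry(
    donor: Atom, h: Atom, acceptor: Atom, x_neighbors: list[Atom],
    da_max: float, donor_angle_min: float, acceptor_angle_min: float,
    quantifier: str,
) -> dict[str, float] | None:
    """Test one D-H...A candidate; return its geometry map or None."""
    d = distance(donor.coords, acceptor.coords)
    if d > da_max + EPS:
        return None
    donor_angle = angle(donor.coords, h.coords, acceptor.coords)
    if donor_angle < donor_angle_min - EPS:
        return None
    if x_neighbors:
        x_angles = [angle(h.coords, acceptor.coords, x.coords) for x in x_neighbors]
        test = all if quantifier == "every" else any
        if not test(a >= acceptor_angle_min - EPS for a in x_angles):
            return None
        acceptor_angle = min(x_angles)
    else:
        acceptor_angle = float("nan")  # vacuous pass (no bonded neighbour)
    return {"distance": d, "donor_angle": donor_angle, "acceptor_angle": acceptor_angle}


def detect_hbonds(
    complex_: Complex, criteria: GeometricCriteria | None = None
) -> list[InteractionRecord]:
    """MD-style hydrogen bonds between ligand and protein (waters are
    handled by the water-bridge detector)."""
    criteria = criteria or GeometricCriteria()
    chem = _chem(complex_)
    donors = _split_by_side(chem.donors, complex_, lambda dh: dh[0].residue)
    acceptors = _split_by_side(
        list(chem.acceptors.items()), complex_, lambda ax: ax[0].residue
    )
    records = []
    for d_side, a_side in (("ligand", "protein"), ("protein", "ligand")):
        for donor, h in donors[d_side]:
            for acc, xs in acceptors[a_side]:
                geo = _hbond_geometry(
                    donor, h, acc, xs,
                    criteria.hbond_da_max,
                    criteria.hbond_donor_angle_min,
                    criteria.hbond_acceptor_angle_min,
                    criteria.acceptor_quantifier,
                )
                if geo is None:
                    continue
                lig_part, prot_part = (donor, acc) if d_side == "ligand" else (acc, donor)
                prot_res = acc.residue if a_side == "protein" else donor.residue
                records.append(
                    InteractionRecord(
                        kind="hbond",
                        ligand_part=lig_part,
                        protein_part=prot_part,
                        residue_key=prot_res.key,
                        geometry=geo,
                        subtype=f"{d_side}_donor",
                    )
                )
    return sorted(records, key=_record_sort_key)


def _water_links(
    water: Residue, partner_atoms_donors, partner_atoms_acceptors,
    chem: PerceivedChemistry, criteria: GeometricCriteria,
):
    """All relaxed H-bond links between one water and a partner side.

    Yields (partner heavy atom, geometry) for water-donates and
    water-accepts links alike.
    """
    w_donors = [(d, h) for (d, h) in chem.donors if d.residue is water]
    w_o = next((a for a in water.atoms if a.element.upper() == "O"), None)
    # water donates to a partner acceptor
    for d, h in w_donors:
        for acc, xs in partner_atoms_acceptors:
            geo = _hbond_geometry(
                d, h, acc, xs,
                criteria.wb_da_max, criteria.wb_donor_angle_min,
                criteria.wb_acceptor_angle_min, criteria.acceptor_quantifier,
            )
            if geo is not None:
                yield acc, geo
    # partner donates to the water oxygen
    if w_o is not None:
        for donor, h in partner_atoms_donors:
            geo = _hbond_geometry(
                donor, h, w_o, [],
                criteria.wb_da_max, criteria.wb_donor_angle_min,
                criteria.wb_acceptor_angle_min, criteria.acceptor_quantifier,
            )
            if geo is not None:
                yield donor, geo


def detect_water_bridges(
    complex_: Complex, criteria: GeometricCriteria | None = None
) -> list[InteractionRecord]:
    """Ligand-water-protein bridges: one water H-bonded (relaxed criteria)
    to both molecules simultaneously; one record per (ligand atom, residue,
    water) triple."""
    criteria = criteria or GeometricCriteria()
    chem = _chem(complex_)
    donors = _split_by_side(chem.donors, complex_, lambda dh: dh[0].residue)
    acceptors = _split_by_side(
        list(chem.acceptors.items()), complex_, lambda ax: ax[0].residue
    )
    records = []
    for water in complex_.waters:
        lig_links = list(_water_links(
            water, donors["ligand"], acceptors["ligand"], chem, criteria))
        prot_links = list(_water_links(
            water, donors["protein"], acceptors["protein"], chem, criteria))
        seen = set()
        for lig_atom, lig_geo in lig_links:
            for prot_atom, prot_geo in prot_links:
                key = (lig_atom.serial, prot_atom.residue.key)
                if key in seen:
                    continue
                seen.add(key)
                records.append(
                    InteractionRecord(
                        kind="water_bridge",
                        ligand_part=lig_atom,
                        protein_part=prot_atom,
                        residue_key=prot_atom.residue.key,
                        water_key=water.key,
                        geometry={
                            "distance": max(lig_geo["distance"], prot_geo["distance"]),
                            "lig_water_distance": lig_geo["distance"],
                            "water_prot_distance": prot_geo["distance"],
                        },
                    )
                )
    return sorted(records, key=_record_sort_key)


def detect_pi_pi(
    complex_: Complex, criteria: GeometricCriteria | None = None
) -> list[InteractionRecord]:
    """Aromatic stacking, face-to-face or edge-to-face, between ligand and
    protein rings; the interplanar angle is folded to [0, 90] degrees."""
    criteria = criteria or GeometricCriteria()
    chem = _chem(complex_)
    rings = _split_by_side(chem.rings, complex_, lambda r: r.residue)
    records = []
    for lr in rings["ligand"]:
        for pr in rings["protein"]:
            c = distance(lr.centroid, pr.centroid)
            theta = interplanar_angle(lr.normal, pr.normal)
            subtype = None
            if theta <= criteria.pipi_f2f_angle_max + EPS and \
                    c <= criteria.pipi_f2f_centroid_max + EPS:
                subtype = "face_to_face"
            elif theta >= criteria.pipi_e2f_angle_min - EPS and \
                    c <= criteria.pipi_e2f_centroid_max + EPS:
                subtype = "edge_to_face"
            if subtype is None:
                continue
            records.append(
                InteractionRecord(
                    kind="pi_pi",
                    ligand_part=lr,
                    protein_part=pr,
                    residue_key=pr.residue.key,
                    geometry={"distance": c, "interplanar_angle": theta},
                    subtype=subtype,
                )
            )
    return sorted(records, key=_record_sort_key)


def detect_pi_cation(
    complex_: Complex, criteria: GeometricCriteria | None = None
) -> list[InteractionRecord]:
    """Ring centroid within 4.5 A of a positive charge site, either
    direction (ligand ring vs protein cation, protein ring vs ligand cation)."""
    criteria = criteria or GeometricCriteria()
    chem = _chem(complex_)
    rings = _split_by_side(chem.rings, complex_, lambda r: r.residue)
    cations = _split_by_side(chem.pos_charges, complex_, lambda g: g.residue)
    records = []
    for ring_side, cat_side in (("ligand", "protein"), ("protein", "ligand")):
        for ring in rings[ring_side]:
            for cat in cations[cat_side]:
                d = distance(ring.centroid, cat.site)
                if d > criteria.pication_max + EPS:
                    continue
                lig_part, prot_part = (ring, cat) if ring_side == "ligand" else (cat, ring)
                prot_res = cat.residue if cat_side == "protein" else ring.residue
                records.append(
                    InteractionRecord(
                        kind="pi_cation",
                        ligand_part=lig_part,
                        protein_part=prot_part,
                        residue_key=prot_res.key,
                        geometry={"distance": d},
                        subtype=f"{ring_side}_ring",
                    )
                )
    return sorted(records, key=_record_sort_key)


def detect_hydrophobic(
    complex_: Complex, criteria: GeometricCriteria | None = None
) -> list[InteractionRecord]:
    """Apolar contacts within 3.6 A, aggregated to one record per protein
    residue carrying the minimum distance (and the closest atom pair)."""
    criteria = criteria or GeometricCriteria()
    chem = _chem(complex_)
    hydrophobics = _split_by_side(
        sorted(chem.hydrophobic_atoms, key=lambda a: a.serial),
        complex_, lambda a: a.residue,
    )
    lig, prot = hydrophobics["ligand"], hydrophobics["protein"]
    if not lig or not prot:
        return []
    tree = cKDTree(np.array([a.coords for a in prot]))
    best: dict[str, tuple[float, Atom, Atom]] = {}
    for la in lig:
        for j in tree.query_ball_point(la.coords, criteria.hydrophobic_max + EPS):
            pa = prot[j]
            d = distance(la.coords, pa.coords)
            key = pa.residue.key
            if key not in best or d < best[key][0]:
                best[key] = (d, la, pa)
    records = [
        InteractionRecord(
            kind="hydrophobic",
            ligand_part=la,
            protein_part=pa,
            residue_key=key,
            geometry={"distance": d},
        )
        for key, (d, la, pa) in best.items()
    ]
    return sorted(records, key=_record_sort_key)


def detect_ionic(
    complex_: Complex,
    criteria: GeometricCriteria | None = None,
    hbond_records: list[InteractionRecord] | None = None,
) -> list[InteractionRecord]:
    """Opposite charge sites within 3.7 A that are not already hydrogen
    bonded (H-bond precedence; pass ``hbond_records`` to reuse a previous
    detection, otherwise they are recomputed)."""
    criteria = criteria or GeometricCriteria()
    chem = _chem(complex_)
    if hbond_records is None:
        hbond_records = detect_hbonds(complex_, criteria)
    engaged: set[int] = set()
    for rec in hbond_records:
        for part in (rec.ligand_part, rec.protein_part):
            if isinstance(part, Atom):
                engaged.add(part.serial)

    pos = _split_by_side(chem.pos_charges, complex_, lambda g: g.residue)
    neg = _split_by_side(chem.neg_charges, complex_, lambda g: g.residue)
    records = []
    for lig_groups, prot_groups in ((pos["ligand"], neg["protein"]),
                                    (neg["ligand"], pos["protein"])):
        for lg in lig_groups:
            for pg in prot_groups:
                d = distance(lg.site, pg.site)
                if d > criteria.ionic_max + EPS:
                    continue
                if any(a.serial in engaged for a in (*lg.atoms, *pg.atoms)):
                    continue
                records.append(
                    InteractionRecord(
                        kind="ionic",
                        ligand_part=lg,
                        protein_part=pg,
                        residue_key=pg.residue.key,
                        geometry={"distance": d},
                    )
                )
    return sorted(records, key=_record_sort_key)


def _record_sort_key(rec: InteractionRecord):
    return (rec.residue_key, rec.kind, round(rec.geometry.get("distance", 0.0), 6),
            rec.part_label(rec.ligand_part), rec.part_label(rec.protein_part),
            rec.water_key or "")


def detect_all(
    complex_: Complex, criteria: GeometricCriteria | None = None
) -> dict[str, list[InteractionRecord]]:
    """Run every detector; ionic detection sees the H-bond records for its
    exclusion rule."""
    criteria = criteria or GeometricCriteria()
    hbonds = detect_hbonds(complex_, criteria)
    return {
        "hbond": hbonds,
        "hbond_contact_docking": detect_hbond_contacts_docking(complex_, criteria),
        "water_bridge": detect_water_bridges(complex_, criteria),
        "pi_pi": detect_pi_pi(complex_, criteria),
        "pi_cation": detect_pi_cation(complex_, criteria),
        "hydrophobic": detect_hydrophobic(complex_, criteria),
        "ionic": detect_ionic(complex_, criteria, hbond_records=hbonds),
    }


# ---------------------------------------------------------------------------
# re-validation and tables
# ---------------------------------------------------------------------------

def revalidate(rec: InteractionRecord, criteria: GeometricCriteria) -> bool:
    """Check a record's stored geometry against the thresholds of its kind."""
    g = rec.geometry
    if rec.kind == "hbond_contact_docking":
        return g["distance"] <= criteria.docking_contact_max + EPS
    if rec.kind == "hbond":
        ok = g["distance"] <= criteria.hbond_da_max + EPS
        ok &= g["donor_angle"] >= criteria.hbond_donor_angle_min - EPS
        if not np.isnan(g["acceptor_angle"]):
            ok &= g["acceptor_angle"] >= criteria.hbond_acceptor_angle_min - EPS
        return bool(ok)
    if rec.kind == "water_bridge":
        return (g["lig_water_distance"] <= criteria.wb_da_max + EPS
                and g["water_prot_distance"] <= criteria.wb_da_max + EPS)
    if rec.kind == "pi_pi":
        if rec.subtype == "face_to_face":
            return (g["distance"] <= criteria.pipi_f2f_centroid_max + EPS
                    and g["interplanar_angle"] <= criteria.pipi_f2f_angle_max + EPS)
        return (g["distance"] <= criteria.pipi_e2f_centroid_max + EPS
                and g["interplanar_angle"] >= criteria.pipi_e2f_angle_min - EPS)
    if rec.kind == "pi_cation":
        return g["distance"] <= criteria.pication_max + EPS
    if rec.kind == "hydrophobic":
        return g["distance"] <= criteria.hydrophobic_max + EPS
    if rec.kind == "ionic":
        return g["distance"] <= criteria.ionic_max + EPS
    raise ValueError(f"unknown record kind {rec.kind!r}")


def contact_distance_table(
    complex_: Complex,
    residue_keys: list[str],
    criteria: GeometricCriteria | None = None,
) -> pd.DataFrame:
    """Minimum-distance contact table for the listed protein residues.

    One row per (residue, interaction kind) with the minimum distance and
    closest parts; weak C-H...heteroatom proximities (within the docking
    cutoff) are reported under the ``ch_contact`` label since they are not a
    first-class hydrogen-bond kind. Unknown residue keys raise ``KeyError``.
    """
    criteria = criteria or GeometricCriteria()
    known = {r.key for r in complex_.protein_residues}
    for key in residue_keys:
        if key not in known:
            raise KeyError(f"unknown residue key {key!r}")
    wanted = set(residue_keys)

    rows = []
    for kind, records in detect_all(complex_, criteria).items():
        best: dict[str, InteractionRecord] = {}
        for rec in records:
            if rec.residue_key not in wanted:
                continue
            prev = best.get(rec.residue_key)
            if prev is None or rec.geometry["distance"] < prev.geometry["distance"]:
                best[rec.residue_key] = rec
        for key, rec in best.items():
            rows.append({
                "residue": key,
                "ligand_atom": rec.part_label(rec.ligand_part),
                "protein_atom": rec.part_label(rec.protein_part),
                "distance": round(rec.geometry["distance"], 3),
                "kind": kind,
            })
    rows += _weak_ch_rows(complex_, wanted, criteria)
    df = pd.DataFrame(rows, columns=["residue", "ligand_atom", "protein_atom",
                                     "distance", "kind"])
    return df.sort_values(["residue", "distance", "kind"]).reset_index(drop=True)


def _weak_ch_rows(complex_: Complex, wanted: set[str],
                  criteria: GeometricCriteria) -> list[dict]:
    """Closest C-H...heteroatom proximity per residue (docking cutoff)."""
    lig_ch = [a for a in complex_.ligand.atoms
              if a.is_hydrogen and a.parent_heavy is not None
              and a.parent_heavy.element.upper() == "C"]
    best: dict[str, tuple[float, Atom, Atom]] = {}
    for res in complex_.protein_residues:
        if res.key not in wanted:
            continue
        hets = [a for a in res.atoms
                if not a.is_hydrogen and a.element.upper() in HETEROATOMS]
        for h in lig_ch:
            for het in hets:
                d = distance(h.coords, het.coords)
                if d <= criteria.docking_contact_max + EPS and \
                        (res.key not in best or d < best[res.key][0]):
                    best[res.key] = (d, h, het)
    return [
        {"residue": key, "ligand_atom": h.name, "protein_atom": het.name,
         "distance": round(d, 3), "kind": "ch_contact"}
        for key, (d, h, het) in best.items()
    ]


def records_to_frame(records: list[InteractionRecord]) -> pd.DataFrame:
    """Flatten records for TSV/JSON export (fixed column order)."""
    cols = ["kind", "residue", "ligand_part", "protein_part", "water", "subtype",
            "frame", "distance", "donor_angle", "acceptor_angle",
            "interplanar_angle", "lig_water_distance", "water_prot_distance"]
    rows = [rec.to_row() for rec in records]
    df = pd.DataFrame(rows)
    for c in cols:
        if c not in df.columns:
            df[c] = ""
    return df[cols].fillna("")
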