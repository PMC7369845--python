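"""Independent brute-force detection oracles.

Pure-Python all-pairs / all-triples re-implementations of every geometric
criterion, written with their own distance/angle arithmetic (math module, no
numpy) so they share nothing with the package's detection path except the
perceived role annotations and the inclusive-bound convention. Each oracle
returns a normalized comparable (set or Counter) and each package record
list has a matching normalizer.
"""

from __future__ import annotations

import math
from collections import Counter

EPS = 1e-9


def _dist(p, q) -> float:
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))


def _angle_at(a, b, c) -> float:
    u = [a[i] - b[i] for i in range(3)]
    v = [c[i] - b[i] for i in range(3)]
    nu = math.sqrt(sum(x * x for x in u))
    nv = math.sqrt(sum(x * x for x in v))
    cosang = sum(x * y for x, y in zip(u, v)) / (nu * nv)
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def _side(atom, cplx) -> str:
    if atom.residue is cplx.ligand:
        return "ligand"
    if atom.residue.is_water:
        return "water"
    return "protein"


def _newell_normal(coords):
    """Ring plane normal by Newell's method (independent of SVD)."""
    nx = ny = nz = 0.0
    n = len(coords)
    for i in range(n):
        x1, y1, z1 = coords[i]
        x2, y2, z2 = coords[(i + 1) % n]
        nx += (y1 - y2) * (z1 + z2)
        ny += (z1 - z2) * (x1 + x2)
        nz += (x1 - x2) * (y1 + y2)
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return (nx / norm, ny / norm, nz / norm)


def _centroid(coords):
    n = len(coords)
    return tuple(sum(c[i] for c in coords) / n for i in range(3))


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def oracle_docking(cplx, crit) -> Counter:
    chem = cplx.annotations
    out = Counter()
    for h_side, a_side in (("ligand", "protein"), ("protein", "ligand")):
        hs = [h for d, h in chem.donors if _side(d, cplx) == h_side]
        residues = [cplx.ligand] if a_side == "ligand" else cplx.protein_residues
        hets = [a for r in residues for a in r.atoms
                if not a.is_hydrogen and a.element.upper() in ("N", "O", "S")]
        for h in hs:
            for het in hets:
                if _dist(h.coords, het.coords) <= crit.docking_contact_max + EPS:
                    out[(h.serial, het.serial)] += 1
    return out


def normalize_docking(records) -> Counter:
    out = Counter()
    for rec in records:
        h = rec.ligand_part if rec.subtype == "ligand_h" else rec.protein_part
        het = rec.protein_part if rec.subtype == "ligand_h" else rec.ligand_part
        out[(h.serial, het.serial)] += 1
    return out


def _hbond_pass(donor, h, acc, xs, da_max, don_min, acc_min, quantifier) -> bool:
    if _dist(donor.coords, acc.coords) > da_max + EPS:
        return False
    if _angle_at(donor.coords, h.coords, acc.coords) < don_min - EPS:
        return False
    if xs:
        angles = [_angle_at(h.coords, acc.coords, x.coords) for x in xs]
        test = all if quantifier == "every" else any
        if not test(a >= acc_min - EPS for a in angles):
            return False
    return True


def oracle_hbonds(cplx, crit) -> Counter:
    chem = cplx.annotations
    out = Counter()
    for d_side, a_side in (("ligand", "protein"), ("protein", "ligand")):
        for donor, h in chem.donors:
            if _side(donor, cplx) != d_side:
                continue
            for acc, xs in chem.acceptors.items():
                if _side(acc, cplx) != a_side:
                    continue
                if _hbond_pass(donor, h, acc, xs, crit.hbond_da_max,
                               crit.hbond_donor_angle_min,
                               crit.hbond_acceptor_angle_min,
                               crit.acceptor_quantifier):
                    out[(donor.serial, acc.serial)] += 1
    return out


def normalize_hbonds(records) -> Counter:
    out = Counter()
    for rec in records:
        donor, acc = ((rec.ligand_part, rec.protein_part)
                      if rec.subtype == "ligand_donor"
                      else (rec.protein_part, rec.ligand_part))
        out[(donor.serial, acc.serial)] += 1
    return out


def oracle_water_bridges(cplx, crit) -> set:
    chem = cplx.annotations
    out = set()
    for water in cplx.waters:
        w_donors = [(d, h) for d, h in chem.donors if d.residue is water]
        w_o = next((a for a in water.atoms if a.element.upper() == "O"), None)

        def links(side):
            partners = set()
            for d, h in w_donors:
                for acc, xs in chem.acceptors.items():
                    if _side(acc, cplx) != side:
                        continue
                    if _hbond_pass(d, h, acc, xs, crit.wb_da_max,
                                   crit.wb_donor_angle_min,
                                   crit.wb_acceptor_angle_min,
                                   crit.acceptor_quantifier):
                        partners.add(acc)
            if w_o is not None:
                for d, h in chem.donors:
                    if _side(d, cplx) != side:
                        continue
                    if _hbond_pass(d, h, w_o, [], crit.wb_da_max,
                                   crit.wb_donor_angle_min,
                                   crit.wb_acceptor_angle_min,
                                   crit.acceptor_quantifier):
                        partners.add(d)
            return partners

        for la in links("ligand"):
            for pa in links("protein"):
                out.add((la.serial, pa.residue.key, water.key))
    return out


def normalize_water_bridges(records) -> set:
    return {(rec.ligand_part.serial, rec.residue_key, rec.water_key)
            for rec in records}


def oracle_pi_pi(cplx, crit) -> set:
    chem = cplx.annotations
    out = set()
    lig_rings = [r for r in chem.rings if r.residue is cplx.ligand]
    prot_rings = [r for r in chem.rings
                  if r.residue is not cplx.ligand and not r.residue.is_water]
    for lr in lig_rings:
        lc = _centroid([a.coords for a in lr.member_atoms])
        ln = _newell_normal([a.coords for a in lr.member_atoms])
        for pr in prot_rings:
            pc = _centroid([a.coords for a in pr.member_atoms])
            pn = _newell_normal([a.coords for a in pr.member_atoms])
            c = _dist(lc, pc)
            cosang = abs(sum(a * b for a, b in zip(ln, pn)))
            theta = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
            subtype = None
            if theta <= crit.pipi_f2f_angle_max + EPS and \
                    c <= crit.pipi_f2f_centroid_max + EPS:
                subtype = "face_to_face"
            elif theta >= crit.pipi_e2f_angle_min - EPS and \
                    c <= crit.pipi_e2f_centroid_max + EPS:
                subtype = "edge_to_face"
            if subtype:
                out.add((frozenset(a.serial for a in lr.member_atoms),
                         frozenset(a.serial for a in pr.member_atoms), subtype))
    return out


def normalize_pi_pi(records) -> set:
    return {
        (frozenset(a.serial for a in rec.ligand_part.member_atoms),
         frozenset(a.serial for a in rec.protein_part.member_atoms), rec.subtype)
        for rec in records
    }


def oracle_pi_cation(cplx, crit) -> set:
    chem = cplx.annotations
    out = set()
    for ring_side, cat_side in (("ligand", "protein"), ("protein", "ligand")):
        rings = [r for r in chem.rings
                 if _side(r.member_atoms[0], cplx) == ring_side]
        cats = [g for g in chem.pos_charges
                if _side(g.atoms[0], cplx) == cat_side]
        for ring in rings:
            centroid = _centroid([a.coords for a in ring.member_atoms])
            for cat in cats:
                site = _centroid([a.coords for a in cat.site_atoms])
                if _dist(centroid, site) <= crit.pication_max + EPS:
                    out.add((frozenset(a.serial for a in ring.member_atoms),
                             frozenset(a.serial for a in cat.atoms)))
    return out


def normalize_pi_cation(records) -> set:
    out = set()
    for rec in records:
        ring = rec.ligand_part if rec.subtype == "ligand_ring" else rec.protein_part
        cat = rec.protein_part if rec.subtype == "ligand_ring" else rec.ligand_part
        out.add((frozenset(a.serial for a in ring.member_atoms),
                 frozenset(a.serial for a in cat.atoms)))
    return out


def oracle_hydrophobic(cplx, crit) -> set:
    chem = cplx.annotations
    lig = [a for a in chem.hydrophobic_atoms if _side(a, cplx) == "ligand"]
    prot = [a for a in chem.hydrophobic_atoms if _side(a, cplx) == "protein"]
    best = {}
    for la in lig:
        for pa in prot:
            d = _dist(la.coords, pa.coords)
            if d > crit.hydrophobic_max + EPS:
                continue
            key = pa.residue.key
            if key not in best or d < best[key][0]:
                best[key] = (d, la.serial, pa.serial)
    return {(k, la, pa, round(d, 9)) for k, (d, la, pa) in best.items()}


def normalize_hydrophobic(records) -> set:
    return {(rec.residue_key, rec.ligand_part.serial, rec.protein_part.serial,
             round(rec.geometry["distance"], 9)) for rec in records}


def oracle_ionic(cplx, crit) -> set:
    chem = cplx.annotations
    engaged = set()
    for (d, a) in oracle_hbonds(cplx, crit):
        engaged.update((d, a))
    out = set()
    pos = {"ligand": [], "protein": []}
    neg = {"ligand": [], "protein": []}
    for g in chem.pos_charges:
        s = _side(g.atoms[0], cplx)
        if s in pos:
            pos[s].append(g)
    for g in chem.neg_charges:
        s = _side(g.atoms[0], cplx)
        if s in neg:
            neg[s].append(g)
    for lgs, pgs in ((pos["ligand"], neg["protein"]), (neg["ligand"], pos["protein"])):
        for lg in lgs:
            for pg in pgs:
                site_l = _centroid([a.coords for a in lg.site_atoms])
                site_p = _centroid([a.coords for a in pg.site_atoms])
                if _dist(site_l, site_p) > crit.ionic_max + EPS:
                    continue
                if any(a.serial in engaged for a in (*lg.atoms, *pg.atoms)):
                    continue
                out.add((frozenset(a.serial for a in lg.atoms),
                         frozenset(a.serial for a in pg.atoms)))
    return out


def normalize_ionic(records) -> set:
    return {(frozenset(a.serial for a in rec.ligand_part.atoms),
             frozenset(a.serial for a in rec.protein_part.atoms))
            for rec in records}


#: (oracle, package detector name, record normalizer) per kind
PAIRS = {
    "hbond_contact_docking": (oracle_docking, normalize_docking),
    "hbond": (oracle_hbonds, normalize_hbonds),
    "water_bridge": (oracle_water_bridges, normalize_water_bridges),
    "pi_pi": (oracle_pi_pi, normalize_pi_pi),
    "pi_cation": (oracle_pi_cation, normalize_pi_cation),
    "hydrophobic": (oracle_hydrophobic, normalize_hydrophobic),
    "ionic": (oracle_ionic, normalize_ionic),
}
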