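"""Geometric detectors: boundary fixtures, oracle equivalence, invariances."""

import numpy as np
import pytest

import oracles
from conftest import SIX_KINDS, assemble, atom, residue
from plinteract.geometry import rotation_matrix
from plinteract.interactions import (
    GeometricCriteria,
    contact_distance_table,
    detect_all,
    detect_hbond_contacts_docking,
    detect_hbonds,
    detect_ionic,
    detect_pi_cation,
    detect_pi_pi,
    revalidate,
)
from plinteract.perception import perceive
from plinteract.synthetic import PlantSpec, build_pocket, random_scene

CRIT = GeometricCriteria()


# ---------------------------------------------------------------------------
# hand-constructed geometries
# ---------------------------------------------------------------------------

def _hbond_fixture(d_pos, h_pos, a_pos, x_pos):
    """Ligand N-H donating to a protein backbone carbonyl O (neighbour C)."""
    lig = residue("LIG", 900, [atom("N1", "N", d_pos), atom("H1", "H", h_pos),
                               atom("C9", "C", np.asarray(d_pos) + (0, 0, 40.0))])
    prot = residue("GLY", 1, [atom("O", "O", a_pos), atom("C", "C", x_pos)])
    return assemble([prot], lig)


def test_hbond_collinear_construction_detected():
    cplx = _hbond_fixture((0, 0, 0), (1, 0, 0), (2.4, 0, 0), (2.4, 1, 0))
    (rec,) = detect_hbonds(cplx, CRIT)
    assert rec.geometry["distance"] == pytest.approx(2.4)
    assert rec.geometry["donor_angle"] == pytest.approx(180.0)
    assert rec.geometry["acceptor_angle"] == pytest.approx(90.0)
    assert revalidate(rec, CRIT)


def test_hbond_distance_bound_is_exclusive_past_cutoff():
    cplx = _hbond_fixture((0, 0, 0), (1, 0, 0), (2.6, 0, 0), (2.6, 1, 0))
    assert detect_hbonds(cplx, CRIT) == []


def test_hbond_donor_angle_fails_at_90():
    cplx = _hbond_fixture((0, 0, 0), (0, 1, 0), (2.0, 1, 0), (2.0, 2, 0))
    assert detect_hbonds(cplx, CRIT) == []


def test_hbond_acceptor_angle_quantifier():
    """With a second acceptor neighbour violating the 90 deg test, the
    'every' quantifier rejects and 'any' accepts."""
    lig = residue("LIG", 900, [atom("N1", "N", (0, 0, 0)),
                               atom("H1", "H", (1, 0, 0)),
                               atom("C9", "C", (0, 0, 40.0))])
    # X1 at 90 deg (passes), X2 on the hydrogen side, ~10 deg (fails)
    prot = residue("GLY", 1, [atom("O", "O", (2.4, 0, 0)),
                              atom("C", "C", (2.4, 1, 0)),
                              atom("CA", "C", (1.2, 0.2, 0))])
    cplx = assemble([prot], lig)
    chem = cplx.annotations
    o = cplx.protein_residues[0].atom("O")
    chem.acceptors[o] = [cplx.protein_residues[0].atom("C"),
                         cplx.protein_residues[0].atom("CA")]
    assert detect_hbonds(cplx, CRIT) == []
    import dataclasses
    assert len(detect_hbonds(
        cplx, dataclasses.replace(CRIT, acceptor_quantifier="any"))) == 1


def test_docking_contact_inclusive_bound():
    lig = residue("LIG", 900, [atom("N1", "N", (-1, 0, 0)),
                               atom("H1", "H", (0, 0, 0)),
                               atom("C9", "C", (0, 0, 40.0))])
    prot = residue("GLY", 1, [atom("O", "O", (3.2, 0, 0))])
    cplx = assemble([prot], lig)
    (rec,) = detect_hbond_contacts_docking(cplx, CRIT)
    assert rec.geometry["distance"] == pytest.approx(3.2)
    prot2 = residue("GLY", 1, [atom("O", "O", (3.25, 0, 0))])
    lig2 = residue("LIG", 900, [atom("N1", "N", (-1, 0, 0)),
                                atom("H1", "H", (0, 0, 0)),
                                atom("C9", "C", (0, 0, 40.0))])
    assert detect_hbond_contacts_docking(assemble([prot2], lig2), CRIT) == []


def _two_rings(centroid_dist, tilt_deg):
    scene = build_pocket(
        [PlantSpec(kind="pi_pi",
                   geometry_params={"distance": centroid_dist, "angle": tilt_deg})],
        seed=0,
    )
    perceive(scene.complex)
    return scene.complex


@pytest.mark.parametrize(
    "dist, tilt, subtype",
    [
        (3.4, 0.0, "face_to_face"),   # parallel stacking geometry
        (3.7, 90.0, "edge_to_face"),  # T-shaped arrangement
        (6.0, 0.0, None),             # beyond both centroid cutoffs
        (4.7, 0.0, None),             # parallel but too far for face-to-face
    ],
)
def test_pi_pi_subtypes(dist, tilt, subtype):
    records = detect_pi_pi(_two_rings(dist, tilt), CRIT)
    if subtype is None:
        assert records == []
    else:
        (rec,) = records
        assert rec.subtype == subtype
        assert rec.geometry["distance"] == pytest.approx(dist)


def test_pi_cation_boundary():
    def scene(d):
        s = build_pocket([PlantSpec(kind="pi_cation",
                                    geometry_params={"distance": d})], seed=0)
        perceive(s.complex)
        return s.complex
    (rec,) = detect_pi_cation(scene(4.4), CRIT)
    assert rec.geometry["distance"] == pytest.approx(4.4)
    assert detect_pi_cation(scene(4.6), CRIT) == []


def test_ionic_inclusive_and_hbond_precedence():
    # bare +/- pair at exactly 3.7 A: ionic fires
    lig = residue("LIG", 900, [atom("N1", "N", (0, 0, 0), charge=+1),
                               atom("C9", "C", (0, 0, 40.0))])
    prot = residue("GLU", 1, [atom("OE1", "O", (3.7, 1.1, 0)),
                              atom("OE2", "O", (3.7, -1.1, 0)),
                              atom("CD", "C", (4.4, 0, 0))])
    cplx = assemble([prot], lig)
    (rec,) = detect_ionic(cplx, CRIT)
    assert rec.geometry["distance"] == pytest.approx(3.7)
    # same charge pair but with a qualifying D-H...A geometry: suppressed
    glu_atoms = lambda: [atom("OE1", "O", (2.3, 0, 0)),
                         atom("OE2", "O", (2.3, -2.2, 0)),
                         atom("CD", "C", (2.915, 1.065, 0))]
    lig2 = residue("LIG", 900, [atom("N1", "N", (0, 0, 0), charge=+1),
                                atom("H1", "H", (1.0, 0, 0)),
                                atom("C9", "C", (0, 0, 40.0))])
    cplx2 = assemble([residue("GLU", 1, glu_atoms())], lig2)
    assert len(detect_hbonds(cplx2, CRIT)) == 1
    assert detect_ionic(cplx2, CRIT) == []
    # without the hydrogen the same geometry counts as ionic
    lig3 = residue("LIG", 900, [atom("N1", "N", (0, 0, 0), charge=+1),
                                atom("C9", "C", (0, 0, 40.0))])
    assert len(detect_ionic(assemble([residue("GLU", 1, glu_atoms())], lig3),
                            CRIT)) == 1


# ---------------------------------------------------------------------------
# oracle equivalence, invariances
# ---------------------------------------------------------------------------

DETECTORS = {
    "hbond": detect_hbonds,
    "hbond_contact_docking": detect_hbond_contacts_docking,
}


@pytest.mark.parametrize("seed", range(12))
def test_detectors_equal_brute_force_oracles(seed):
    cplx = perceive(random_scene(seed))
    results = detect_all(cplx, CRIT)
    for kind, (oracle, normalize) in oracles.PAIRS.items():
        assert normalize(results[kind]) == oracle(cplx, CRIT), kind


@pytest.mark.parametrize("seed", [3, 17])
def test_detection_invariant_under_rigid_motion(seed):
    cplx = perceive(random_scene(seed))
    before = {k: sorted((r.residue_key, r.kind,
                         round(r.geometry["distance"], 5)) for r in v)
              for k, v in detect_all(cplx, CRIT).items()}
    rng = np.random.default_rng(seed)
    R = rotation_matrix(rng.normal(size=3), float(rng.uniform(10, 350)))
    t = rng.uniform(-20, 20, size=3)
    cplx.set_coords(cplx.coords_array() @ R.T + t)
    perceive(cplx)
    after = {k: sorted((r.residue_key, r.kind,
                        round(r.geometry["distance"], 5)) for r in v)
             for k, v in detect_all(cplx, CRIT).items()}
    assert before == after


@pytest.mark.parametrize("seed", [1, 5])
def test_every_record_revalidates(seed):
    cplx = perceive(random_scene(seed))
    for kind, records in detect_all(cplx, CRIT).items():
        for rec in records:
            assert revalidate(rec, CRIT), (kind, rec.geometry)


def test_tightening_thresholds_never_adds_records():
    import dataclasses
    cplx = perceive(random_scene(23))
    loose = detect_all(cplx, CRIT)
    tight_crit = dataclasses.replace(
        CRIT,
        docking_contact_max=2.9, hbond_da_max=2.3, wb_da_max=2.5,
        pication_max=4.0, hydrophobic_max=3.2, ionic_max=3.3,
        pipi_f2f_centroid_max=4.0, pipi_e2f_centroid_max=5.0,
        hbond_donor_angle_min=140.0, wb_donor_angle_min=130.0,
    )
    tight = detect_all(cplx, tight_crit)
    for kind, (_oracle, normalize) in oracles.PAIRS.items():
        if kind == "ionic":
            continue  # tightening the H-bond angle can un-exclude an ionic pair
        assert set(normalize(tight[kind])) <= set(normalize(loose[kind])), kind


# ---------------------------------------------------------------------------
# contact tables
# ---------------------------------------------------------------------------

def test_contact_table_planted_hbond():
    scene = build_pocket(
        [PlantSpec(kind="hbond", residue_name="GLU", seq_number=917,
                   geometry_params={"distance": 2.30})],
        seed=2,
    )
    perceive(scene.complex)
    table = contact_distance_table(scene.complex, ["GLU917"], CRIT)
    hbond_rows = table[table["kind"] == "hbond"]
    assert list(hbond_rows["residue"]) == ["GLU917"]
    assert hbond_rows["distance"].iloc[0] == pytest.approx(2.30)


def test_contact_table_empty_and_unknown_key(six_plant_scene):
    cplx = six_plant_scene.complex
    assert contact_distance_table(cplx, [], CRIT).empty
    with pytest.raises(KeyError, match="GLU999"):
        contact_distance_table(cplx, ["GLU999"], CRIT)
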