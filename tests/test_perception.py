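"""Role perception, termini ionisation, pocket extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import assemble, atom, residue
from plinteract.geometry import interplanar_angle
from plinteract.perception import (
    AromaticRing,
    extract_pocket,
    ionize_termini,
    perceive,
)
from plinteract.synthetic import _SCENE_TEMPLATES, random_scene, toy_indazole


def _residue_from_template(name, seq, offset=(0, 0, 0), chain="A"):
    return residue(
        name, seq,
        [atom(nm, el, np.asarray(xyz, float) + np.asarray(offset, float))
         for nm, el, xyz in _SCENE_TEMPLATES[name]],
        chain=chain,
    )


def _far_ligand():
    return residue("LIG", 900, [atom("C1", "C", (90, 0, 0)),
                                atom("C2", "C", (91.5, 0, 0)),
                                atom("C3", "C", (90.7, 1.3, 0))])


def test_lysine_roles():
    cplx = assemble([_residue_from_template("LYS", 1)], _far_ligand())
    chem = cplx.annotations
    nz = cplx.protein_residues[0].atom("NZ")
    assert any(d is nz for d, _h in chem.donors)
    assert any(g.sign == +1 and g.atoms == [nz] for g in chem.pos_charges)


def test_glutamate_roles():
    cplx = assemble([_residue_from_template("GLU", 1)], _far_ligand())
    chem = cplx.annotations
    res = cplx.protein_residues[0]
    oe1, oe2 = res.atom("OE1"), res.atom("OE2")
    assert oe1 in chem.acceptors and oe2 in chem.acceptors
    assert chem.acceptors[oe1] == [res.atom("CD")]
    (neg,) = chem.neg_charges
    assert neg.sign == -1
    assert np.allclose(neg.site, (oe1.coords + oe2.coords) / 2)


def test_toy_indazole_ligand_roles():
    """Fused 5+6 aromatic system with N-H, pyridinic N and a sulfonyl group:
    two rings, the N-H donates, pyridinic N and both sulfonyl O accept."""
    lig = residue("LIG", 900, toy_indazole(np.zeros(3)))
    anchor = residue("GLY", 1, [atom("N", "N", (50, 0, 0))])
    cplx = assemble([anchor], lig)
    chem = cplx.annotations
    assert sorted(len(r.member_atoms) for r in chem.rings) == [5, 6]
    lig_donors = [(d.name, h.name) for d, h in chem.donors if d.residue is lig]
    assert lig_donors == [("N1", "H1")]
    lig_acceptors = sorted(a.name for a in chem.acceptors if a.residue is lig)
    assert lig_acceptors == ["N2", "O1", "O2"]
    for ring in chem.rings:
        assert ring.planarity_rms <= 0.1
        assert np.isclose(np.linalg.norm(ring.normal), 1.0)


def test_perceive_is_deterministic_and_idempotent(six_plant_scene):
    cplx = six_plant_scene.complex
    first = perceive(cplx).annotations
    second = perceive(cplx).annotations
    assert [(d.serial, h.serial) for d, h in first.donors] == \
           [(d.serial, h.serial) for d, h in second.donors]
    assert [a.serial for a in first.acceptors] == [a.serial for a in second.acceptors]
    assert [frozenset(a.serial for a in r.member_atoms) for r in first.rings] == \
           [frozenset(a.serial for a in r.member_atoms) for r in second.rings]


def test_ring_normal_flip_is_angle_invariant():
    lig = residue("LIG", 900, toy_indazole(np.zeros(3)))
    anchor = residue("GLY", 1, [atom("N", "N", (50, 0, 0))])
    cplx = assemble([anchor], lig)
    ring = cplx.annotations.rings[0]
    flipped = AromaticRing(member_atoms=list(reversed(ring.member_atoms)))
    assert np.allclose(np.abs(np.dot(ring.normal, flipped.normal)), 1.0)
    other = cplx.annotations.rings[1]
    assert np.isclose(
        interplanar_angle(ring.normal, other.normal),
        interplanar_angle(flipped.normal, other.normal),
    )


def test_ionize_termini_single_and_multi_chain():
    chains = [
        _residue_from_template("ALA", 1),
        _residue_from_template("GLY", 2, offset=(6, 0, 0)),
        _residue_from_template("SER", 3, offset=(12, 0, 0)),
        _residue_from_template("ALA", 11, offset=(0, 12, 0), chain="B"),
        _residue_from_template("GLY", 12, offset=(6, 12, 0), chain="B"),
    ]
    cplx = assemble(chains, _far_ligand())
    base_pos = len(cplx.annotations.pos_charges)
    base_neg = len(cplx.annotations.neg_charges)
    ionize_termini(cplx)
    assert len(cplx.annotations.pos_charges) == base_pos + 2  # one per chain
    assert len(cplx.annotations.neg_charges) == base_neg + 2
    ionize_termini(cplx)  # idempotent
    assert len(cplx.annotations.pos_charges) == base_pos + 2
    assert len(cplx.annotations.neg_charges) == base_neg + 2


def test_ionize_single_residue_chain_carries_both_charges():
    cplx = assemble([_residue_from_template("ALA", 1)], _far_ligand())
    n_pos, n_neg = len(cplx.annotations.pos_charges), len(cplx.annotations.neg_charges)
    ionize_termini(cplx)
    assert len(cplx.annotations.pos_charges) == n_pos + 1
    assert len(cplx.annotations.neg_charges) == n_neg + 1


def test_extract_pocket_residue_boundary():
    lig = residue("LIG", 900, [atom("C1", "C", (0, 0, 0)),
                               atom("C2", "C", (1.5, 0, 0)),
                               atom("C3", "C", (0.7, 1.3, 0))])
    near = residue("ALA", 1, [atom("N", "N", (5.4, 0, 0)),
                              atom("CA", "C", (6.8, 0, 0))])  # 3.9 A from C2
    far = residue("ALA", 2, [atom("N", "N", (-4.1, 0, 0)),
                             atom("CA", "C", (-5.5, 0, 0))])  # 4.1 A from C1
    cplx = assemble([near, far], lig)
    pocket = extract_pocket(cplx, 4.0)
    assert [r.seq_number for r in pocket.protein_residues] == [1]
    # residues are kept whole
    assert len(pocket.protein_residues[0].atoms) == 2


@settings(deadline=None, max_examples=20)
@given(seed=st.integers(0, 10_000), radius=st.floats(2.0, 10.0))
def test_extract_pocket_matches_all_pairs_scan(seed, radius):
    cplx = random_scene(seed, n_protein=8, n_waters=2)
    pocket = extract_pocket(cplx, radius)
    lig = np.array([a.coords for a in cplx.ligand.atoms])
    expected = set()
    for res in (*cplx.protein_residues, *cplx.waters):
        coords = np.array([a.coords for a in res.atoms])
        d = np.linalg.norm(lig[:, None, :] - coords[None, :, :], axis=2)
        if d.min() <= radius:
            expected.add((res.chain_id, res.seq_number))
    got = {(r.chain_id, r.seq_number)
           for r in (*pocket.protein_residues, *pocket.waters)}
    assert got == expected


@settings(deadline=None, max_examples=15)
@given(seed=st.integers(0, 10_000),
       radii=st.tuples(st.floats(2.0, 8.0), st.floats(2.0, 8.0)))
def test_extract_pocket_monotone_in_radius(seed, radii):
    r1, r2 = sorted(radii)
    cplx = random_scene(seed, n_protein=8, n_waters=2)
    small = {(r.chain_id, r.seq_number)
             for r in extract_pocket(cplx, r1).protein_residues}
    large = {(r.chain_id, r.seq_number)
             for r in extract_pocket(cplx, r2).protein_residues}
    assert small <= large


def test_extract_pocket_rejects_nonpositive_radius(six_plant_scene):
    with pytest.raises(ValueError):
        extract_pocket(six_plant_scene.complex, 0.0)
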