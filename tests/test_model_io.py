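"""Structure/trajectory/table I/O: partitioning, round trips, error paths."""

import numpy as np
import pytest

from plinteract.errors import (
    EnergyTableError,
    FrameError,
    SelectionError,
    TopologyError,
)
from plinteract.model_io import (
    read_complex,
    read_energy_table,
    read_trajectory,
    write_complex,
    write_trajectory,
)
from plinteract.synthetic import PlantSpec, build_pocket, build_trajectory

TOY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.400   2.400   0.300  1.00  0.00           O
ATOM      5  N   GLY A   2       4.000   0.000   0.000  1.00  0.00           N
ATOM      6  CA  GLY A   2       5.458   0.000   0.000  1.00  0.00           C
ATOM      7  N   SER A   3       8.000   0.000   0.000  1.00  0.00           N
ATOM      8  CA  SER A   3       9.458   0.000   0.000  1.00  0.00           C
HETATM    9  C1  LIG A 900      15.000   0.000   0.000  1.00  0.00           C
HETATM   10  N1  LIG A 900      16.300   0.000   0.000  1.00  0.00           N
HETATM   11  O   HOH W 501      20.000   0.000   0.000  1.00  0.00           O
HETATM   12  H1  HOH W 501      20.960   0.000   0.000  1.00  0.00           H
END
"""


def test_read_complex_partitions_protein_ligand_water(tmp_path):
    p = tmp_path / "toy.pdb"
    p.write_text(TOY_PDB)
    cplx = read_complex(p, "LIG")
    assert len(cplx.protein_residues) == 3
    assert cplx.ligand.name == "LIG" and len(cplx.ligand.atoms) == 2
    assert len(cplx.waters) == 1
    assert cplx.n_atoms == 12  # no record silently dropped
    water_h = cplx.waters[0].atoms[1]
    assert water_h.parent_heavy is cplx.waters[0].atoms[0]


def test_ligand_selector_must_match_exactly_one(tmp_path):
    p = tmp_path / "toy.pdb"
    p.write_text(TOY_PDB)
    with pytest.raises(SelectionError):
        read_complex(p, "XXX")  # zero matches
    with pytest.raises(SelectionError):
        read_complex(p, "HOH")  # water cannot be the ligand
    cplx = read_complex(p, "A:900")
    assert cplx.ligand.name == "LIG"


def test_orphan_hydrogen_raises_topology_error(tmp_path):
    bad = TOY_PDB.replace(
        "HETATM   12  H1  HOH W 501      20.960",
        "HETATM   12  H1  HOH W 501      25.960",
    )
    p = tmp_path / "bad.pdb"
    p.write_text(bad)
    with pytest.raises(TopologyError):
        read_complex(p, "LIG")


def test_complex_roundtrip_is_write_stable(tmp_path):
    scene = build_pocket(
        [PlantSpec(kind="hbond"), PlantSpec(kind="pi_pi")],
        n_decoy_residues=3, seed=5,
    )
    p1, p2 = tmp_path / "a.pdb", tmp_path / "b.pdb"
    write_complex(scene.complex, p1, remarks=["SEED 5"])
    reread = read_complex(p1, "LIG")
    assert reread.n_atoms == scene.complex.n_atoms
    assert [a.name for a in reread.atoms()] == [a.name for a in scene.complex.atoms()]
    # coordinates round-trip to the writer's 3-decimal precision
    assert np.abs(reread.coords_array() - scene.complex.coords_array()).max() <= 5e-4
    write_complex(reread, p2, remarks=["SEED 5"])
    assert p1.read_bytes() == p2.read_bytes()


def test_trajectory_roundtrip_and_times(tmp_path):
    scene = build_pocket([PlantSpec(kind="hbond")], n_decoy_residues=2, seed=3)
    traj, _ = build_trajectory(scene, n_frames=5, jitter_sd=0.02, seed=4)
    p = tmp_path / "t.pdb"
    write_trajectory(traj, p)
    back = read_trajectory(p, scene.complex)
    assert back.n_frames == 5
    assert back.times == [0.0, 1.0, 2.0, 3.0, 4.0]
    for a, b in zip(traj.frames, back.frames):
        assert np.abs(a - b).max() <= 1e-3


def test_trajectory_single_model(tmp_path):
    scene = build_pocket([PlantSpec(kind="hbond")], seed=3)
    traj, _ = build_trajectory(scene, n_frames=1, seed=4)
    p = tmp_path / "t.pdb"
    write_trajectory(traj, p)
    back = read_trajectory(p, scene.complex)
    assert back.n_frames == 1 and back.times == [0.0]


def test_trajectory_atom_count_mismatch_names_model(tmp_path):
    scene = build_pocket([PlantSpec(kind="hbond")], seed=3)
    traj, _ = build_trajectory(scene, n_frames=3, seed=4)
    p = tmp_path / "t.pdb"
    write_trajectory(traj, p)
    lines = p.read_text().splitlines()
    # drop one atom line from the second MODEL block
    second_model = [i for i, l in enumerate(lines) if l.startswith("MODEL")][1]
    atom_line = next(i for i in range(second_model, len(lines))
                     if lines[i].startswith(("ATOM", "HETATM")))
    del lines[atom_line]
    p.write_text("\n".join(lines) + "\n")
    with pytest.raises(FrameError, match="model 2"):
        read_trajectory(p, scene.complex)


def test_biopython_agrees_on_coordinates(tmp_path):
    """Cross-check the internal PDB codec against Biopython's parser."""
    Bio = pytest.importorskip("Bio.PDB")
    scene = build_pocket([PlantSpec(kind="hbond"), PlantSpec(kind="ionic")],
                         n_decoy_residues=2, seed=9)
    p = tmp_path / "x.pdb"
    write_complex(scene.complex, p)
    mine = read_complex(p, "LIG")
    parser = Bio.PDBParser(QUIET=True)
    structure = parser.get_structure("x", str(p))
    ours = {
        (a.residue.chain_id, a.residue.seq_number, a.name): a.coords
        for a in mine.atoms()
    }
    n_checked = 0
    for bio_atom in structure.get_atoms():
        _, _, chain, (_, seq, _), (name, _) = bio_atom.get_full_id()
        key = (chain, seq, name)
        assert key in ours
        assert np.abs(np.asarray(bio_atom.coord) - ours[key]).max() <= 1e-3
        n_checked += 1
    assert n_checked == mine.n_atoms


SAPT_ROW = (
    "ligand\tresidue\te_elst\te_exch\te_ind\te_disp\n"
    "8\tALA866\t-5.32\t5.67\t-1.48\t-5.14\n"
)


def test_energy_table_row_without_total(tmp_path):
    p = tmp_path / "s.tsv"
    p.write_text(SAPT_ROW)
    (rec,) = read_energy_table(p, "sapt")
    assert rec.e_total is None
    assert (rec.e_elst, rec.e_exch, rec.e_ind, rec.e_disp) == (-5.32, 5.67, -1.48, -5.14)


def test_energy_table_header_only_and_errors(tmp_path):
    p = tmp_path / "s.tsv"
    p.write_text("ligand\tresidue\te_elst\te_exch\te_ind\te_disp\n")
    assert read_energy_table(p, "sapt") == []
    p.write_text(SAPT_ROW.replace("5.67", "abc"))
    with pytest.raises(EnergyTableError, match="row 0"):
        read_energy_table(p, "sapt")
    with pytest.raises(EnergyTableError, match="schema"):
        read_energy_table(p, "mulliken")
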