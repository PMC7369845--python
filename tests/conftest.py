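"""Shared fixtures and construction helpers."""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from plinteract.model_io import Atom, Complex, Residue
from plinteract.perception import perceive
from plinteract.synthetic import PLANT_KINDS, PlantSpec, build_pocket

SIX_KINDS = ("hbond", "water_bridge", "pi_pi", "pi_cation", "hydrophobic", "ionic")


def atom(name, element, xyz, charge=0):
    return Atom(serial=0, name=name, element=element,
                coords=np.asarray(xyz, float),
                is_hydrogen=element.upper() == "H", formal_charge=charge)


def assemble(protein_residues, ligand, waters=()):
    """Renumber serials, link hydrogens, build and perceive a Complex."""
    serial = 0
    for res in (*protein_residues, ligand, *waters):
        for a in res.atoms:
            serial += 1
            a.serial = serial
    cplx = Complex(protein_residues=list(protein_residues), ligand=ligand,
                   waters=list(waters))
    for res in cplx.residues():
        heavies = res.heavy_atoms()
        for h in res.atoms:
            if h.is_hydrogen and heavies:
                h.parent_heavy = min(
                    heavies, key=lambda x: np.linalg.norm(h.coords - x.coords))
    return perceive(cplx)


def residue(name, seq, atoms, chain="A"):
    res = Residue(chain_id=chain, seq_number=seq, name=name)
    for a in atoms:
        res.add(a)
    return res


@pytest.fixture(scope="session")
def six_plant_scene():
    """One plant of each of the six interaction classes plus decoys."""
    specs = [PlantSpec(kind=k) for k in SIX_KINDS]
    scene = build_pocket(specs, n_decoy_residues=4, seed=11)
    perceive(scene.complex)
    return scene


@pytest.fixture(scope="session")
def all_kind_scene():
    """All seven plant kinds (adds the docking-stage contact plant)."""
    specs = [PlantSpec(kind=k) for k in PLANT_KINDS]
    scene = build_pocket(specs, n_decoy_residues=4, seed=7)
    perceive(scene.complex)
    return scene
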