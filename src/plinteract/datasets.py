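"""Bundled worked-example energy tables.

Curated reference interaction-energy decompositions for a set of
arylsulphonyl azole ligands (numbered 1-9) against VEGFR2 ATP-pocket
residues: per-pair SAPT0 components (electrostatics, exchange, induction,
dispersion), per-pair PIEDA components (E_es, E_ex, E_CT+mix, E_disp, G_sol)
and per-ligand total interaction energies (TIE). Stored totals are carried
as published, including a deliberately retained internally inconsistent
PIEDA row (ligand 8 / Glu885) and one SAPT row (ligand 8 / Glu885) whose
printed total drifts from its component sum - both exercise the consistency
checker.
"""

from __future__ import annotations

from importlib import resources

from .model_io import PiedaRecord, SaptRecord, read_energy_table


def _data_path(name: str):
    return resources.files("plinteract.data").joinpath(name)


def load_sapt_reference() -> list[SaptRecord]:
    with resources.as_file(_data_path("sapt_reference.tsv")) as p:
        return read_energy_table(p, "sapt")


def load_pieda_reference() -> list[PiedaRecord]:
    with resources.as_file(_data_path("pieda_reference.tsv")) as p:
        return read_energy_table(p, "pieda")


def load_tie_reference() -> dict[str, float]:
    """Per-ligand total interaction energies, kcal/mol."""
    import pandas as pd
    with resources.as_file(_data_path("tie_reference.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype={"ligand": str})
    return dict(zip(df["ligand"], df["tie"].astype(float)))
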