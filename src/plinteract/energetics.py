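"""Aggregation of externally computed interaction-energy decompositions.

This module does arithmetic and bookkeeping only: SAPT0 and PIEDA component
totals with stored-total consistency checking, two-body FMO (FMO2) total
assembly, the total interaction energy (TIE) over per-residue pair
interaction energies, the Raha-Merz thermodynamic-cycle interaction enthalpy,
and deterministic ligand ranking. All energies are plain floats in kcal/mol;
computing the underlying quantum-chemical numbers is upstream of this
package.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .model_io import EnthalpyRecord, PiedaRecord, SaptRecord

#: stored-total agreement tolerances (kcal/mol), sized to absorb the rounding
#: drift of 2-3 decimal printed tables
SAPT_TOTAL_TOL = 0.005
PIEDA_TOTAL_TOL = 0.015

#: default pair-interaction-energy magnitude cutoff for TIE inclusion
TIE_THRESHOLD = 3.0


@dataclass
class TieSummary:
    """Total interaction energy for one ligand: the sum of per-residue pair
    interaction energies whose magnitude meets the inclusion threshold."""

    ligand_id: str
    tie: float
    included_residues: list[tuple[str, float]]
    threshold: float


@dataclass
class ConsistencyFlag:
    """A stored total that disagrees with its component sum."""

    ligand_id: str
    residue_key: str
    stored_total: float
    component_sum: float

    @property
    def deviation(self) -> float:
        return self.stored_total - self.component_sum


def sapt_total(record: SaptRecord) -> float:
    """SAPT0 total = electrostatics + exchange + induction + dispersion."""
    return record.e_elst + record.e_exch + record.e_ind + record.e_disp


def pieda_total(record: PiedaRecord) -> float:
    """PIEDA total = E_es + E_ex + E_CT+mix + E_disp + G_sol."""
    return record.e_es + record.e_ex + record.e_ct_mix + record.e_disp + record.g_sol


def check_consistency(records, tolerance: float | None = None) -> list[ConsistencyFlag]:
    """Flag records whose stored total deviates from the component sum by
    more than the tolerance. Report-only: stored totals are never 'corrected'
    (printed tables are occasionally internally inconsistent, and that fact
    is itself worth surfacing)."""
    flags = []
    for rec in records:
        if isinstance(rec, SaptRecord):
            stored, total = rec.e_total, sapt_total(rec)
            tol = SAPT_TOTAL_TOL if tolerance is None else tolerance
        elif isinstance(rec, PiedaRecord):
            stored, total = rec.e_tot, pieda_total(rec)
            tol = PIEDA_TOTAL_TOL if tolerance is None else tolerance
        else:
            raise TypeError(f"cannot check {type(rec).__name__}")
        if stored is not None and abs(stored - total) > tol:
            flags.append(ConsistencyFlag(rec.ligand_id, rec.residue_key, stored, total))
    return flags


def fmo2_total(monomer_energies, dimer_energies) -> float:
    """Two-body FMO total energy: sum_{I>J} E_IJ - (N-2) * sum_I E_I.

    ``dimer_energies`` maps unordered fragment index pairs to dimer energies
    and must cover every pair; a missing pair raises ``KeyError`` naming it.
    """
    monomers = list(monomer_energies)
    n = len(monomers)
    if n < 2:
        raise ValueError("FMO2 needs >=2 fragments")
    normalized = {}
    for (i, j), e in dimer_energies.items():
        normalized[(min(i, j), max(i, j))] = e
    dimer_sum = 0.0
    for j in range(n):
        for i in range(j + 1, n):
            pair = (j, i)
            if pair not in normalized:
                raise KeyError(f"missing dimer energy for pair {pair}")
            dimer_sum += normalized[pair]
    return dimer_sum - (n - 2) * sum(monomers)


def tie(
    records: list[PiedaRecord],
    threshold: float = TIE_THRESHOLD,
    use_magnitude: bool = True,
) -> TieSummary:
    """Total interaction energy for one ligand's PIEDA records.

    Residues with |E_tot| >= threshold (inclusive) contribute; with
    ``use_magnitude=False`` the raw signed E_tot is compared instead. The
    per-record total is the stored E_tot when present, else the component
    sum.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    ligands = {r.ligand_id for r in records}
    if len(ligands) > 1:
        raise ValueError(f"records span multiple ligands: {sorted(ligands)}")
    included = []
    for rec in records:
        e_tot = rec.e_tot if rec.e_tot is not None else pieda_total(rec)
        measure = abs(e_tot) if use_magnitude else e_tot
        if measure >= threshold:
            included.append((rec.residue_key, e_tot))
    included.sort(key=lambda pair: (pair[1], pair[0]))
    return TieSummary(
        ligand_id=next(iter(ligands)) if ligands else "",
        tie=sum(e for _, e in included),
        included_residues=included,
        threshold=threshold,
    )


def interaction_enthalpy(record: EnthalpyRecord) -> float:
    """Thermodynamic-cycle interaction enthalpy:
    dH_int = dHf(PL) - [dHf_complex(P) + dHf_complex(L)]."""
    return record.hf_complex - (
        record.hf_protein_in_complex + record.hf_ligand_in_complex
    )


def rank_ligands(energies: dict[str, float] | list[TieSummary]) -> pd.DataFrame:
    """Rank ligands ascending by energy (most negative = strongest binder
    first); ties broken by ligand id, lexicographic. Accepts a plain
    ligand->energy mapping or a list of :class:`TieSummary`."""
    if isinstance(energies, dict):
        items = list(energies.items())
    else:
        items = [(s.ligand_id, s.tie) for s in energies]
    if not items:
        raise ValueError("nothing to rank")
    items.sort(key=lambda kv: (kv[1], kv[0]))
    return pd.DataFrame(
        {"rank": range(1, len(items) + 1),
         "ligand": [k for k, _ in items],
         "energy": [v for _, v in items]}
    )
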