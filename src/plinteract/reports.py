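"""Pipeline orchestration: pose and trajectory report bundles.

Pure functions of (inputs, configuration, seed): rerunning with the same
arguments produces byte-identical output files. Machine-readable outputs go
to files only; logging goes to stderr with stage tags.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .interactions import (
    GeometricCriteria,
    contact_distance_table,
    detect_all,
    records_to_frame,
)
from .model_io import Complex, Trajectory, read_complex, read_trajectory
from .perception import PerceptionOptions, extract_pocket, ionize_termini, perceive
from .trajectory import ligand_rmsd, occupancy, residue_rmsf

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Shared run configuration; defaults follow the study conventions
    (4 A binding sphere, |PIE| >= 3 kcal/mol TIE threshold)."""

    complex_path: str | None = None
    trajectory_path: str | None = None
    ligand_selector: str = "LIG"
    criteria_overrides: dict = field(default_factory=dict)
    pocket_radius: float = 4.0
    tie_threshold: float = 3.0
    ionize: bool = False
    reference_frame: int = 0
    seed: int = 0
    out_dir: str = "."

    def __post_init__(self):
        if self.pocket_radius <= 0:
            raise ValueError("pocket_radius must be > 0")
        if self.tie_threshold < 0:
            raise ValueError("tie_threshold must be >= 0")

    def criteria(self) -> GeometricCriteria:
        return GeometricCriteria().updated(self.criteria_overrides)

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _write_json(payload, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def run_pose_analysis(config: RunConfig, complex_: Complex | None = None) -> dict:
    """Pocket extraction -> perception -> all detectors -> contact tables.

    Returns a bundle mapping output names to file paths; also includes the
    in-memory records under ``"records"``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if complex_ is None:
        log.info("[read] loading complex from %s", config.complex_path)
        complex_ = read_complex(config.complex_path, config.ligand_selector)
    log.info("[pocket] extracting binding sphere, radius %.2f A", config.pocket_radius)
    pocket = extract_pocket(complex_, config.pocket_radius)
    log.info("[perceive] annotating chemistry")
    perceive(pocket, PerceptionOptions())
    if config.ionize:
        ionize_termini(pocket)
    criteria = config.criteria()
    log.info("[detect] running all detectors")
    by_kind = detect_all(pocket, criteria)
    records = [rec for records in by_kind.values() for rec in records]
    pocket_keys = sorted(r.key for r in pocket.protein_residues)
    table = contact_distance_table(pocket, pocket_keys, criteria)

    contacts_path = out / "contacts.tsv"
    table.to_csv(contacts_path, sep="\t", index=False)
    records_path = out / "records.tsv"
    records_to_frame(records).to_csv(records_path, sep="\t", index=False)
    summary = {
        "n_pocket_residues": len(pocket.protein_residues),
        "n_waters": len(pocket.waters),
        "counts": {kind: len(v) for kind, v in by_kind.items()},
        "residues": {
            kind: sorted({rec.residue_key for rec in v})
            for kind, v in by_kind.items()
        },
    }
    summary_path = out / "summary.json"
    _write_json(summary, summary_path)
    return {
        "contacts": contacts_path,
        "records_table": records_path,
        "summary": summary_path,
        "records": by_kind,
        "pocket": pocket,
    }


def run_trajectory_analysis(
    config: RunConfig,
    trajectory: Trajectory | None = None,
) -> dict:
    """RMSD (both alignment modes), RMSF and occupancy over a trajectory,
    plus a per-residue stacked-fraction interaction diagram (JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if trajectory is None:
        log.info("[read] loading topology and trajectory")
        topo = read_complex(config.complex_path, config.ligand_selector)
        trajectory = read_trajectory(config.trajectory_path, topo)
    criteria = config.criteria()

    log.info("[rmsd] ligand RMSD, both modes")
    rmsd_rows = {"time_ps": trajectory.times}
    for mode in ("lig_fit_protein", "lig_fit_lig"):
        series = ligand_rmsd(trajectory, mode=mode,
                             reference_frame=config.reference_frame)
        rmsd_rows[mode] = [round(v, 6) for v in series.values]
    rmsd_path = out / "rmsd.tsv"
    pd.DataFrame(rmsd_rows).to_csv(rmsd_path, sep="\t", index=False)

    rmsf_path = out / "rmsf.tsv"
    if trajectory.n_frames >= 2:
        log.info("[rmsf] per-residue backbone RMSF")
        rmsf = residue_rmsf(trajectory)
        pd.DataFrame(
            {"residue": list(rmsf), "rmsf": [round(v, 6) for v in rmsf.values()]}
        ).to_csv(rmsf_path, sep="\t", index=False)
    else:
        pd.DataFrame({"residue": [], "rmsf": []}).to_csv(rmsf_path, sep="\t", index=False)

    log.info("[occupancy] per-residue interaction occupancy")
    profile = occupancy(trajectory, criteria)
    occ_rows = [
        {"residue": res, "kind": kind, "fraction": round(frac, 6)}
        for (res, kind), frac in sorted(profile.entries.items())
    ]
    occ_path = out / "occupancy.tsv"
    pd.DataFrame(occ_rows, columns=["residue", "kind", "fraction"]).to_csv(
        occ_path, sep="\t", index=False
    )

    diagram: dict[str, dict[str, float]] = {}
    for (res, kind), frac in sorted(profile.entries.items()):
        diagram.setdefault(res, {})[kind] = round(frac, 6)
    diagram_path = out / "diagram.json"
    _write_json({"n_frames": profile.n_frames, "residues": diagram}, diagram_path)

    return {
        "rmsd": rmsd_path,
        "rmsf": rmsf_path,
        "occupancy": occ_path,
        "diagram": diagram_path,
        "profile": profile,
    }
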