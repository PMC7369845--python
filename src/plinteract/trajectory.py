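"""Time-series analytics over a trajectory: ligand RMSD, per-residue RMSF,
and per-residue interaction occupancy.

RMSD modes follow the MD-analysis convention: ``lig_fit_protein`` superposes
each frame's protein backbone (N, CA, C) onto the reference frame's backbone
and then measures the ligand heavy-atom RMSD without further fitting (pocket
stability); ``lig_fit_lig`` superposes the ligand onto its own reference
conformation first (internal fluctuation). RMSF aligns every frame onto the
time-mean backbone structure (mean and fit iterated twice) and reports the
per-residue root-mean-square displacement. Heavy atoms only throughout:
hydrogen positions are noise-dominated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import AlignmentError
from .interactions import GeometricCriteria, detect_all
from .model_io import Complex, Trajectory
from .perception import PerceptionOptions, perceive

BACKBONE_NAMES = ("N", "CA", "C")


@dataclass
class RmsdSeries:
    mode: str
    values: np.ndarray
    reference_frame: int
    times: list[float]

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if np.any(self.values < -1e-12):
            raise ValueError("RMSD values must be non-negative")


@dataclass
class OccupancyProfile:
    """Fraction of frames, per (residue, interaction kind), with >=1 contact."""

    entries: dict[tuple[str, str], float]
    n_frames: int

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        for key, frac in self.entries.items():
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"fraction out of [0,1] for {key}")

    def fraction(self, residue_key: str, kind: str) -> float:
        return self.entries.get((residue_key, kind), 0.0)


# ---------------------------------------------------------------------------
# rigid superposition
# ---------------------------------------------------------------------------

def superpose(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares rigid fit of ``mobile`` onto ``reference``.

    Returns (R, t) with ``mobile @ R.T + t ~= reference``. Raises
    :class:`AlignmentError` for <3 atoms or collinear/degenerate sets rather
    than returning an arbitrary rotation.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.shape[0] < 3:
        raise AlignmentError("need >=3 matched atoms for a rigid fit")
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    for pts in (mobile - mc, reference - rc):
        s = np.linalg.svd(pts, compute_uv=False)
        if s[1] < 1e-8 * max(1.0, s[0]):
            raise AlignmentError("degenerate (collinear) atom configuration")
    rot, _ = Rotation.align_vectors(reference - rc, mobile - mc)
    R = rot.as_matrix()
    t = rc - mc @ R.T
    return R, t


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def _atom_indices(complex_: Complex):
    """(protein backbone heavy indices, ligand heavy indices, per-residue
    backbone index map) into the canonical atom order."""
    backbone, ligand, by_residue = [], [], {}
    for i, atom in enumerate(complex_.atoms()):
        res = atom.residue
        if res is complex_.ligand:
            if not atom.is_hydrogen:
                ligand.append(i)
        elif not res.is_water and atom.name in BACKBONE_NAMES and not atom.is_hydrogen:
            backbone.append(i)
            by_residue.setdefault(res.key, []).append(i)
    return np.array(backbone), np.array(ligand), {
        k: np.array(v) for k, v in by_residue.items()
    }


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def ligand_rmsd(
    traj: Trajectory, mode: str = "lig_fit_protein", reference_frame: int = 0
) -> RmsdSeries:
    if mode not in ("lig_fit_protein", "lig_fit_lig"):
        raise ValueError(f"unknown RMSD mode {mode!r}")
    backbone, ligand, _ = _atom_indices(traj.topology)
    if len(ligand) < 3:
        raise AlignmentError("ligand needs >=3 heavy atoms for RMSD")
    ref = traj.frames[reference_frame]
    values = []
    for frame in traj.frames:
        if mode == "lig_fit_protein":
            R, t = superpose(frame[backbone], ref[backbone])
            moved = frame[ligand] @ R.T + t
            values.append(_rmsd(moved, ref[ligand]))
        else:
            R, t = superpose(frame[ligand], ref[ligand])
            moved = frame[ligand] @ R.T + t
            values.append(_rmsd(moved, ref[ligand]))
    return RmsdSeries(mode=mode, values=np.array(values),
                      reference_frame=reference_frame, times=list(traj.times))


def residue_rmsf(traj: Trajectory, n_iterations: int = 2) -> dict[str, float]:
    """Per-residue backbone RMSF about the time-mean structure.

    Frames are aligned on the protein backbone to the running mean structure
    and the mean is recomputed, iterated ``n_iterations`` times.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs >=2 frames")
    backbone, _, by_residue = _atom_indices(traj.topology)
    frames = np.array([f[backbone] for f in traj.frames])
    mean = frames[0].copy()
    aligned = frames.copy()
    for _ in range(n_iterations):
        for i in range(len(frames)):
            R, t = superpose(frames[i], mean)
            aligned[i] = frames[i] @ R.T + t
        mean = aligned.mean(axis=0)
    disp2 = np.sum((aligned - mean) ** 2, axis=2)  # (n_frames, n_backbone)
    pos_of = {idx: j for j, idx in enumerate(backbone)}
    out = {}
    for key, idxs in by_residue.items():
        cols = [pos_of[i] for i in idxs]
        out[key] = float(np.sqrt(np.mean(disp2[:, cols])))
    return out


def occupancy(
    traj: Trajectory,
    criteria: GeometricCriteria | None = None,
    options: PerceptionOptions | None = None,
) -> OccupancyProfile:
    """Per-(residue, kind) fraction of frames with at least one contact.

    Presence is binary per frame (instance multiplicity is not counted), so
    fractions are bounded by 1. Role perception is done once on the topology;
    only coordinate-derived ring geometry is refreshed per frame.
    """
    criteria = criteria or GeometricCriteria()
    topo = traj.topology
    base = topo.coords_array()
    if topo.annotations is None:
        perceive(topo, options)
    counts: dict[tuple[str, str], int] = {}
    try:
        for frame_idx, frame in enumerate(traj.frames):
            topo.set_coords(frame)
            topo.annotations.refresh_geometry()
            present = set()
            for kind, records in detect_all(topo, criteria).items():
                for rec in records:
                    present.add((rec.residue_key, kind))
            for key in present:
                counts[key] = counts.get(key, 0) + 1
    finally:
        topo.set_coords(base)
        topo.annotations.refresh_geometry()
    n = traj.n_frames
    return OccupancyProfile(
        entries={k: c / n for k, c in sorted(counts.items())}, n_frames=n
    )
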