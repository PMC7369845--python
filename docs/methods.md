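# Methods

## Scope and model

`plinteract` treats a protein–ligand complex as a purely geometric object:
atoms with coordinates, residues, perceived chemical roles. Interaction
classes are defined by explicit distance/angle criteria, not by energies or
force fields. The package therefore answers *fingerprint* questions
(which residue, which class, how often) and does *bookkeeping* of interaction
energies computed upstream (SAPT0, FMO2/PIEDA, semi-empirical heats of
formation); it never computes quantum-chemical or molecular-mechanics
energies itself.

## Chemical-role perception

Protein roles come from a fixed per-residue lookup over the 20 standard
amino acids plus water: backbone carbonyl O and sidechain O/N/S acceptors
with their bonded neighbours (the X of the H⋯A–X acceptor-angle test),
donors as any hydrogen bonded to N/O/S, aromatic rings for Phe/Tyr/Trp/His,
charged groups for Lys/Arg/Asp/Glu, and hydrophobic sidechain atoms for
{Ala, Val, Leu, Ile, Pro, Met, Phe, Trp, Tyr-ring, Cys-SG}. Carboxylate and
guanidinium charge sites are the O/N midpoint so the 3.7 Å ionic criterion
treats both oxygens symmetrically.

Ligand roles use element/connectivity heuristics on a distance-derived bond
graph (heavy–heavy cutoff 1.75 Å, 1.95 Å when sulfur is involved): N/O/S
with an explicit hydrogen donate; any O, H-free N with ≤ 2 heavy neighbours
and no positive formal charge (pyridinic), and divalent H-free S accept;
5/6-membered C/N/S rings with RMS out-of-plane deviation ≤ 0.1 Å count as
aromatic; carbons bonded only to C/H/S are hydrophobic. Formal charges are
read from the input (no pKa model). Histidine is neutral by default
(ND1/NE2 acceptors), switchable to protonated. Hydrogens attach to their
parent heavy atom by the nearest-neighbour rule with a 1.2 Å covalent cap,
because CONECT records are unreliable in practice.

Chain termini can be ionised (NH3+ on the first residue's backbone N, COO−
at the last residue's O/OXT midpoint); the operation is idempotent and a
single-residue chain legitimately carries both charges.

Pocket extraction keeps whole residues: any residue (or water) with at
least one atom within the binding-sphere radius (default 4 Å) of any ligand
atom survives. Membership is monotone in the radius.

## Geometric criteria and conventions

All thresholds are inclusive. Comparisons carry a 1e-9 slack so that
analytically constructed boundary fixtures (an H⋯O pair at exactly 3.2 Å)
are not lost to binary floating-point representation; the slack is far below
any experimentally meaningful precision.

Two hydrogen-contact notions coexist deliberately. The docking-stage
criterion is a proton-to-heteroatom distance (≤ 3.2 Å, no angles) — the
loose filter used when scoring docked poses. The MD-style hydrogen bond is
donor–acceptor distance ≤ 2.5 Å with donor angle ≥ 120° and acceptor angle
≥ 90°. The acceptor-angle test applies to *every* bonded neighbour X of the
acceptor by default (the stricter reading; `any` is available), and passes
vacuously for acceptors with no heavy neighbour (water O), which is logged.
Weak C–H⋯O proximities are not a first-class class; they appear only in the
contact-distance table under `ch_contact`.

Ring normals have arbitrary sign, so interplanar angles are folded to
[0°, 90°]. The π–π centroid cutoffs (4.4 Å face-to-face, 5.5 Å
edge-to-face) and angle bands (≤ 30°, ≥ 60°) were chosen so that the
canonical parallel stack at 3.4 Å and T-shaped arrangement at 3.7 Å are
detected while a 4.7 Å parallel separation — commonly regarded as
negligible stacking — is not.

Ionic contacts have hydrogen-bond precedence: a ≤ 3.7 Å opposite-charge
pair whose atoms already appear in an H-bond record of the same frame is
not double-counted as ionic.

## Trajectory statistics

Superpositions are least-squares rigid fits (Kabsch, via
`scipy.spatial.transform.Rotation.align_vectors`); fewer than three atoms or
a collinear configuration raises an error rather than returning an arbitrary
rotation. Heavy atoms only — hydrogen positions are noise-dominated.

- `lig_fit_protein`: fit each frame's protein backbone (N, CA, C) onto the
  reference frame, then measure ligand heavy-atom RMSD without further
  fitting. Measures pose stability within the pocket.
- `lig_fit_lig`: fit the ligand onto its reference conformation first;
  measures internal ligand fluctuation only.
- RMSF: frames are aligned on the backbone to the time-mean structure, with
  mean and fit iterated twice (the reference choice — first frame vs mean —
  is not standardised in the literature; the mean structure is used here and
  converges in two iterations for the trajectories at hand). Per-residue
  RMSF is the root-mean-square displacement of that residue's backbone
  atoms about their mean positions.
- Occupancy: presence is binary per frame per (residue, class) — instance
  multiplicity is not counted — so fractions are bounded by 1, matching how
  interaction histograms are conventionally reported. Role perception runs
  once on the topology; only coordinate-derived ring geometry is refreshed
  per frame.

## Energy bookkeeping

Energies are plain floats in kcal/mol. Stored totals in input tables are
checked against component sums with tolerances sized to printed-table
rounding: 0.005 kcal/mol for 4-component SAPT0 rows, 0.015 kcal/mol for
5-component PIEDA rows. The checker reports inconsistent rows and never
alters them — the bundled reference tables intentionally retain one
published PIEDA row (ligand 8 / Glu885) whose stored total disagrees with
its component sum by ~2.2 kcal/mol, and one SAPT0 row with a 0.01 kcal/mol
printing drift, as permanent checker test articles. Whether published E_tot
values include G_sol is not always internally consistent; the component-sum
convention here includes it, which reproduces all but that one row.

TIE inclusion uses the magnitude reading |E_tot| ≥ 3 kcal/mol (inclusive):
the cutoff phrase "PIE ≥ 3 kcal/mol" is sign-ambiguous in common usage while
reported TIE contributions are attractive; the signed reading is available
via a flag. Ranking is ascending (most negative first) with lexicographic
ligand-id tie-break, so it is deterministic.

## Synthetic study conditions

The generator is the stand-in for undeposited docked poses, trajectories
and QM tables, and its defaults *are* the study conditions:

- Planted geometries sit comfortably inside their criteria: H-bond at
  2.30 Å/180°/120° (within the 2.25–2.30 Å range typical of strong
  pyrrolic-NH⋯carbonyl contacts), water bridge 2.50 Å per link, π-stack at
  3.7 Å centroids (also the canonical T-shape separation; chosen over
  3.4 Å so the stack is not simultaneously a ≤ 3.6 Å hydrophobic contact),
  π–cation 4.0 Å, hydrophobic 3.4 Å, ionic 3.4 Å.
- Plants are spaced 14 Å apart (≥ 8 Å exclusion), with an idealised planar
  arylsulphonyl-indazole-like scaffold anchoring the ligand and chemically
  quiet decoys (Ala/Leu/Ser/Gly) rejection-placed ≥ 8 Å from everything.
- Trajectories switch each plant on per frame with an independent Bernoulli
  draw; "off" frames displace the plant's ligand atoms 4 Å away from the
  partner (≥ 1.5 Å beyond every criterion). Background Gaussian jitter is
  capped at σ = 0.05 Å so planted margins hold at several standard
  deviations; larger jitter raises an error instead of silently eroding the
  truth. Occupancy probabilities 0.10/0.37/0.62/0.99 mirror the range of
  occupancies reported in kinase-pocket MD interaction histograms.
- Energy tables draw components from ±20 kcal/mol ranges matching published
  table magnitudes; corrupted rows perturb the stored total by
  0.05–0.5 kcal/mol, safely past both tolerances.
- Everything is a pure function of (spec, seed): regeneration is
  byte-identical, with the seed recorded in a PDB REMARK.

What the synthetic scenes deliberately do **not** emulate: physically
relaxed conformations, rotamer statistics, solvent structure, or realistic
contact correlations. Passing tests therefore demonstrate that the
*measurement machinery* is exact on known geometry and calibrated
statistically — not that any particular real complex behaves this way.

## Numerical and design notes

- PDB I/O is a compact fixed-column codec (3-decimal coordinates,
  deterministic record order, altloc 'A'/blank kept with a warning for the
  rest, per-model `REMARK ... TIME <ps>`); round trips are stable to the
  writer's precision and the reader reports parse errors with line numbers.
  Coordinates are Å throughout.
- Ring member order is canonicalised (lowest-serial atom first, walking
  toward its lower-serial neighbour) so ring labels and outputs are
  byte-stable across runs.
- Detectors prune candidate pairs with k-d trees; equivalence with plain
  all-pairs/all-triples enumeration is asserted exactly in the test suite
  over randomized scenes of ≤ 200 atoms.
- Problem sizes in the shipped checks — 100 random oracle scenes, 1000-frame
  occupancy runs, 1000-draw arithmetic cross-checks — were chosen to give
  tight statistical bounds (3 binomial SDs at n = 1000 is ±4.6 percentage
  points at p = 0.37) while remaining interactive to run.

## Known limitations

- No bond-order/aromaticity perception beyond planarity heuristics; exotic
  ligand chemotypes (e.g. charged heteroaromatics) may need explicit formal
  charges in the input.
- Hydrogens must be explicit for donor-side criteria; there is no hydrogen
  placement.
- Water bridges are single-water only; no higher-order bridge chains.
- Halogen bonds, salt-bridge networks and SASA-based terms are out of scope.
- mmCIF and binary trajectory formats (DCD/XTC) are not read; multi-model
  PDB keeps the artifact diffable and dependency-light.
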