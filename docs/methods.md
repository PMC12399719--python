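# Methods

This note records the models, parameter choices and numerical conventions
behind `consdock`, and what the synthetic-data tests do and do not
demonstrate about real screening data.

## Symmetry-aware pose RMSD

Two docked conformations of one ligand are compared over heavy atoms only
(hydrogens are excluded throughout; docked hydrogen placement is
engine-dependent and carries no signal).  Chemical equivalence is captured
by the automorphism group of the heavy-atom multigraph: nodes are labelled
by element, edges by bond order, with aromatic treated as its own order
rather than resolved to alternating single/double bonds.  This reproduces
the carboxylate-oxygen and phenyl-flip equivalences without any
format-specific canonicalisation, but it also means a protonated acid drawn
with distinct C=O / C–OH bonds is *not* symmetric — the equivalence is a
property of the input bond orders, by design.  Automorphisms are enumerated
by VF2 backtracking (networkx) with a configurable cap (default 10,000) so
pathological graphs fail loudly instead of hanging.

The default metric is **in-place** RMSD: docking poses share the receptor
frame, and redocking validation conventionally measures deviation without
re-superposition.  An optimal rigid (Kabsch) fit per automorphism is
available via `superpose=True`.  Redocking acceptance uses an inclusive
3.0 Å threshold.

For a multi-program ensemble the full symmetric n×n matrix is computed
(automorphisms enumerated once and reused).  Matrices are validated for
symmetry, non-negativity and zero diagonal on construction.

## Consensus clustering

Complete-linkage agglomerative clustering is implemented directly (about
thirty lines) rather than delegated, because the selection rule needs
deterministic tie-breaking: merges are chosen by smallest complete-linkage
distance, ties broken by the pair containing the smallest pose index, and
merging stops when the smallest inter-cluster distance exceeds the cutoff
(inclusive).  Cutting this way guarantees the defining invariant — every
within-cluster pose pair is within the cutoff (2.0 Å default) — and makes
the partition invariant to pose reordering.  The test suite cross-checks
the partition against scipy's independent complete-linkage implementation
and, on small n, against exhaustive enumeration of all valid partitions.

The **consensus level** counts *distinct programs* in the largest cluster,
not raw poses: a program contributing two nearby poses should not raise
confidence by itself.  The raw largest-cluster size is reported alongside.
Size ties go to the cluster with more distinct programs, then to the one
containing the smallest pose index.  Selection keeps ligands with level ≥
`min_level` (default 9 of 12) and emits a level histogram.

The binding-free-energy helper implements only the combination
ΔG_bind = E_complex − E_ligand − E_receptor; component energies come from
an external rescoring engine and are treated as opaque reals.

## Geometric interaction criteria

Hydrogen bonds: donor–acceptor heavy-atom distance ≤ 3.5 Å (inclusive) and
D–H···A angle measured **at the hydrogen** > 120° (exclusive).  Donors are
N/O — and thiol S — bearing an explicit hydrogen; acceptors are N/O/S.  No
charge- or hybridisation-dependent special cases: the filter is geometric
by construction, and a donor without an explicit hydrogen is skipped with a
warning rather than falling back to a distance-only rule.  On the ligand,
hydrogen attachment comes from the bond list; on the protein, from a
1.35 Å distance criterion within the residue (PDB files carry no bonds).
Catalytic-residue filtering accepts backbone or side-chain atoms of the
named residues.

π-stacking (centroid distance ≤ 5.5 Å; inter-normal angle ≤ 30° face-to-
face or within 30° of perpendicular edge-to-face), hydrophobic contacts
(ligand C to apolar side-chain C ≤ 4.5 Å, aggregated to one record per
residue) and halogen bonds (C–X···acceptor, X ∈ {Cl, Br, I}, ≤ 3.6 Å,
angle ≥ 140°) use conventional thresholds; none of these have a single
authoritative value, so all are exposed as parameters.

The hierarchical stage driver enforces pipeline ordering (a compound may
not appear in stage k+1 without surviving stage k) and books residual
percentages against the *first* stage's input.  Percentages are printed to
two decimals with round-half-even; published tables produced by other
software occasionally truncate instead (e.g. 0.91 where rounding gives
0.92), and this package documents its convention rather than matching that
anomaly.

## Gaussian shape overlap

Each heavy atom carries an isotropic Gaussian ρ(r) = P·exp(−α|r−c|²) with a
single uniform radius R = 1.70 Å (a carbon-like van der Waals radius; a
per-element table can be supplied, but a uniform radius keeps the grid
oracle and the analytic form trivially comparable).  P and α are pinned by
two constraints: the integral of one atomic Gaussian *and* its self-overlap
both equal the hard-sphere volume V_s = (4/3)πR³.  This gives P = 2√2 and
α = 2π·V_s^(−2/3), and makes the single-atom self-overlap exactly one hard
sphere.  Because the overlap of two density *sums* expands exactly into
pairwise Gaussian products, the first-order analytic expression

    V_AB = V_s · Σ_ij exp(−α·d_ij²/2)

is not an approximation to the model — grid integration at 0.05 Å agrees
within 1%.  The Tanimoto is V_AB/(V_AA+V_BB−V_AB).

Alignment is principal axes plus the four proper axis flips, no gradient
refinement: adequate for identity and near-identity comparisons, and
deliberately simple.  For molecules with (near-)degenerate principal
moments the frame is ambiguous and the aligned Tanimoto is a lower bound.
Conformer generation is the caller's responsibility: the screen that
motivated this package compared multi-conformer databases, and a
pre-computed multi-conformer SDF can be supplied, but the default compares
single conformers.

Drug-likeness checks are range rules over a user-supplied descriptor table
(Rule-of-Five defaults: MW ≤ 500, logP ≤ 5, donors ≤ 5, acceptors ≤ 10;
extended windows add logS ∈ [−6.5, 0.5] and PSA ∈ [7, 200] Å²).  RDKit
descriptor computation is provided as a convenience; predicted ADME
descriptors from proprietary tools are accepted as external input, never
reimplemented.

## Trajectory analysis

The RMSD reference is frame 0 of the supplied trajectory (configurable to
an external structure); every frame is superposed on the protein
α-carbons by a Kabsch fit before protein-Cα or ligand-heavy-atom RMSD is
measured.  Occupancy counts a frame once per (kind, chain, residue) key
even when several atom pairs qualify, matching how per-residue interaction
percentages are conventionally reported.  Windowed reports treat each
window as an independent trajectory (its first frame is the reference), so
whole-trajectory occupancy is exactly the frame-weighted mean of window
occupancies.

Trajectory clustering subsamples every stride-th **frame** (default 10).
A recording interval of 200 ps makes every 10th frame a 2 ns spacing; tool
documentation sometimes describes the same setting in nanoseconds, so the
stride is kept in frames and configurable.  Up to `max_clusters` (default
5) largest clusters are kept, the remainder pooled as unclustered; the
representative is the member of the most populated cluster minimising its
summed RMSD to co-members — always a real frame, never an average
structure.  The clustering cutoff has no defensible universal default and
is therefore a required argument.

## Synthetic data: what it shows and what it does not

The generators emulate the *statistical structure* each stage consumes:

- Pose ensembles plant `n_consensus` poses as rigid translations of a base
  pose within `cluster_radius`/2 (so any pair is within `cluster_radius`)
  and the remaining poses at magnitudes spaced by `outlier_offset`, making
  outliers mutually distant as well.  Defaults (12 programs, cluster radius
  1.0 Å, outlier offset 8.0 Å, cutoff 2.0 Å) keep the planted level
  unambiguous by construction.
- The pocket receptor is a seven-residue chain whose CYS 313/314 thiols
  point into open space; its backbone is deliberately non-collinear so an
  α-carbon fit pins all rotational degrees of freedom.  Contact poses place
  a carbonyl oxygen at exactly 2.8 Å / 160° from the thiol; non-contacts
  are displaced far outside the cap.
- Trajectories pin donor and acceptor atoms to the exact planted geometry
  (2.8 Å / 160° on planted frames, 4.5 Å otherwise) and add Gaussian noise
  (σ = 0.05 Å default) to everything else.  Deterministic planting makes
  occupancy recovery exact; stochastic planting is Bernoulli per frame.

Passing these tests demonstrates that the *machinery* — matrix, clustering,
level scoring, detectors, occupancy bookkeeping — is correct on inputs
whose ground truth is known.  It does not demonstrate anything about real
docking accuracy: synthetic poses are rigid translations (no internal
torsions), the pocket has no steric context, trajectories have no physics,
and planted geometries sit comfortably inside the criteria rather than at
their boundaries.  Real ensembles whose pose spread straddles the 2.0 Å
cutoff will be sensitive to it in ways the generator deliberately avoids.

## Numerical conventions and degenerate inputs

- Coordinates in Å; residue numbering verbatim from the file; 0-based atom
  indices internally, 1-based only in rendered reports.
- Aromaticity is trusted from input flags (SDF type 4, MOL2 `ar`), never
  re-perceived, keeping parity across formats.
- Hydrogens are never added implicitly; operations needing them state it.
- altloc duplicates in PDB input keep the highest-occupancy alternate and
  log the choice.
- Kabsch uses SVD with a determinant correction (proper rotations only);
  degenerate point sets (collinear fits) are the caller's concern, and the
  synthetic receptor is built to avoid them.
- All generator randomness flows through one `numpy` Generator per call,
  seeded explicitly; the clustering and selection paths contain no
  randomness at all.

## Known limitations

- No docking, scoring, MD integration or MM-GBSA component energies: this
  package is the analysis layer around such engines, not a replacement.
- No protonation/tautomer assignment or structure preparation; inputs are
  taken as given.
- Shape alignment has no gradient refinement and single-conformer defaults;
  scores are comparable within a run, not to proprietary shape tools.
- Ring-conformer flips that are not graph automorphisms (e.g. chair/boat)
  are outside the symmetry correction.
- The MOL2 reader accepts the TRIPOS dialect only; SDF is V2000 only.
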