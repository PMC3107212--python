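# Methods

## The screen

`clashscan` asks a purely geometric question: can a protein P bind partners
R and S at the same time? The inputs are two structures — one resolving the
complex P–R, the other P–S — and the answer is obtained by superimposing
the two P instances and measuring how much space the two partners would
have to share. The screen deliberately uses two unrelated volume estimators
and requires them to agree, so that a single method's discretization
artifacts cannot produce a spurious collision.

### Interface detection

A residue of chain A belongs to the A:B interface iff any of its heavy
atoms lies within `contact_cutoff` (default **5.0 Å**) of any heavy atom of
chain B. This is a deterministic stand-in for server-based interface
predictors; 5.0 Å between heavy-atom centers is a common contact criterion
that captures van der Waals contact plus water-mediated proximity.
Hydrogens are ignored (rarely present in crystal structures). Interfaces
with fewer than **5** residues on either side are discarded as unlikely to
represent functional binding.

Interfaces of the two P instances are compared **through the alignment**,
never through author residue numbers, which routinely disagree between
entries. The two interfaces are *distinct* only if they share no aligned
column at all — an intentionally strict definition, so that every reported
collision involves unambiguously separate binding sites. The shared
fraction reported for overlapping interfaces is normalized by the smaller
interface.

### Alignment

Instances of the same protein are aligned with Needleman–Wunsch
(BLOSUM62, gap open 10, gap extend 0.5). For the intended use case — two
depositions of the same sequence differing mainly in resolved residues —
any sensible scoring gives the same correspondence. Matched pairs are
restricted to residues with a Cα atom in both instances. Pairs are
discarded when the sequence lengths differ by more than **15** residues
(likely different constructs) or when fewer than **30** residues align
(fragments).

### Superposition

The rigid transform minimizing Cα RMSD over matched pairs is computed by
Kearsley's quaternion method: the residual sum of squares is a quadratic
form in the rotation quaternion, so the optimal rotation is the eigenvector
of a symmetric 4×4 matrix for its smallest eigenvalue, and
RMSD = √(λ₀/N). Unlike a naive SVD solution, the quaternion parametrization
cannot return a reflection. The quaternion's sign ambiguity is resolved by
requiring a non-negative scalar part. Near-collinear point sets (second
singular value ≈ 0) are rejected as degenerate rather than silently
returning an arbitrary rotation; such pairs are marked unevaluable and
excluded. Superpositions with RMSD ≥ **7 Å** are discarded as unreliable.

### Overlap volumes

The overlap of the secondary proteins, after transferring S into R's frame,
is V(R) + V(S) − V(R ∪ S), computed twice:

* **SES_GRID** — solvent-excluded volume on a voxel grid (default spacing
  **0.5 Å**, probe **1.5 Å**). Atom spheres inflated by the probe radius
  are rasterized; the set of voxels a probe center can reach from outside
  the box is found by connected-component labelling; the solvent region is
  that set dilated back by the probe radius (Euclidean distance transform),
  i.e. a morphological closing of the van der Waals union. Interior
  cavities count as molecular volume. Volumes are integrated with
  first-order partial-voxel weighting of a signed boundary field, which
  removes the grid-phase sensitivity of plain voxel counting (error on a
  1.9 Å sphere at 0.2 Å spacing: ≈ 0.2% instead of up to ±3%). The
  closing step retains an O(spacing) surface bias (≈ +4% on a 2 Å sphere,
  proportionally less for protein-sized bodies); both colliding partners
  are measured identically, so the bias largely cancels in the overlap.
* **SAS_MC** — the volume inside the solvent-accessible surface, i.e. of
  the union of atom spheres inflated by the probe (default **1.4 Å**),
  estimated by Monte-Carlo sampling (default **2×10⁶** points, fixed seed)
  over the joint bounding box. A single sample cloud classifies membership
  in R and S, so V(R) + V(S) − V(R ∪ S) holds exactly sample-by-sample and
  the overlap estimator is unbiased with a reported standard error.

Probe radii follow the conventional defaults of solvent-excluded
(1.5 Å) and solvent-accessible (1.4 Å) surface computations. Van der Waals
radii are Bondi-type values shipped with the package and configurable;
unknown elements fall back to 1.7 Å with a warning. Slightly negative
overlaps from discretization are clamped to zero (logged).

A pair is a collision only if **both** methods report ≥ **2000 Å³** of
overlap — a volume on the order of a dozen residues, far beyond any
discretization noise — mirroring a dual-method consistency requirement
rather than trusting either estimator alone.

### Threshold senses

"At least five residues", "at least thirty amino acids" and "at least
2000 Å³" are non-strict (≥); "less than 7 Å" is strict (<); sequence
lengths "differing by more than 15" are excluded, so a difference of
exactly 15 passes.

## Synthetic study conditions

The generator (`clashscan.synth`) builds complete two-structure scenarios
with certified ground truth and no input data:

* The primary chain is an idealized extended chain: Cα atoms 3.8 Å apart
  along an axis with an alternating 0.4 Å transverse offset (β-strand-like
  zig-zag — a perfectly collinear trace would make superposition
  degenerate), plus in-plane N, C, O (and Cβ) at standard bond-length
  offsets. Default length 40 residues.
* Secondary chains combine (i) contact residues placed 4.6 Å above chosen
  primary residues, a height at which exactly one primary residue lies
  within the 5.0 Å cutoff (nearest neighbours sit at ≥ 5.3 Å by
  construction), and (ii) a compact pseudo-domain of glycine atoms filling
  a ball of radius 10 Å on a 1.7 Å grid. Domains are deliberately not
  realistic folds: filling a ball guarantees that a ball of radius ≈ 10 Å
  (grid half-diagonal subtracted, smallest vdW radius added) is *completely
  covered*, so the overlap of two domains displaced by d is bounded below
  by the closed-form lens volume of two such balls.
* The second structure is built with 0.05 Å coordinate jitter (residual
  RMSD ≈ 0.09 Å) and then moved by an arbitrary rigid motion, which the
  superposition step must undo.
* Scenario displacement is restricted to regimes where the overlap gate's
  outcome is certain: |d| ≤ 4 Å keeps the lens bound ≥ 2999 Å³ (> 2000 with
  margin), |d| ≥ 38 Å separates every atom group by > 10 Å so the overlap
  is exactly zero. Requests in between are rejected rather than guessed.
* Ground truth is computed by mechanisms independent of the screen's
  implementation: interface sets by brute-force double loops over
  coordinates, the reference RMSD by a plain SVD (Kabsch) fit, and the
  overlap gate by the analytic lens bound. For gate-failure scenarios only
  the gates certified by construction are recorded as expected.

The 50-scenario ensemble (`make_ensemble`, seed 42 by default) mixes ~60%
clean collisions with varying displacement and one of each failure mode per
decade: separated domains, shared interface residues, undersized
interfaces, > 15-residue length difference, short chains, and a 90°-bent
second instance (superposition RMSD ≈ 20 Å).

What passing on this ensemble shows: the gate logic, the coordinate
bookkeeping across alignment/superposition/transfer, and the volumetric
estimators behave correctly on geometry with known answers. What it does
not show: robustness to real-structure pathologies — alternative
conformations, disordered termini, non-identical constructs mapped to one
accession, crystal-contact interfaces — beyond what the worked PDB
examples cover.

## Numerical choices

* Voxel grids add a margin of max(r) + 2·probe + 3·spacing around the atoms
  so the exterior is always connected for the flood fill; R, S and R ∪ S
  are evaluated on one common grid so their volumes are consistent.
* Monte-Carlo sampling is deterministic for a fixed seed (default 1337);
  the ensemble and acceptance runs derive all seeds from one input seed.
* Altloc duplicates keep the highest-occupancy conformer, ties broken by
  altloc letter order. Multi-model entries keep model 1 only. Waters,
  ligands and nucleic acids are excluded; modified residues with standard
  backbones (MSE and similar) are kept under their parent one-letter code.
  Hetero groups are never included in interface or volume computations.
* Enumeration treats every chain instance separately (one entry may contain
  several copies of the same protein) and deduplicates pairs under swapping
  the two interactions. The two P instances must be different chain
  instances; R and S must map to different accessions (P itself may recur
  as a partner, as in homo-oligomer cases).
* The cascade short-circuits after a failed gate for speed; a
  `short_circuit=False` mode evaluates every computable gate and is tested
  to agree on the final classification.

## Problem sizes

The default study conditions evaluate 50 scenarios of ~2,100 atoms per
structure pair (voxel grids of ~10⁶ cells, 2×10⁶ Monte-Carlo samples per
overlap), chosen to exercise every gate with comfortable certified margins
while keeping a full run in a few minutes on one core.

## Known limitations

* The interface criterion is a fixed distance cutoff, not a
  buried-surface-area or predictor-based definition; the record type admits
  other definitions behind the same interface.
* The SES closing is voxel-based: its absolute volumes carry an
  O(spacing) surface bias and it does not reproduce an analytic
  reduced-surface computation exactly. Agreement with published
  per-example overlap volumes is therefore approximate by construction
  (the original tools' parameters are unpublished).
* Accession grouping trusts the supplied mapping table; the near-identity
  fallback (≥ 98% identity, ≤ 15 residue length difference) can over-merge
  close paralogs.
* No assembly expansion: only chains present in the deposited coordinates
  are screened. mmCIF input is not supported.
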