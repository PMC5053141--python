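# Methods

`lorefine` automates the decisions a crystallographer faces when
refining a macromolecular model against weak, low-resolution data:
which homologous structures to trust as a source of prior information,
which restraints to derive from them, which of several plausible
refinement recipes to run, and how to pick the winner afterwards.  The
package implements the bespoke computations of that workflow —
homologue assessment and ranking, external-restraint generation,
protocol enumeration and Q-score selection — around a pluggable
refinement backend, with a built-in toy restrained minimizer so the
whole pipeline runs on synthetic structures.

## Homologue assessment

For every candidate reference chain against every target chain:

* **Sequence alignment.** Global alignment with BLOSUM62 and affine
  gaps (open 10, extend 0.5).  Identity is the percentage of aligned
  positions with identical residues; coverage the percentage of target
  residues aligned.  Nonstandard residues read from PDB files map to
  `X`, which keeps identity estimates conservative.  A full local
  *structural* alignment would be an alternative; sequence alignment
  plus atom-name matching is sufficient here because every accepted
  homologue shares at least 75 % identity, a regime where sequence
  alignment is reliable.
* **Global r.m.s.d.** Least-squares rigid superposition (Kabsch, via
  SVD with a proper-rotation correction) of matched CA atoms.  CA-only
  makes the measure a chain-level conformational distance insensitive
  to side-chain differences.
* **Flexible (local) score.** Mean backbone (N, CA, C, O) r.m.s.d.
  over sliding nine-residue windows of contiguously aligned residues,
  stride 1, each window superposed independently.  Because each window
  is fitted on its own, rigid domain motion about a hinge barely moves
  this score while it dominates the global r.m.s.d. — the pair of
  numbers therefore distinguishes "globally different but locally
  identical" homologues (excellent restraint sources) from locally
  divergent ones.  Alignments shorter than nine residues fall back to
  a single fragment when at least five residues align; below that the
  score is undefined and the homologue cannot be assessed.

Homologues with identity below 75 % or coverage below 75 % are
rejected (boundary values retained).  Survivors are ranked by
`global_rmsd + flexible_score`, ascending; ties break toward higher
identity, then input order.  The reverse ordering by global r.m.s.d.
("most different first") feeds the distant-homologue protocols.

## Restraint generation

Three restraint flavours, all serialized as REFMAC-style
`exte dist ... value ... sigma ... type 0` keyword lines (a trailing
`#` comment carries provenance and the alternative-group id; keyword
parsers ignore comments, and the package's reader uses them to make
the round trip lossless):

* **Homologue restraints.** For every pair of matched atoms whose
  distance *in the reference* is within 4.2 Å and whose covalent bond
  path in the target is at least 4 bonds, the reference distance
  becomes the restraint objective (sigma 0.1 Å).  1-2, 1-3 and 1-4
  relations are excluded because standard geometry restraints already
  govern them.  Covalent connectivity is inferred from intra-residue
  interatomic distances (1.85 Å heavy-atom cutoff, 2.1 Å involving
  sulfur) plus inter-residue peptide C–N links.  With several
  references, restraints for the same atom pair share a group id; the
  minimizer treats group members as alternatives.
* **Hydrogen-bond restraints.** Backbone N···O pairs detected in the
  target itself, each restrained to the standard 2.8 Å bond length
  (sigma 0.1 Å).  Detection criteria: N···O ≤ 3.5 Å, sequence
  separation ≥ 2 within a chain, C=O···N angle ≥ 90°, N–H···O angle
  ≥ 120° with the amide hydrogen inferred from the backbone (bisector
  construction; skipped for chain-initial nitrogens, whose hydrogens
  are rotatable), and at most one bond per donor (a single amide
  hydrogen), keeping the closest qualifying acceptor.  The
  distance/angle-only criteria admit the spurious i→i+3 contact of an
  ideal α-helix; the two hydrogen-position criteria are what reduce
  the pattern to the canonical i→i+4 ladder.
* **Jelly-body-style self-restraints.** Every non-bonded pair within
  4.2 Å restrained to its *current* distance with a tight sigma
  (0.02 Å).  The residual is zero at the starting conformation, so
  these act as a stiff regularizer rather than a bias toward any new
  conformation.

Sigmas are package choices (the workflow's upstream tools keep theirs
internal): self-restraints must be an order of magnitude tighter than
informative external restraints to act as regularizers.  Hydrogen
atoms are never restrained.

## Protocol grid and execution

With ranked homologues available, the grid comprises external
restraints from the top 1, 2, 3 homologues, from the 1, 2, 3 most
different homologues, from all homologues, plus the two homologue-free
protocols: hydrogen-bond restraints (ERB) and jelly-body restraints
(JELLY).  Protocols whose unordered homologue-id sets coincide are
deduplicated, so the count is 2/3/5/7/9 for 0/1/2/3/≥4 homologues —
with exactly three homologues the top-3, most-different-3 and
all-homologue subsets are one and the same protocol.  Users may raise
or lower the homologue count K.  Target chains for which no homologue
survives filtering receive hydrogen-bond restraints inside every
external-restraint protocol.

Every ERH/ERB protocol runs two backend rounds: refinement under the
external restraints, then a second round under freshly generated
jelly-body restraints that lets the structure relax in its new
conformation.  The JELLY protocol is a single round.  In
molecular-replacement mode an extended jelly relaxation is prepended:
100 cycles, or 200 when the starting R statistic exceeds 40 % — the
threshold is a package choice within the workflow's stated 100–200
band.  Twin and scaling options are pass-through fields on the backend
request; the toy backend ignores them.  Protocols execute as isolated
work units (optionally in parallel); aggregation is deterministic by
protocol id, and a failing protocol is recorded and skipped rather
than aborting the run.  The winning recipe is saved as a YAML protocol
file which, supplied to a later run, restricts execution to exactly
that protocol.

## Q-score selection

Each protocol yields R_free (percent, lower better) and, when
available, a MolProbity-style geometry percentile MP (higher better).
The combined score is

    q_i = R_free,i + c · (MP_max − MP_i),
    c   = (R_free,max − R_free,min) / (MP_max − MP_min),

so the best-geometry protocol keeps q = R_free and every other
protocol's R_free is inflated in proportion to its geometry deficit,
scaled so the two ranges are commensurate.  When all MP values
coincide (including the single-protocol case) c = 0 and q degenerates
to R_free; when MP is unavailable selection falls back to argmin
R_free outright.  The published workflow states these properties and
the weight definition verbatim but prints the scoring equation only as
an image; the form above is a reconstruction satisfying every stated
property (best-geometry protocol uninflated, inflation proportional to
the geometry gap, range-ratio weight), and exact numerical parity with
the original program is not claimed.  Useful consequences, asserted as
tests: adding a constant to every R_free shifts every q by that
constant, and any affine rescaling of the MP values leaves q
unchanged.  Ties break toward lower R_free, then better geometry, then
protocol order.

## Toy refinement backend

Real maximum-likelihood refinement is outside this package; the
backend contract (model + restraints + options in, refined model +
statistics out) lets an external program be plugged in via a shell
template.  The built-in toy backend makes everything exercisable:

* **Minimizer.** Gradient descent with a backtracking line search on
  `E = Σ_groups min_alternatives ((d − d_target)/σ)²`; within each
  group the alternative closest to the current interatomic distance is
  active each cycle, mirroring how multi-homologue alternative
  restraints are consumed downstream.  Energy is non-increasing across
  cycles; the default is 20 cycles per stage, enough for the small
  synthetic structures the package targets.
* **Statistics.** The minimizer's own report is a bounded monotone
  transform of its residual, `100·s/(1+s)` with `s = √(E/N_groups)`.
  This is *not* a crystallographic R factor, and by itself it cannot
  rank protocols — a jelly-body run starts and ends at E ≈ 0.  The
  backend therefore accepts a pseudo-observation structure standing in
  for the diffraction experiment (for synthetic benchmarks, the ground
  truth): its non-bonded interatomic distances within 5 Å (sigma
  0.5 Å) become observations, split deterministically 90/10 into work
  and cross-validation sets, and r_work/r_free are the same transform
  evaluated against them.  Refinement itself never sees the
  observations — it remains restraint-only — so r_free is a genuine
  out-of-objective measure of how close a protocol brought the model
  to the reference.  A geometry proxy (backbone-regularity percentile,
  `100·exp(−5·rms deviation)` of consecutive CA–CA distances from
  3.80 Å and peptide C–N from 1.33 Å) stands in for the MolProbity
  percentile so Q-score ranking is exercised end to end.

## Synthetic structures

Generators build poly-Ala backbones from ideal internal coordinates
(NeRF chain extension; φ/ψ = −57.8°/−47.0° for helices,
−139°/135° for strands; side chains stop at CB since no computation
here looks past it):

* **Homologue generator** — mutates `⌈(1 − identity/100)·n⌉` residue
  names (never to glycine, keeping the atom set fixed; names only,
  coordinates untouched, so identity and conformation vary
  independently) and adds i.i.d. Gaussian coordinate noise.
* **Hinge-bent conformers** — the C-terminal half is rotated rigidly
  about an axis through the hinge CA, perpendicular to the principal
  direction of the *stationary* half (so successive bends at one hinge
  share the axis and compose exactly).
* **Benchmark case** — a 30-residue ground-truth helix; the target is
  a σ = 0.5 Å-perturbed copy (standing in for a poorly refined
  low-resolution model); five homologues at identities
  95/90/85/78/70 % with conformational noise 0.05/0.15/0.30/0.50/
  0.80 Å, so identity rank and conformational rank agree and the 70 %
  decoy falls below the filtering threshold.  Identity/noise grids are
  package choices spanning the workflow's relevant regime (above,
  around and below the 75 % cutoff).

All generators are deterministic under a fixed seed.  What the
generators do **not** emulate: real side chains, ligands, solvent,
crystal packing, diffraction data, and genuinely divergent homologue
folds.  Passing tests therefore demonstrate the correctness of the
bookkeeping, geometry and selection logic — not that any particular
crystallographic case will improve.

## Numerical choices and degenerate inputs

* Superposition requires ≥ 3 non-collinear points; reflections are
  excluded by the determinant correction.  Agreement with a
  rotation-grid-search oracle is held to 1e-3 Å on small point sets.
* Altloc handling keeps the highest occupancy, ties toward altloc `A`.
  Residue numbers outside the fixed-width PDB range are rejected on
  write; coordinates round-trip at the format's 3-decimal precision.
* Line-search tolerance 1e-12 on energy decrease; minimization stops
  when no step of the backtracking schedule improves the energy.
* Empty restraint sets refine to the identity; an all-protocols-failed
  run raises with per-protocol diagnostics.

## Known limitations

* The toy backend's statistics rank protocols only as well as the
  pseudo-observation distances represent the experiment; there is no
  likelihood, no bulk solvent, no twinning — the twin/scaling flags
  are plumbing for real backends.
* ERF (fragment-library) protocol kinds are identifiers only;
  generating their restraints is out of scope, as is computing real
  MolProbity statistics and running BLAST searches (homologues are
  supplied locally; the remote-search hook is a disabled stub).
* Gradient descent on distance restraints has mirror-image local
  minima; on heavily perturbed inputs individual seeds can stall a
  little above the typical recovery error, which is why recovery is
  stated as a median.
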