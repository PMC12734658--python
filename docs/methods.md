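# Methods

This note documents the models, conventions and design choices behind
`heterofrag`, in the spirit of a package manual: what is computed, under
which assumptions, and what the bundled tests do and do not demonstrate.

## Molecular representation

Structures are RDKit mols with canonical isomeric SMILES as their identity.
Canonical strings are dialect-dependent, so run logs and `RunConfig` record
the RDKit version.  Salt stripping keeps the largest covalently connected
organic component (heavy-atom count, ties broken by molecular weight;
carbon-free components never win): fragment products are typically
registered as HCl/HI salts but all property and similarity work is defined
on the neutral parent.

## Stereochemistry model

A "defined stereocenter" is a tetrahedral atom carrying an explicit
descriptor.  `invert_stereocenters` flips every defined descriptor — for a
molecule with two defined centers this is exactly the enantiomer; for one or
three centers the operation still inverts all of them and the caller can
read the counts from `StereoSummary` (the behaviour is deliberate: the
toolkit never guesses which subset of centers a user meant).  Undefined
centers stay undefined and double-bond geometry is untouched.  Stereo
perception is refreshed after inversion so chirality-aware consumers see
consistent descriptors.

**Racemate key.**  Racemic libraries need an identity shared by both
enantiomers: the lexicographically smaller of the canonical SMILES of the
molecule and of its inverted copy.  Enantiomers collide by construction;
diastereomers differ because they differ as graphs-with-parity.  The
enumerator materializes the key-minimal enantiomer of each racemate.

**cis/trans classification.**  For two defined stereocenters on adjacent
atoms of one saturated ring, each bearing exactly one exocyclic heavy
substituent, the classifier re-expresses each chiral tag relative to the
neighbor frame (other stereocenter, other ring neighbor, substituent, H) by
permutation parity.  In that frame, opposite effective tags mean the two
substituents lie on the same ring face (cis), equal tags mean opposite faces
(trans).  The convention follows from the ring geometry (derived by placing
the shared ring bond on an axis and reading the two viewing orientations)
and is validated in the test suite against an independent 3D oracle: embed a
conformer (ETKDG, fixed seed), fit the ring plane by SVD, and compare the
signs of the two substituent displacements off the plane.  The two routes
agree on all 8 stereoisomers of the two test patterns (2 patterns ×
cis/trans × enantiomer).  Inputs outside the precondition (wrong center
count, non-adjacent centers, aromatic ring, extra substituents) return
`not_applicable` with the center counts, never a guess.

## The design matrix

The packaged configuration (`data/design_matrix.yaml`) declares seven
series: 2,3- and 3,4-pyrrolidine, 2,3-, 3,4- and 4,3-piperidine, and the
4,3-substituted cyclic sulfone and gem-difluorocyclohexane.  Positions count
from the anchor atom (ring N, sulfonyl S, or CF2 carbon) as position 1, and
the aryl group always sits vicinal to the polar head (|Δposition| = 1), the
arrangement produced by arylation directed to the position beta to the
head-group attachment point.  Fragment numbering is editorial data carried
in the config, not derived; blocks expand stereo-major/aryl-minor and the
enumerator validates the declared id count against the expansion, the
uniqueness of ids, and the pairwise distinctness of racemate keys.  Status
annotations (synthesized / commercial / not_prepared, with reasons) ride on
the config; the five not-prepared designs reflect chemistry constraints
(oxidative deprotections that spirocyclize in the presence of the
4-methoxyphenyl group; cis-fluoroarene intermediates epimerized to trans
rather than separated) and two designs are commercial paroxetine
substructures.  The nitrile pair in the 4,3-piperidine series is recorded as
cis; the source material does not state its relative configuration and the
choice affects only those two SMILES, not any tally.

Structures are assembled from ring templates written so the two substitution
sites close the ring bond (guaranteeing adjacency); of the two parity
combinations the one whose classification matches the declared relative
configuration is kept, and the classification is re-asserted on the final
molecule.  N-heterocycles carry a free ring N–H: protecting groups belong to
the synthesis, not to the fragment products.

## Descriptors and Rule-of-3 profiling

The six descriptors: molecular weight (standard atomic weights), Crippen
atom-contribution cLogP, Lipinski H-bond donors and acceptors (the standard
SMARTS-based `NumHDonors` / `NumHAcceptors` counts of common fragment
tooling — an acceptor here is an N/O outside acid-type O–H and similar
environments, which is what keeps a carboxylic-acid fragment at a sensible
count), Ertl topological polar surface area (N/O contributions), and the
strict rotatable-bond count (non-ring single bonds between heavy atoms,
amide C–N and terminal bonds excluded).  All six are constitutional, so
enantiomers have identical vectors; `racemate_properties` nevertheless
computes both enantiomers and asserts the equality at run time, making the
racemate-representativeness of the numbers a checked fact rather than an
assumption.

Library statistics use the sample (n−1) standard deviation; a single-member
library reports SD 0 with an explicit flag.  Ro3 normalization divides each
library mean by its limit — MW 300 g/mol, logP 3, HBD 3, HBA 3, plus the
extended-convention TPSA 60 Å² and 3 rotatable bonds so that all six radar
axes have a target.  Compliance uses strict `<` as the rule is printed; a
value exactly at a limit is reported non-compliant (visible in the rotatable
bond axis, where fragments with exactly 3 rotatable bonds count against the
per-molecule compliance fraction while the library mean stays inside the
boundary).  The radar renderer always writes a companion CSV with the
plotted numbers.

## Novelty analysis

Comparator extraction matches four SMARTS motifs (aliphatic-ring
pyrrolidine and piperidine with an unoxidized ring nitrogen, the
1,1-dioxothiane ring, and the gem-difluorinated cyclohexane).  Each pattern
is validated at load time against the four parent scaffolds (diagonal match
matrix), so a malformed pattern fails configuration, not per molecule.

Fingerprints are folded Morgan environments, radius 2 (ECFP4-like) and 2048
bits by default — the radius is a community default, configurable.
Chirality is excluded by default so the two enantiomers of a racemate hash
identically; a flag turns it on.  Tanimoto similarity is |A∩B|/|A∪B| with
the empty–empty pair defined as 1.0 (documented convention).
Nearest-neighbor search is exact (dense integer matrix product): comparator
sets in the tens of thousands need no approximate index, and exactness keeps
the reports testable.  Novelty is `1 − max Tanimoto`.

Embeddings: UMAP on the raw bit vectors with the Jaccard metric
(n_neighbors 15, min_dist 0.1, fixed random state 42 by default, all
recorded in the `Embedding2D` metadata) reproduces bit-identically for a
fixed seed within one library version, with rotation/reflection freedom
across versions — the test suite asserts reproducibility after Procrustes
alignment at 1e-6.  PCA on the centered bit matrix (full SVD) is the
deterministic fallback and the default in fast tests.  Separation between
labeled groups is the mean silhouette coefficient on the 2D coordinates;
a random-permutation baseline centers on 0, and coincident groups score ≤ 0.

Because the original commercial-catalogue extractions cannot be bundled, the
benchmark comparator is generated: the decoy generator grafts 1–3 common
substituents (halogen, methyl, methoxy, hydroxyl, amide, nitrile, phenyl)
onto ring scaffolds drawn categorically — 40% piperidine, 30% pyrrolidine,
5% cyclic sulfone, 5% gem-difluorocyclohexane in the packaged benchmark,
remainder on motif-free filler rings (benzene, pyridine, cyclohexane,
cyclopentane, tetrahydropyran, tetrahydrofuran, morpholine, naphthalene).
Template grafting onto distinct pristine-scaffold sites guarantees valence
validity without a rejection loop and keeps fillers from accidentally
acquiring a motif (e.g. gem-difluorination).  Generation is deterministic
under its seed; the packaged benchmark uses 1000 decoys, seed 1.

**What the decoys do and do not emulate.**  They reproduce the *structural
logic* of a commercial fragment catalogue — small decorated ring systems
with a known fraction containing the four central motifs — which is what the
motif filter, the novelty report and the separation score exercise.  They do
not reproduce a real catalogue's property distributions, synthetic-route
biases, or diversity profile; a positive separation score on the benchmark
demonstrates that the pipeline detects planted structure at realistic sizes,
not that any particular commercial library is distant from the collection.
For real comparisons, feed actual catalogue SMILES through the same
`novelty` / `embed` entry points.

## Problem sizes and numerical choices

The bundled tests and benchmark run at 44 query molecules against a
1000-decoy comparator (~790 motif-matched), a scale at which exact
similarity search and full-SVD PCA are instantaneous and one UMAP fit takes
seconds; the same code paths handle comparator sets of tens of thousands.
Stochastic steps (decoy generation, stereo assignment of the test pool,
embeddings, permutation baselines) all take explicit seeds.  Degenerate
inputs fail loudly: empty SMILES tables, empty reference sets, non-positive
limits, infeasible motif fractions and degenerate labelings raise typed
errors naming the constraint.

## Known limitations

- No CIP R/S assignment, tautomer canonicalization, charge-state
  enumeration or 3D descriptors; profiling assumes a sensible neutral
  parent.
- cis/trans classification is defined only for the vicinal two-center,
  one-substituent-each pattern of this library; bridged or fused systems
  return `not_applicable`.
- The Ro3 TPSA and rotatable-bond limits are the common extended
  convention, not part of the original three-parameter rule; both are
  plain fields on `Ro3Limits` for users who prefer other targets.
- UMAP geometry is not comparable across umap-learn versions; only the
  seeded-run reproducibility and the separation statistics are contractual.
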