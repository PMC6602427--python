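# Methods

## Problem and conventions

`ppiddg` predicts the change in protein–protein binding free energy
caused by a single missense mutation, from the three-dimensional
structure of the wild-type complex. Binding free energies derive from
dissociation constants via ΔG = R T ln K_D with
R = 1.985×10⁻³ kcal K⁻¹ mol⁻¹ and K_D in molar; the prediction target
is ΔΔG_wt−mt = ΔG_wild-type − ΔG_mutant in kcal/mol. Under this
convention a destabilising mutation is **negative**. Because ΔG is a
state function, the reverse mutation (mutant → wild type) must carry
exactly −ΔΔG; the dataset builder exploits this identity for
augmentation and the test suite asserts it exactly.

All distance cutoffs in the package are inclusive (≤). Residues are
addressed by author numbering with optional insertion codes. Waters and
hetero compounds are dropped on reading; one altloc conformer is kept
per atom (highest occupancy, ties toward altloc 'A'). Cleaning beyond
this (NMR model selection, missing-atom repair) is intentionally out of
scope: inputs are assumed to be reasonably complete crystal structures.

## Structural features

**Graph-based signatures.** Heavy atoms within a sphere (default
radius 10 Å) of the mutated residue's geometric centre are labelled
with one or more of eight pharmacophore classes (hydrophobic, aromatic,
donor, acceptor, positive, negative, sulfur, neutral) from a shipped
per-residue atom table. For every unordered atom pair and every
unordered label pair it realises, one count is added at the smallest
rung of an ascending distance ladder (default 1.0–10.0 Å in 0.5 Å
steps) that is ≥ the pair distance; counts are then cumulated along the
ladder, giving a cumulative distribution of typed distance patterns.
The radius and ladder are configuration knobs; the defaults follow the
cutoff-scanning family of descriptors this design descends from.
Pairs within the mutated residue itself are included — the residue is
part of its own environment. Signatures are computed on the wild-type
structure only. The implementation is verified exactly (integer
equality) against an independent all-pairs brute-force oracle.

**Residue environment.** Relative solvent accessibility is
Shrake–Rupley SASA of the residue in the full complex divided by the
Tien et al. (2013) theoretical maximum ASA of its amino acid. The SASA
implementation is in-house (960 golden-spiral points, 1.4 Å probe,
Bondi radii, heavy atoms only) and is cross-checked in the tests
against Biopython's independent Shrake–Rupley; an isolated residue can
exceed RSA 1 because the normalising table assumes a tripeptide
context. The backbone phi torsion is reported in degrees with NaN as
the undefined-sentinel at chain starts (encoded in the feature vector
as phi = 0 plus a phi_defined flag, never a silent zero). Residue depth
avoids an external surface binary: the surface is defined as all atoms
with nonzero SASA and depth is the mean distance from the residue's
heavy atoms to the nearest surface-atom centre. This correlates with
the classical solvent-surface definition while staying dependency-free
and exactly reproducible. Chain amino-acid composition is a plain
20-vector of frequencies (alphabetical order, 'X' excluded from the
denominator).

Note on invariances: torsions, signatures and contact counts are
exactly invariant under rigid-body motions; point-sampled SASA (and
hence RSA, and depth through its surface set) is invariant only to
within sampling noise, so the tests bound those at 0.01–0.05 rather
than 1e-6.

**Contacts and networks.** Atom pairs are classified with explicit
distance rules over shipped radii and donor/acceptor tables: covalent
if d ≤ r_cov(a)+r_cov(b)+0.4 Å; hydrogen bond if a donor-capable and an
acceptor-capable heavy atom are within 3.9 Å (no angle term, so the
rule works on hydrogen-free crystal structures); aromatic between atoms
of two rings whose centroids are within 5.0 Å; van der Waals if
d ≤ r_vdw(a)+r_vdw(b)+0.5 Å and not covalent. This is a deliberate
reduction of full interatomic-contact typing to the four classes the
predictor consumes; all thresholds sit in one table
(`interactions.CONTACT_RULES`). A residue is interfacial when any heavy
atom is within 5 Å of another chain (inclusive — verified at the exact
boundary). The contact network of the interface closest to the mutated
residue (closest by centre-to-midpoint distance; ties resolve
lexicographically) is summarised on its largest connected component by
mean normalised closeness, Freeman central-point dominance from
normalised betweenness, and graph-centre size; "central points" is
ambiguous in the field, so both dominance and centre size are emitted
and feature selection may drop either.

**Mutant models and contact deltas.** How mutant side chains are built
is genuinely open; the package grafts an idealised side-chain template
(ideal bond lengths/angles, most common rotamer, NeRF construction on
the N–CA–CB frame, crystallographic CB orientation preserved when
present, CB reconstructed from the backbone when mutating away from
glycine). The graft is deterministic, leaves the backbone untouched,
and can be bypassed by supplying an externally modelled mutant
structure. The contact-delta block is wild-type minus mutant per-kind
counts at the mutated residue; covalent counts include the residue's
own bonds (reflecting side-chain size) while the non-covalent kinds
count only contacts to other residues.

**Evolutionary scores.** PSI-BLAST ASCII PSSMs are consumed as files
(running the search is out of scope); the feature block is (wild-type
score, mutant score, difference) at the mutation position, and the
reader fails loudly if the PSSM query letter disagrees with the stated
wild type. **Contact potentials** are symmetric 20×20 lookups in
AAindex matrix format; which three published tables to use is not
determined by the method itself, so the package ships three clearly
labelled synthetic stand-ins (hydrophobic pairing, charge pairing,
volume mismatch) and takes real AAindex entries via configuration.
**Energy terms** (chain–chain interaction energy, predicted folding
ΔΔG) come from an adapter reading FoldX-style tables, or an explicit
null adapter; the block is then absent from the vector, never
zero-filled, and training works without it.

**Elastic network fluctuations.** The mutated monomer's CA atoms form
an elastic network under two force fields: "calpha" with Hinsen
distance-dependent spring constants (piecewise at 4 Å, 15 Å pair
cutoff) and "pfanm" with parameter-free 1/d² springs over all pairs.
Per-residue mean-square fluctuations are the residue-wise trace of the
Hessian pseudo-inverse, computed by eigendecomposition with exactly six
rigid-body modes discarded (tolerance 1e-8 × largest eigenvalue; more
than six near-zero modes raises as degenerate geometry). The feature
block carries the mutated residue's value and the monomer mean for each
force field (4 slots) — the minimal faithful summary of a per-residue
profile. Agreement with direct pseudo-inversion is asserted to 1e-8.

## Dataset construction and splits

SKEMPI-2.0-dialect tables (semicolon-separated, parsed affinities in
molar, per-row temperature with 298.15 K fallback) are curated to
single-point mutations; replicate ΔΔG values of the same variant are
averaged when max − min < 2.0 kcal/mol (strict) and the variant is
discarded otherwise. ΔΔG = 0 counts as "increased affinity" in
stratification. Reverse augmentation doubles the set with exact
negation and is guarded against double application.

Split generators: (i) repeated stratified k-fold over forward records
(stratified on the sign of the forward ΔΔG — the imbalance that
motivates augmentation), with each reverse twin inheriting its forward
record's fold so twins never straddle a train/test boundary;
(ii) leave-one-complex-out on `complex_id`; (iii)
leave-one-binding-site-out on `binding_site_id`, which falls back to
pdb + chain + position when a curated site annotation is unavailable.
All schemes are exact partitions; hygiene is tested exhaustively.

## Learner

An extremely-randomised-trees regressor (500 trees by default, full
feature sampling, fixed seed; all hyperparameters exposed) maps the
named feature vector to ΔΔG. Predictions refuse inputs whose slot
schema differs from the training schema, naming the first offending
slot. Models persist via joblib with an embedded schema and version;
a round trip reproduces predictions bit-exactly. Scanning modes
enumerate interface residues and predict alanine substitutions
(non-alanine positions only) or all 19 substitutions per position with
per-position means for heat-map summaries; wild-type-only feature
blocks are cached per site, which is bit-transparent because they do
not depend on the substituted amino acid.

## Evaluation statistics

Pearson's r, Kendall's tau-b (tie-corrected — experimental tables
contain ties) and RMSE; zero-variance inputs yield NaN correlations
with RMSE still reported. Correlations from independent samples are
compared two-tailed via Fisher's r-to-z,
z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)); Kendall scores enter
through Greiner's relation r = sin(π τ/2). Hotspot classification
binarises predicted and observed ΔΔG at a destabilisation threshold
(default 2.0 kcal/mol, configurable) in a configurable sign convention
and reports per-class precision and recall with NaN for classes absent
from the observations.

## Synthetic data: what it emulates and what it does not

Two generators make all tests self-contained. `make_toy_complex` builds
deterministic two-chain extended-backbone peptides (ideal geometry,
0.02 Å coordinate jitter, optional per-residue substitutions) whose
minimal inter-chain heavy-atom distance is calibrated to a requested
gap, with the closest pair snapped analytically onto the gap; it
emulates a small, clean protein–protein interface with controllable
separation. `make_synthetic_features` draws standard-normal feature
tables with a planted linear target on five slots (coefficients
2, −1.5, 1, 0.5, −1; noise sd 0.1 at n = 500 for recovery checks).
Neither generator reproduces real structural statistics — packing
density, rotamer diversity, crystallographic noise, conservation
signal, or the true ΔΔG distribution — so passing tests demonstrate
algorithmic correctness (exact oracles, invariances, split hygiene,
signal recovery), not benchmark accuracy on experimental mutation
panels, which requires external SKEMPI and PDB downloads outside the
tested core.

Problem sizes used throughout (toy complexes of 5–6 residues per
chain, 10–20-residue elastic-network fixtures, n = 500 synthetic
training sets, 50 random environments of up to 200 atoms) were chosen
as the smallest scales at which each property is non-trivially
exercised.

## Numerical choices and known limitations

- Ties in the closest-interface search and altloc selection resolve
  lexicographically; the signature ladder must be strictly ascending.
- The zero-mode tolerance (1e-8 relative) and the pseudo-inverse rcond
  are matched so the eigendecomposition path equals direct
  pseudo-inversion.
- Hydrogen-bond detection has no angular term and will over-count in
  dense polar clusters; aromatic detection uses ring centroids only
  (no dihedral between ring planes).
- Idealised side-chain grafting ignores steric relaxation; clashes in
  the mutant model inflate van der Waals deltas for large
  substitutions.
- The SASA point sampling limits rotational invariance of RSA/depth to
  roughly two decimal places.
- PSSMs, AAindex tables and energy terms are consumed, not computed;
  predictions without them use a reduced (still valid) schema, and
  models are only applicable to vectors with the schema they were
  trained on.
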