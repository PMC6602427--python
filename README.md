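# ppiddg

Predicting how missense mutations change the binding affinity of
protein–protein complexes.

Mutations at protein–protein interfaces are enriched among disease
variants, yet measuring their effect on binding is slow and expensive.
`ppiddg` is a structure-based machine-learning predictor of the change
in binding free energy upon mutation,

```
ΔG        = R T ln K_D                 (R = 1.985×10⁻³ kcal K⁻¹ mol⁻¹)
ΔΔG_wt−mt = ΔG_wild-type − ΔG_mutant   (kcal/mol)
```

where K_D is the complex's dissociation constant in molar. Note the
**wt − mt sign convention**: destabilising mutations have negative
ΔΔG here; a CLI flag converts to the opposite (SKEMPI-style)
convention.

The predictor combines six feature families computed from the wild-type
complex structure:

- **graph-based structural signatures** — atoms around the mutated
  residue are typed with pharmacophore labels (donor, acceptor,
  aromatic, hydrophobic, charged, sulfur, neutral) and pairwise
  distances are accumulated into cumulative pair-class × distance-cutoff
  counts ("cutoff scanning");
- **residue environment** — relative solvent accessibility, backbone
  phi torsion, residue depth, and the amino-acid composition of the
  mutated chain;
- **non-covalent contact analysis** — wild-type → mutant differences in
  covalent, van der Waals, aromatic and hydrogen-bond contact counts
  (mutants built by deterministic idealised side-chain grafting), plus
  closeness/central-point-dominance/graph-center metrics of the contact
  network of the closest interface (a residue is interfacial when any
  heavy atom is within 5 Å of another chain);
- **evolutionary conservation** — PSI-BLAST PSSM scores of the
  wild-type and mutant residue (PSSMs consumed as files);
- **residue contact potentials** — symmetric AAindex-format pair-table
  lookups;
- **flexibility** — per-residue fluctuations of CA elastic network
  models of the mutated monomer (Hinsen distance-dependent springs and
  parameter-free 1/d² springs).

Training data are curated from SKEMPI-2.0-style tables (replicates
averaged when they agree within 2 kcal/mol, single-point mutations
only) and augmented with hypothetical reverse mutations carrying the
negated ΔΔG, which balances the dataset and pushes the learner toward
thermodynamic antisymmetry. An extremely-randomised-trees ensemble maps
the feature vector to ΔΔG. Validation utilities cover paired stratified
cross-validation (forward/reverse twins never straddle folds),
leave-one-complex-out, leave-one-binding-site-out, Fisher r-to-z and
tau-to-r correlation comparisons, and hotspot classification.

## Worked example

```python
import numpy as np
from ppiddg import structure_io as sio, model as mdl, dataset as ds
from ppiddg.pipeline import features_for_mutations

# two 6-residue chains, 4 A apart, mixed interface
complex_ = sio.make_toy_complex(6, 4.0, seed=42,
                                sequence_a="AFKDSA", sequence_b="AWENTA")

# curate the shipped affinity fixture and augment with reverse mutations
records = ds.parse_skempi("tests/data/skempi_fixture.csv")
augmented = ds.augment_reverse(records)
print(f"curated {len(records)} records from 12 rows; "
      f"{len(augmented)} after reverse augmentation")
print(f"dG(KD=1 nM, 298.15 K) = {ds.dg_from_kd(1e-9, 298.15):.2f} kcal/mol")

# train a demonstration model on toy-mutation features
muts = [(sio.ResidueRef("A", i), aa) for i in (2, 3, 4) for aa in "GWEL"]
X = features_for_mutations(complex_, muts)
y = np.random.default_rng(0).normal(scale=1.5, size=len(X))
model = mdl.train(X, y, config={"n_estimators": 50}, seed=1)

scan = mdl.alanine_scan(model, complex_)[0]
print(f"interface {scan.interface_id}: {len(scan.rows)} alanine predictions")
print(scan.rows.to_string(index=False))
```

prints

```
curated 8 records from 12 rows; 16 after reverse augmentation
dG(KD=1 nM, 298.15 K) = -12.26 kcal/mol
interface ('A', 'B'): 6 alanine predictions
chain  res_number icode wt_aa mut_aa  ddg_pred
    A           2           F      A  0.242383
    A           3           K      A  0.794767
    A           4           D      A -0.452731
    A           5           S      A -0.736748
    B           4           N      A  0.700775
    B           5           T      A -0.753196
```

The 12-row affinity table curates to 8 usable single-point mutations
(one multi-point row dropped, one over-dispersed replicate pair
discarded, replicate measurements averaged); a 1 nM binder corresponds
to −12.26 kcal/mol of binding free energy; the alanine scan predicts
one ΔΔG per non-alanine interface residue (here the model was fitted to
random targets, so the values only demonstrate the mechanics).

The same modes are available from the shell:

```bash
ppiddg predict --pdb complex.pdb --chain A --mutation F2A --model model.joblib
ppiddg scan --pdb complex.pdb --mode saturation --model model.joblib --out scan/
ppiddg build-dataset --skempi skempi.csv --out curated.csv
ppiddg train --features features.csv --out model.joblib
ppiddg evaluate --features features.csv --scheme loco --out eval.json
```

## Layout

- `src/ppiddg/structure_io.py` — PDB/mmCIF model, SASA/RSA, phi, depth,
  toy-complex generator
- `src/ppiddg/signatures.py` — pharmacophore typing and cutoff-scanning
  signatures
- `src/ppiddg/interactions.py` — contact typing, interfaces, network
  metrics, side-chain grafting, contact deltas
- `src/ppiddg/features.py` — PSSM/AAindex/energy-term readers, elastic
  network fluctuations, feature assembly
- `src/ppiddg/dataset.py` — thermodynamics, SKEMPI curation, reverse
  augmentation, split generators
- `src/ppiddg/model.py` — training, prediction, persistence, scanning
- `src/ppiddg/evaluate.py` — metrics, Fisher r-to-z, tau-to-r, hotspots
- `src/ppiddg/cli.py` — `ppiddg` command

See `docs/methods.md` for the modelling choices and their rationale.
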