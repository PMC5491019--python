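# mddpalm

Prediction of S-palmitoylation sites (cysteine-centered PTM sites) from
protein sequence, built around three ideas:

1. **Window fragments** — every candidate cysteine is represented by a
   (2n+1)-mer peptide window (default n=10), 'X'-padded at protein termini,
   with six numeric encodings (one-hot binary, amino-acid composition,
   adjacent-pair composition, BLOSUM62 rows, position-weight-matrix lookup,
   and a residue-aggregated, logistic-squashed PSSM transform, plus an
   optional accessible-surface-area track).
2. **Motif decomposition** — positive fragments are recursively partitioned
   into substrate-motif subgroups by maximal dependence decomposition: a
   chi-square test over 5×5 contingency tables of amino-acid property
   groups (polar / acidic / basic / hydrophobic / aromatic) finds the
   window position pair with the strongest dependence, and the set is split
   on the dominant property group at that position until subgroups fall
   below a maximum cluster size.
3. **Two-layered SVM** — each motif subgroup trains its own RBF-kernel SVM
   (positives = subgroup members, negatives sampled at 1:8) with
   probability outputs; the vector of subgroup probabilities feeds a
   second-layer SVM whose probability is the final score.  Second-layer
   training features are produced by k-fold cross-fitting of the first
   layer so no fragment is scored by a model that saw it.

Evaluation utilities cover confusion-matrix metrics (Sn/Sp/Acc/MCC),
ROC/AUC, and stratified k-fold cross-validation that re-learns the whole
pipeline inside each fold.  A seeded synthetic generator plants
property-group motifs in cysteine-centered fragments so the entire pipeline
is testable offline.

## CLI

```bash
# train a model from FASTA + site annotations (TSV: id <TAB> 1-based position)
mddpalm train --fasta proteins.fasta --sites sites.tsv --out model/ --seed 1

# score every cysteine of query proteins
mddpalm predict --fasta query.fasta --model model/ --out predictions.tsv

# motif decomposition only (tree JSON + per-subgroup frequency matrices)
mddpalm cluster --fragments fragments.tsv --out clusters/

# metrics from a (label, score) TSV
mddpalm evaluate --scores scores.tsv --out metrics.json

# generate a synthetic motif dataset
mddpalm simulate --out fragments.tsv --seed 1
```

Every subcommand writes a manifest (inputs, seed, config hash, version)
next to its outputs.  Exit codes: 0 success, 2 usage error, 3 data error.

## Library layout

| module                 | contents                                                            |
| ---------------------- | ------------------------------------------------------------------- |
| `mddpalm.sequence_io`  | FASTA/site I/O, fragment extraction, negative derivation, dedup     |
| `mddpalm.features`     | encoders, PWM/PSSM builders, [-1,+1] scaler, hybrid concatenation   |
| `mddpalm.mdd`          | property groups, chi-square dependence, decomposition tree, routing, composition enrichment |
| `mddpalm.model`        | subgroup SVMs, stacking, prediction, grid search, persistence       |
| `mddpalm.evaluate`     | confusion metrics, ROC/AUC, k-fold cross-validation                 |
| `mddpalm.synthetic`    | seeded motif-planting generator and default configurations          |
| `mddpalm.cli`          | `mddpalm` command group                                             |

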