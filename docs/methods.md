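# Methods

`xoscreen` implements a ligand-based consensus virtual-screening procedure for
finding xanthine oxidase (XO) inhibitor candidates among metabolites annotated
in plant extracts. This note records the models, conventions, numerical
choices and known limitations of the implementation.

## Pipeline overview

1. **Curation.** A labeled library (SMILES + active/inactive) is parsed with
   RDKit; records that cannot be parsed are removed and counted, and duplicate
   structures collapse on a canonical key — the canonical isomeric SMILES of
   the parsed graph. Two spellings of one structure are one compound;
   stereoisomers remain distinct (annotated natural products are frequently
   named at the stereoisomer level). Duplicates with conflicting labels abort
   curation rather than silently picking one.
2. **Diversity profiling.** Tanimoto similarity Tc = |A∩B| / |A∪B| over all
   n(n−1)/2 unordered distinct pairs of fingerprints; the profile reports the
   fraction of pairs below a threshold (0.4 by default) and a histogram on
   [0, 1]. Self-pairs are excluded so they cannot inflate the high-similarity
   mass. Tc of two all-zero vectors is defined as 1.0 (identical absence of
   features) with a warning; real libraries never meet this case.
3. **Split.** 70/15/15 train/validation/test. Both held-out partitions have
   exactly ceil(0.15·n) records — the convention that reproduces 337/73/73
   from 483 compounds — drawn in two stages (test first, then validation),
   each stratified by label using largest-remainder apportionment of the
   global class proportions. Every partition's class balance is therefore
   within one compound of the library's. A single integer seed drives both
   stages; identical (library, seed) gives a byte-identical assignment.
4. **Modelling.** One gradient-boosted tree classifier (XGBoost,
   `binary:logistic`) per fingerprint scheme. Five schemes exist: MACCS
   (167 fixed substructure keys) and extended-connectivity fingerprints of
   radius 2 or 3 (ECFP4/ECFP6) folded to 1024 or 2048 presence bits.
5. **Screening.** Applicability-domain (AD) filter, then a five-model
   majority vote, then decoy validation.
6. **Mass annotation.** Theoretical negative-mode adduct m/z and ppm errors
   for metabolite tables.

## Model selection under the stability constraint

The hyperparameter grid covers `n_estimators` 5–200 (discretized to
{5, 10, 25, 50, 100, 150, 200}), `max_depth` 2–10 (every integer),
`learning_rate` {0.001, 0.01, 0.1}, `colsample_bytree` {0.5, 0.7, 0.9},
`reg_lambda` {0, 0.001, 0.01, 0.1, 1}, `min_child_weight` {7, 9, 11, 13} —
11,340 points. Each point is fitted on the training partition; any point
whose train-vs-validation accuracy spread exceeds 5 % is discarded as
overfitting. Among survivors the highest validation accuracy wins, ties
broken by validation AUC, then fewer trees, then shallower depth. The test
partition is never consulted during selection — its spread is reported post
hoc — so model choice cannot leak test information. When no point survives
the constraint the fit fails loudly; this happens by design on label-noise
data, where any fit that memorizes the training set shows a large spread.

Classification metrics use the standard orientation: precision = TP/(TP+FP),
recall = TP/(TP+FN), F1 = 2TP/(2TP+FP+FN), accuracy = (TP+TN)/n. A
`printed_orientation` flag swaps the precision/recall denominators for
compatibility with reports that define them the other way around. AUC is the
rank statistic with mid-rank tie handling (equal to the pairwise concordance
probability). Cross-validation is stratified k-fold (k = 10 by default) with
seeded shuffling. No resampling or class weighting is applied to the mild
class imbalance (~45 % active); the metric battery is reported instead.

Tests and the bundled acceptance script run the constrained search on a
reduced 16-point grid (2 × 2 × 1 × 1 × 2 × 2, every axis exercised) and a
400-molecule synthetic library, which keeps a full five-scheme run under a
minute on one CPU while covering the selection logic; the full grid is the
default for real libraries.

## Applicability domain and consensus

A candidate is in-domain when (a) its average molecular weight is within
200–700 Da and (b) the mean Tc to its five most similar training compounds,
under ECFP4-1024, is at least 0.4. Both failure reasons are reported when
both apply, making the exclusion breakdown auditable. Molecular weight uses
standard atomic weights (the conventional reading of "molecular weight in
Da"); a flag switches to monoisotopic mass for sensitivity analysis. An
unparsable candidate is reported out-of-domain with reason
`encoding_failure` rather than aborting the screen. A candidate that also
occurs in the training set keeps its exact match in the neighbour list
(contributing Tc = 1.0).

With five voters, "majority" is ≥ 3 active votes. Verdicts carry the full
per-scheme vote map and the vote count, so sub-majority candidates remain
visible in reports. Decoy validation draws n compounds (seeded, reproducible)
from the ground-truth actives of the training set that at least one model
predicts active — a flag relaxes eligibility to label-only — spikes them into
the screen, and reports per-model recovery counts.

## Mass annotation conventions

Theoretical ion m/z uses hydrogen-atom arithmetic:
m/z = (k·M + Σ signed monoisotopic masses of adduct atoms)/|z|, with the
electron mass ignored. This convention reproduces published three-decimal
values for the built-in negative-mode adducts ([M−H]⁻, [M+Cl]⁻, [M+HCOO]⁻,
[2M+Na−2H]⁻); an `electron_corrected` flag adds the electron mass for
comparison (+0.00055 Da for a singly charged anion). Atomic constants
(monoisotopic mass of the most abundant isotope and IUPAC 2021 standard
atomic weights, conventional values for interval elements) are embedded so
results do not drift with toolkit versions. ppm error is
(measured − theoretical)/theoretical × 10⁶, displayed to two decimals;
|Δppm| < 0.005 displays as 0.00. Recomputing ppm errors from three-decimal
printed m/z values cannot reproduce errors that were derived from
full-precision measurements; the bundled extract tables note two rows whose
printed values are internally inconsistent (an adduct label contradicting its
m/z, and a display-rounding mismatch), and round-trip tests exclude them.

## Synthetic benchmark

The generator assembles structures from fixed fragment vocabularies: ten
scaffold templates with three substitution slots (benzene, phenol, catechol,
chromone, flavone, pyranose-like, naphthalene, cyclohexane, pyridine,
benzoate-ester cores) and fourteen small substituents, chosen so the library
resembles a polyphenol chemical space without any external data. A molecule
is active exactly when a slot carries the galloyl-ester pharmacophore;
assemblies that recreate that pattern by chance are rejected for inactives,
so the rule is exact before noise. Labels are then flipped independently with
probability `label_noise`. The active count is allocated deterministically
(round(active_fraction·n), default 0.45), structures are unique on the
canonical key, and one seed drives every draw, so identical configs give
identical libraries. Scaffold-vocabulary size controls diversity: more
scaffolds lower the median pairwise Tc monotonically.

The screening generator emits three candidate strata with planted AD
outcomes: in-vocabulary structures of in-window weight (must pass), sub-200
or super-700 Da structures (must fail on weight), and out-of-vocabulary
aliphatic/fluorinated structures of in-window weight (fail on similarity).

What the benchmark does *not* emulate: real structure–activity cliffs,
assay noise structure, scaffold-hopping actives, or the bit-density profile
of a literature-curated inhibitor set. Passing the recovery tests shows the
pipeline's machinery is correct (encoding, selection, constraint, voting,
domain logic), not that its accuracy numbers transfer to real XO data. Two
consequences worth noting: the implanted rule is nearly noiseless, so test
AUC on the noise-free benchmark saturates near 1.0, far above what a real
library yields; and on coin-flip labels (noise 0.5) the boosters make
near-constant predictions at the realized base rate, so the consensus
promotion rate of in-domain candidates flips with that base rate — chance-
level AUC is a theorem there, a low promotion rate is not.

## Numerical and degenerate-input choices

- Fingerprints are binary presence bits; ECFP folding is by modulo of the
  hashed feature identifier (RDKit's Morgan generator convention).
- The 483-molecule diversity profile (~116 k pairs) is computed by one
  integer matrix product; no pairwise loop, no full float matrix retained.
- Largest-remainder ties in the split are broken by class name for
  determinism.
- Empty evaluation sets, single-class sets (AUC reported absent), empty grid
  axes, fractions not summing to one, classes too small to stratify or fold,
  and decoy pools smaller than the request all raise informative errors.
- Model artifacts serialize as a UBJSON booster plus a JSON sidecar (scheme,
  hyperparameters, seed, full selection log); round-trip predictions are
  bit-identical.

## Known limitations

- The AD filter's reference scheme is fixed to ECFP4-1024 by default; the
  criteria object allows any scheme but the voting models always use all
  five.
- Decision threshold is fixed at 0.5 with no probability calibration.
- No scaffold-based splitting; random stratified splits overestimate
  prospective performance on congeneric libraries.
- The mass annotator handles the four negative-mode adducts of the bundled
  tables out of the box; positive mode is rejected (extensible via
  `AdductSpec`).
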