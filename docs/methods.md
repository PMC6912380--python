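# Methods

## Data model

A sample is a 41-nt DNA window over {A,C,G,T} with a cytosine at the centre
(1-based position 21) — the candidate 4mC site. Positions are reported
1-based to users and handled 0-based internally. Lowercase input is
uppercased silently; `U` and IUPAC ambiguity codes are rejected rather than
converted, and no reverse-complement canonicalisation is applied. Strict
FASTA reading aborts on any invalid record, naming the offenders; non-strict
reading skips and reports them.

## Encodings

All seven encoders are deterministic pure functions with fixed dimensions
(Kmer 1364, M6AMRFS 200 = DPE 160 + LPDF 40, RFHC 164, EIIP 64, BPF 164,
DPCP 240, TPCP 704), asserted on every call. Conventions that were genuinely
open and are fixed here:

- **Oligomer ordering** is lexicographic with A < C < G < T on every k-mer,
  dinucleotide and trinucleotide axis, so matrices are reproducible
  column-for-column.
- **Kmer normalisation** divides each k-mer count by the number of windows
  (41 − k + 1), so each per-k block sums to one; frequencies rather than raw
  counts keep blocks comparable across k.
- **DPE per-base code** A=(0,0), C=(1,0), G=(1,1), T=(0,1), concatenated per
  dinucleotide. This is the unique concatenative code consistent with the
  reference tuples AT=(0,0,0,1), AA=(0,0,0,0), GG=(1,1,1,1), AC=(0,0,1,0),
  and the test suite asserts those four tuples before any other DPE test.
- **LPDF** gives f_j = (count of the dinucleotide ending at j within the
  length-j prefix)/j for j = 2..41 — 40 values in (0, 1). **M6AMRFS** is DPE
  followed by LPDF (DPE first, matching the order the two parts are usually
  presented in).
- **RFHC** emits (a, b, c, d_j) per position: the purine / weak-H-bond /
  amino indicator bits (A=(1,1,1), T=(0,1,0), G=(1,0,0), C=(0,0,1)) and the
  cumulative density of the position's base within the prefix.
- **EIIP** weights trinucleotide frequencies (39 overlapping windows) by the
  sum of the per-base pseudopotentials A=0.1260, C=0.1340, G=0.0806,
  T=0.1335.
- **DPCP / TPCP** multiply each oligomer's overlapping-window frequency by
  each property value, oligomer-major. The shipped default tables are
  *documented substitutes*, not a reproduction of any specific published
  appendix: the 16×15 dinucleotide table combines unified nearest-neighbour
  thermodynamics (enthalpy, entropy, free energy and derived stability
  terms), crystallographic base-step geometry averages (twist, tilt, roll,
  shift, slide, rise) and exact compositional descriptors, min-max normalised
  to [0,1]; the 64×11 trinucleotide table is constructed by averaging the two
  overlapping dinucleotide steps over eleven of those columns. Encoder
  correctness is table-independent (tests use synthetic identity / zero /
  random tables), and `load_property_table` accepts user tables (delimited
  text, oligomer in the first column, header row, values already in [0,1]).

## Benchmark construction

Identity between two windows is Hamming identity (matching positions / 41) —
appropriate because windows are fixed-length and gap-free. Redundancy
filtering is greedy incremental clustering in input order at a configurable
cutoff (default 0.8 within a class); it approximates word-filtered
global-alignment clustering tools but can differ near the cutoff for
sequences where gapped alignment would raise the identity. Cross-class
filtering removes negatives whose identity to any positive strictly exceeds
0.6. Splits are stratified: per repeat, floor(frac·n) of each class (default
frac 0.8, 10 repeats) is drawn without replacement into the benchmark set;
explicit per-class benchmark counts can be supplied where round published
sizes (800/800 of 980/980) must be reproduced exactly.

## Synthetic data

The generator emulates the position-specific composition contrast seen around
genuine 4mC sites: uniform ACGT background, centre forced to C, and with
per-block probability `effect_size` the planting of C runs at positions 1–3
and 15–17 and a T run at 28–32 in positives, and an A run at positions 1–3
in negatives. Defaults are 400 windows per class at effect size 0.8 — strong,
clean signal. What it does **not** emulate: genomic dinucleotide composition,
homology between windows, label noise, class imbalance, or any dependence
between positions beyond the planted blocks. Passing tests on this data
demonstrate that the pipeline recovers planted signal without leakage; they
say nothing about accuracy on real genomes, where the signal is weaker and
the published accuracies of comparable predictors sit near 0.8 rather than
near 1.0.

## Ensemble

- 28 base models = {RF, ERT, GB, SVM} × 7 encodings, in a fixed canonical
  column order (encoding-major, family order RF, ERT, GB, SVM).
- Hyperparameters are chosen by grid search on mean 10-fold stratified CV
  accuracy, ties broken by grid order. The default grids are deliberately
  small, desk-scale subsets (RF/ERT: 200 trees, sqrt features; GB: 100
  stages, depth 3, learning rate 0.1, sqrt features; SVM: C=1, gamma=scale);
  `full_grids()` exposes the wide ranges (trees 100–500 × {sqrt, log2}; GB
  {50,100,200}×{0.01,0.1}×{3,5}; SVM C ∈ 2^−5..2^5, gamma ∈ 2^−7..2^3) for
  full-scale reruns. A single-candidate grid skips the vacuous search.
- Meta-training inputs are produced **out-of-fold**: a shared stratified
  10-fold scheme fits each base configuration on nine folds and predicts the
  tenth, so no sample's probabilistic feature comes from a model that saw it.
  The deployed base models are then refit on the full benchmark.
- SVM probabilities come from Platt sigmoid calibration on an internal
  stratified 5-fold CV (`CalibratedClassifierCV(SVC(), ensemble=False)`).
- The four meta-predictors use the same families and grids on the 28-dim
  features. Fusion averages their probabilities and thresholds at ≥ 0.5;
  averaging subsumes majority voting for four voters and avoids 2–2 label
  ties. Fusion is monotone in each meta probability.
- Determinism: every stochastic component (fold shuffling, tree and SVM
  seeds) derives from the training seed through a fixed per-model mapping,
  so fixed seed + fixed data gives byte-identical predictions.
- Persistence is a single joblib bundle carrying a format version, the
  property tables, chosen hyperparameters and fitted states; loading a
  mismatched version is refused.

## Evaluation

ACC is computed as (TP+TN)/N — the standard form. MCC uses the product
formula with a 0 convention (and a warning) when the denominator vanishes;
single-class truth makes SN/SP/AUC undefined and raises. AUC is the
rank-based (trapezoidal) estimate. Position enrichment uses two-proportion
z-tests per (position, base) with Benjamini–Hochberg correction across all
41×4 tests; the constant centre position is flagged rather than tested. AUC
comparison is an unpaired two-tailed equal-variance t-test by default, with a
paired option, and returns p = 1 for two identical zero-variance vectors.
The 28×28 Pearson correlation analysis clusters columns by average linkage on
1 − r and reports the leaf order and the two-cluster memberships;
zero-variance columns are flagged and left NaN. The repeated protocol keeps
the two layers explicit: `crossval` runs repeated stratified k-fold CV of any
model builder, and the 80/20 repeated-split protocol trains on each benchmark
part and scores the matching independent part, with an id-overlap guard that
makes train/test leakage a hard error.

## Problem sizes

The default test-and-acceptance runs use 400 windows per class for the
planted-signal case (80/20 split, held-out n = 160) and 150 per class for the
signal-free leakage control — sizes at which the binomial error of a held-out
accuracy (±0.04 and ±0.065 at one SE) is small relative to the effects being
checked, while a complete two-layer training takes under two minutes on one
CPU.

## Known limitations

- The default physicochemical tables are assembled substitutes (above); for
  exact reproduction of a specific published property set, supply it as a
  table.
- Greedy Hamming clustering is not a drop-in for alignment-based clustering
  on variable-length or gapped data.
- The synthetic generator's independence assumptions make the classification
  task easier than real genomic discrimination; reported synthetic accuracies
  are upper bounds in spirit, not estimates of genomic performance.
- AdaBoost, logistic-regression and k-NN comparators are supported only at
  the metric-comparison level (any scorer can be passed to `crossval` /
  `compare_auc_ttest`); they are not ensemble members.
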