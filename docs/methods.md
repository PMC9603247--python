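# Methods

This note documents the model implemented by `acp_ada`, the defaults
and the reasoning behind the numerical choices, in the spirit of a
model-description appendix.

## Problem and pipeline

Given peptides over the 20-letter amino-acid alphabet with binary
activity labels (1 = anticancer peptide), the pipeline maps each
sequence to a fixed-length numeric vector and fits a boosted ensemble:

    FASTA → length normalization (Lx) → [BPF | mRMR-selected AAINDEX | AAC]
          → per-class feature-space augmentation (training folds only)
          → AdaBoost(Random Forest) → stratified 5-fold CV metrics

The representation assumes that ACP activity is driven by (a) the
identity and order of the first few N-terminal residues, (b) bulk
physicochemical character (charge, hydrophobicity, amphipathicity
proxies), and (c) overall residue composition — hence the three blocks.
No positional information beyond the N-terminal window and no pairwise
(k-mer) structure is encoded.

## Length normalization

Peptides shorter than `Lx` are padded with the neutral symbol `X`;
longer ones keep their first `Lx` residues (the N-terminal prefix,
which carries the BPF signal; no C-terminal variant is offered). The
pre-normalization length is kept on the record. `Lx ∈ {40, 50, 60}`
spans the bulk of observed ACP lengths (10–60); default 50.

## Encoding blocks

**BPF** (`20·k` entries, default `k = 7` → 140): position `i` of the
first `k` residues occupies a 20-entry one-hot group in alphabet order
`ACDEFGHIKLMNPQRSTVWY`; `X` maps to an all-zero group. `k = 7` is the
window reported to discriminate best in this family of predictors.

**AAINDEX** (`Lx · n_properties` raw entries): residue-major
flattening — entry `i·n_properties + p` holds property `p` of residue
`i`; `X` contributes zeros, mirroring the BPF zero-pad convention.
Property values are used as published (no scaling) by default;
`scale_properties=True` z-scores each property across its 20 residue
values. The packaged table holds ten classic published scales; any
AAINDEX-style TSV (one property per row, `NA` allowed, NA rows dropped
at load) can be substituted, e.g. a full 544-row table filters to 531
complete properties and gives a 21 240-dimensional raw encoding at
`Lx = 40`.

**AAC** (20 entries): residue-type counts over the non-`X` residues of
the normalized sequence, divided by the non-`X` count, so the block is
always a probability vector (sums to 1) and equals the classical
composition for unpadded peptides. For truncated peptides an
alternative denominator — the original length — is available via
`aac_denominator="original"`; the default keeps the probability-vector
property.

## mRMR feature selection

The raw AAINDEX space is reduced to `n_selected = 50` columns by greedy
forward selection maximizing `relevance − mean redundancy`:

* relevance = |point-biserial Pearson correlation| between column and
  label. For a binary label this ranks columns identically to the
  one-way ANOVA F statistic but is bounded in [0, 1], the same scale as
  the redundancy term; an unbounded relevance (F blows up to infinity
  on a perfectly separating column) would let exact duplicates of a
  selected column win the difference criterion. The classic F-statistic
  form (`method="f_stat"`, capped at a large sentinel) and a
  mutual-information form with 10-quantile binning (`method="mi"`)
  are provided for comparison.
* redundancy = mean |Pearson correlation| with the already-selected
  columns (mutual information under `method="mi"`).
* ties in the criterion (at 1e-12 relative tolerance) break to the
  lower mean redundancy, then the lower column index. The secondary
  key matters: once an exact label copy is selected, relevance and
  redundancy coincide for every remaining column and all criteria tie
  at zero; redundancy then separates a duplicate (redundancy 1) from
  fresh columns. The rule is deterministic and invariant to row order.
* zero-variance columns get relevance 0 and are never preferred; a
  matrix with no label-correlated column is rejected rather than
  selecting arbitrarily.

By default selection is fitted inside each training fold
(`selection_policy="per_fold"`), so held-out rows never influence the
chosen columns; `"global"` fits once on the full dataset for
replication of protocols that selected features before splitting.

## Data augmentation

Per class, `ceil(N/100 · class size)` pseudo-rows are drawn
(`N ∈ {100, 200, 300}` in the benchmark grid): a source row `F_i` is
sampled with replacement and perturbed multiplicatively,

    F_new = F_i + F_i ⊙ V · a,

with `V = 0` over the BPF block (noise would corrupt the 0/1 order
bits) and random elsewhere. Defaults: `V ~ U[0, 1)`, under which every
entry moves by strictly less than `a·|entry|` and zero entries stay
zero; `noise="gaussian"` substitutes standard-normal `V`. The
coefficient `a` defaults to 0.02 (ACP740-scale sets; 0.005 suits
smaller ACP240-scale sets). Augmentation is applied strictly inside
training folds — evaluation data is never augmented.

Draw order is part of the contract so seeded runs replay bit-for-bit:
classes in ascending label order; per class one `integers` call for all
source indices, then one noise vector per pseudo-row
(`numpy.random.default_rng(seed)`).

## Classifier

`AdaBoostClassifier` with learning rate 0.04, 406 boosting rounds and
seed 121, over a `RandomForestClassifier` base learner with 300 trees,
`min_samples_split=10`, `min_samples_leaf=1`, square-root feature
subsampling, bootstrap off and seed 120. scikit-learn's discrete SAMME
boosting is used (the only variant current scikit-learn provides;
boosting terminates early when a round fits the training set
perfectly, which is common on strongly separable data). Six comparison
classifiers (MLP, SVM, RF, KN, ET, GB) run at library defaults with a
fixed seed and exist for the with/without-augmentation sweep only.

## Metrics

ACC, PRE, SEN, SPE from the 2×2 confusion table with 1 = ACP, and the
Matthews correlation coefficient in its standard form

    MCC = (TP·TN − FP·FN) / √((TP+FN)(TP+FP)(TN+FP)(TN+FN)),

which equals the Pearson correlation of the two binary vectors (an
identity the tests check directly). Ratios with a zero denominator are
reported as 0 and flagged `undefined` so degenerate folds still
aggregate. MCC is the model-selection criterion in the grid runner
because it is informative under class imbalance.

## Cross-validation harness

`StratifiedKFold(shuffle=True)` with a fixed fold seed; stratification
keeps class balance in small sets. Reported values are unweighted means
over folds; per-fold values, fold memberships, selected columns and all
configs are retained in the report so a run can be audited and replayed.
The grid runner re-encodes from raw sequences per `Lx` (the raw
AAINDEX space, and hence the selection, changes with `Lx`) and the
per-fold augmentation seed is offset by the fold index so folds draw
independent noise.

## Synthetic data

The generator emulates the *shape* of ACP benchmarks: class sizes
(presets for 376/364 and 129/111), lengths uniform on 10–60, and a
composition signal — positives enriched in K/R with a mild hydrophobic
boost, negatives mildly acidic — consistent with the amphipathic
cationic character of real ACPs. Residues are i.i.d. within a
sequence, so there is no motif, periodicity, or length–class
correlation; passing tests therefore demonstrate pipeline correctness
and calibration of its mechanics, not predictive performance on real
peptides. The `strong-bias-200` preset (100/100, sharper K/R vs D/E
split) is the end-to-end benchmark condition; any competent classifier
should approach perfect accuracy there, making deviations diagnostic.

Benchmark problem sizes used by the test suite and the acceptance
script — 200-peptide CV runs, 30–100-peptide module tests, a
2000-sequence composition-convergence check — were chosen to exercise
every code path at desk scale while keeping runs short.

A synthetic full-size property table (544 rows, 13 with `NA`,
standard-normal values) stands in for a complete physicochemical
database in tests of the NA-filtering and high-dimensional paths; it is
labelled synthetic and carries no physicochemical meaning.

## Degenerate inputs and numerical conventions

* All-`X` sequences: valid records, but composition encoding is
  refused (zero denominator).
* Empty record lists encode to a 0-row matrix with the correct width;
  empty prediction input returns empty outputs.
* Single-class label vectors are rejected by selection, augmentation
  and training.
* Augmentation pseudo-counts round up (never under-deliver).
* Model training and prediction validate feature width and carry the
  selection fingerprint (SHA-1 of the training matrix) to catch
  encoder/model mismatches.

## Known limitations

* Composition-driven synthetic data cannot certify real-world ACP
  accuracy; the public ACP740/ACP240 FASTA sets must be supplied by the
  user to replicate published-scale benchmarks.
* The packaged ten-property table is a compact default, not a full
  physicochemical database; selection over it explores a much smaller
  column space than a 531-property table.
* No redundancy reduction (CD-HIT-style) is performed; inputs are
  assumed deduplicated.
* No probability calibration is attempted; scores are the ensemble's
  `predict_proba` output.
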