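# Methods

This note records the model, its tunable parameters, the numerical
conventions, and the design choices made where more than one reasonable
option existed. It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model and assumptions

The predictor assumes that interaction propensity is readable from
primary sequence alone: proteins through the composition-and-order
signal of reduced-alphabet 3-mers, RNAs through the distributional
semantics of nucleotide 3-mers. No structure, conservation or
physicochemical profile is used. Both feature maps are
length-independent by construction (SVD reduction; blockwise pooling),
which is what makes multi-kilobase lncRNAs tractable without
truncation.

### Protein path

* Amino-acid classes: {A,G,V}, {Y,M,T,S}, {I,L,F,P}, {H,N,Q,W}, {D,E},
  {R,K}, {C}, in that fixed order; the triad (g1,g2,g3) indexes row
  49·g1 + 7·g2 + g3 of the occurrence matrix. This is the standard
  conjoint-triad partition of all 20 residues under the dipole /
  side-chain-volume scheme. (Some statements of the partition circulate
  with a corrupted second class "TMTS", which duplicates T and omits Y;
  we use Y,M,T,S.)
* k = 3 (configurable), so the matrix has 7³ = 343 rows and n−2 columns.
* Reduction: σ₁·u₁ with the sign fixed so the largest-magnitude entry is
  positive. Scaling by σ₁ (default) retains sequence-length/occupancy
  information; `scale_by_sigma=False` yields the unit-norm u₁ variant.
  An all-zero matrix (every window ambiguous) reduces to the zero
  vector with a warning.
* Triads covering an ambiguous residue contribute an all-zero column
  rather than being dropped, preserving the n−2 column count.

### RNA path

* 3-mer tokenization, stride 1; windows containing non-ACGU characters
  are skipped. T is normalized to U at read time, so DNA-convention
  files are accepted losslessly.
* GloVe hyperparameters: d = 32, symmetric flat context window of 5
  tokens, x_max = 100, α = 0.75, AdaGrad with base rate 0.05, 50
  epochs, seeded initialisation. The embedding dimension is the method
  constant; the window and weighting constants are the canonical GloVe
  defaults, adopted because the corpus (64-word vocabulary, usually
  10⁴–10⁵ tokens) gives no reason to deviate. All are configurable.
* The final word vector is ω + ω̃ (standard symmetric-role practice).
* Embedding scope: by default the GloVe corpus is the *training-fold*
  RNA sequences only, so cross-validation folds share no information
  through the (label-free) embedding; `embedding_scope='all'` enables
  whole-dataset fitting, which is the common but slightly leaky
  practice.
* Local fusion pooling operates on *tokens* (the pooled objects are
  token vectors): G = 11 contiguous blocks, the first (L mod G) blocks
  one token larger (balanced-partition convention, larger blocks
  first), blockwise means concatenated block-major; with fewer than G
  tokens the trailing blocks are exact zeros.

### Feature remap

The discrete Hilbert transform is implemented as a frequency-domain
multiplier: strictly positive frequencies × (−i), strictly negative
× (+i), DC and (for even length) the Nyquist bin zeroed; the output is
the real sequence of the same length (the imaginary part of the
analytic signal). This convention makes the transform a deterministic
linear involution-up-to-sign: H(H(x)) = −x for mean-free signals, and
‖H(x)‖ = ‖x‖ when DC and Nyquist carry no energy. The transform is
applied to each molecule's raw vector *separately* (keeping the printed
343 and 11×32 dimensions meaningful) and *replaces* the raw vector;
concatenating raw+transformed is available via configuration. The
auto-covariance baseline uses 8 lags per molecule vector and the
wavelet baseline a single-level Haar decomposition (odd lengths
zero-padded) — these parameter choices are this package's
instantiations of the baselines, not claims about any prior setting.

### Ensemble

* Base learners: XGBoost with depth-6 trees (a linear booster is
  selectable but inconsistent with a tree depth, so trees are the
  default), an RBF SVM behind a standardizing scaler with sigmoid
  (Platt) calibration on 3 internal folds, a random forest with 25 Gini
  trees and `random_state=1`, and extremely randomized trees at library
  defaults. The SVM scaler is a conditioning choice: the protein
  vectors have norms of order √n, which would otherwise dominate the
  kernel's global bandwidth.
* Internal encoding uses F = 4 stratified seeded fractions — F is
  deliberately distinct from the number of base classifiers N = 4 even
  though both happen to be four. Test-time encodings are the average of
  the F fold models' probabilities; no refit on the full training set
  is performed, so every prediction path is covered by the recorded
  fold models.
* Adaptive weights: λ^c = 1 − (1 − (w^c)²)^N with w^c the mean held-out
  AUC of classifier c and N the number of base classifiers. The
  formula is 1 for a perfect classifier, shrinks weak ones toward 0,
  and is monotone in w^c; it is pluggable (`weight_fn`). λ(0) = 0 is a
  theoretical edge (an AUC-0 classifier), accepted rather than clamped.
* Meta layer: L2-regularized logistic regression (C = 1), convex and
  deterministic. Voting resolves 2–2 ties (and probabilities of exactly
  0.5) to the negative class, logged as rejections.

### Evaluation

Stratified five-fold cross-validation over *pairs* (molecules may be
shared across folds, as in the published benchmark protocols); the full
pipeline, embedding included, is refitted per fold. The classification
threshold is 0.5 on the meta probability; AUC uses the raw
probabilities in the rank-statistic form (ties count ½). The reported
"±" is the population standard deviation over folds. Metrics with zero
denominators return 0 with a warning.

## Synthetic data generator

The generator emulates the *shape* of the small public RNA–protein
interaction benchmarks: defaults of 25 RNAs × 247 proteins × 488
balanced pairs, RNA lengths 50–3000 nt, protein lengths 50–1500 aa,
uniform background composition. The interaction signal is motif
co-occurrence, so that the signal must survive the actual feature path
(tokenization, embedding, pooling, SVD, transform) rather than being a
feature-space shift:

* When signal strength s > 0, fixed fractions (0.6 / 0.6) of the RNAs
  and proteins are designated motif-bearing; designated sequences
  receive the motif at one uniformly placed occurrence per 200
  residues (minimum one). Recurring occurrences mirror the repeated
  binding sites of real RBP targets and are what keeps a 16-nt motif
  detectable through blockwise mean pooling of a 3000-nt transcript — a
  single occurrence would be diluted ~200-fold and carry no usable
  signal at benchmark sample sizes.
* Positive pairs are drawn from motif×motif combinations with
  probability s; negative pairs never pair two motif-bearing
  molecules. Assigning motif status at the sequence level (rather than
  implanting per pair) keeps labels consistent when the same RNA
  appears in many pairs, exactly as in the few-RNAs/many-proteins
  benchmark shape.
* At s = 0 nothing is implanted and pairing is uniform — a pure null in
  which any cross-validated AUC away from 0.5 reflects overfitting to
  shared-molecule base rates, not signal.
* Labels are flipped independently with probability ε (default 0).

What the generator does **not** emulate: real lncRNA composition bias,
secondary structure, homology between sequences, and realistic motif
degeneracy (the motif is exact). Passing tests therefore demonstrate
that the pipeline recovers a planted sequence-level co-occurrence
signal at benchmark-scale sample sizes and is calibrated under the
null — not that it attains any particular accuracy on biological data.

## Problem sizes

Library-level studies in the test suite and the acceptance script use a
300-pair dataset (16 RNAs × 150 proteins, the default length ranges)
for signal-recovery runs, and smaller (40–120 pair, shortened-sequence)
datasets for structural and determinism checks — the package's standard
desk-scale study configurations.

## Known limitations

* The SVM's sigmoid calibration can be poorly conditioned on very small
  internal folds (< ~30 samples per class); the stacking meta layer
  absorbs most of the damage, but single-learner probabilities at that
  scale should not be over-interpreted.
* The GloVe trainer is a plain per-cell AdaGrad loop; at the 64-word
  vocabulary this is fast, but it is not meant for large vocabularies.
* Proteins shorter than 3 residues (or RNAs shorter than 3 nt) cannot
  be featurized and are rejected with an error naming the record.
* Cross-validation is over pairs; molecules shared between folds mean
  the reported numbers measure generalization to unseen *pairs*, not to
  unseen molecules. This matches the published benchmark protocol but
  overstates performance for truly novel RNAs or proteins.
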