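# rpistack

Sequence-only prediction of non-coding RNA–protein interactions.

Interactions between ncRNAs (in particular lncRNAs) and RNA-binding
proteins drive gene regulation, splicing and chromatin remodelling, but
wet-lab interaction screens are slow and expensive. `rpistack` predicts
whether an (RNA, protein) pair interacts using nothing but the two
sequences, for computational biologists who want a fast, trainable
screen over candidate pairs.

## Method

**Protein features.** The 20 amino acids are partitioned into 7
conjoint-triad classes by dipole moment and side-chain volume —
{A,G,V}, {Y,M,T,S}, {I,L,F,P}, {H,N,Q,W}, {D,E}, {R,K}, {C}. A protein of
length *n* becomes a binary sparse matrix *L* ∈ {0,1}^(7³ × (n−2)) whose
column *j* one-hot encodes the class triad at positions (j, j+1, j+2).
The matrix is reduced to a fixed vector σ₁u₁ ∈ ℝ³⁴³ by its leading
singular pair (sign fixed deterministically; triads covering ambiguous
residues give all-zero columns).

**RNA features.** An RNA of length *m* is a sentence of *m*−2 overlapping
3-mer words over a 64-word vocabulary. A GloVe model — implemented here
from scratch — fits word vectors ω, ω̃ and biases to the windowed
co-occurrence counts x_ij by minimising

    J = Σ_ij f(x_ij) (ω_i·ω̃_j + b_i + b̃_j − log x_ij)²,
    f(x) = (x/x_max)^α for x < x_max, else 1,

with d = 32, a symmetric flat window of 5 tokens, x_max = 100, α = 0.75,
AdaGrad updates. Token vectors (ω+ω̃) are pooled by a *local fusion
strategy*: the token sequence is split into G = 11 contiguous blocks
(larger blocks first), blockwise means are concatenated, and missing
blocks are zero-filled — a fixed 352-vector for any RNA length.

**Feature remap.** Each raw molecule vector is passed through the
discrete Hilbert transform (−i on positive frequencies, +i on negative,
DC/Nyquist zeroed) — a 90° phase shifter that preserves energy —
and the pair is represented by the 343 + 352 = 695 concatenation.
Auto-covariance and single-level Haar DWT remaps are available as
baselines, plus identity.

**Classifier.** A stacking ensemble: four base learners (depth-6
gradient-boosted trees, RBF SVM with sigmoid-calibrated probabilities,
a 25-tree Gini random forest, extremely randomized trees) are each
fitted on F = 4 stratified internal fractions, producing out-of-fold
probability encodings tr^c, fold-averaged test encodings
te^c = (1/F)Σᵢ teᵢ^c, and held-out AUCs w^c. Adaptive weights
λ^c = 1 − (1 − (w^c)²)^N (N = 4 base classifiers) shrink weak learners'
encodings before a logistic level-1 decoder combines them. Uniform
averaging, plain stacking and strict-majority voting (ties → reject →
negative) are available for comparison.

Performance is reported by stratified five-fold cross-validation with
Acc, Prec, Sen, F1, MCC and ROC AUC (mean ± population std over folds).

## Worked example

Because the published benchmark interaction sets are external
supplements, the package ships a seeded generator that emulates their
shape (few RNAs, many proteins, hundreds of pairs) with a planted
motif-co-occurrence signal:

```sh
rpistack simulate --seed 42 --n-pairs 120 --n-rnas 12 --n-proteins 60 --out demo_data
rpistack evaluate --rna-fasta demo_data/rnas.fasta \
                  --protein-fasta demo_data/proteins.fasta \
                  --pairs demo_data/pairs.tsv \
                  --seed 42 --out demo_eval
cat demo_eval/report.tsv
```

```text
fold    acc       prec      sen       f1        mcc       auc
0       0.791667  0.888889  0.666667  0.761905  0.602464  0.951389
1       0.791667  0.705882  1.000000  0.827586  0.641689  0.895833
2       0.875000  0.800000  1.000000  0.888889  0.774597  0.888889
3       0.750000  0.800000  0.666667  0.727273  0.507093  0.944444
4       0.833333  0.833333  0.833333  0.833333  0.666667  0.916667
mean    0.808333  0.805621  0.833333  0.807797  0.638502  0.919444
std     0.042492  0.059519  0.149071  0.056938  0.087054  0.025077
```

Each fold row holds the held-out metrics of a pipeline (embedding,
features, transform, ensemble) refitted on the other four folds; the
mean AUC of 0.92 says a random interacting pair outscores a random
non-interacting one 92% of the time on this dataset. `rpistack train`
persists a reusable model bundle and `rpistack predict` scores
unlabeled pairs with it; `--strategy` and `--transform` switch the
ensemble strategy and the feature remap for ablation-style comparisons.

Library use mirrors the CLI:

```python
from rpistack import SimulationConfig, simulate, PipelineConfig, cross_validate

dataset = simulate(SimulationConfig(n_pairs=300, n_rnas=16, n_proteins=150, seed=1))
report = cross_validate(dataset, PipelineConfig(seed=1), folds=5, seed=1)
print(report.summary_frame().round(3))
```

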