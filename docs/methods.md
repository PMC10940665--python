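# Methods

`multippi` predicts protein-protein interactions (PPIs) by representing each
candidate pair as the concatenation of two per-protein feature vectors — a
sequence part and a network part — and scoring the pair with a Random Forest
under stratified five-fold cross-validation.  This note documents the model,
its parameters and defaults, the synthetic data the package tests itself
against, and the numerical conventions that make results reproducible.

## Sequence features: standardized descriptors and auto-covariance

Each of the 20 standard amino acids carries six physicochemical descriptors:
net charge index of side chains (NCISC), side-chain volume (VSC), polarity
(P1), solvent-accessible surface area (SASA), hydrophobicity (H), and
polarizability (P2).  Before use, every descriptor column P_j is
standardized over the 20 amino acids,

    P'_ij = (P_ij - mean_j) / sd_j ,

with the *population* standard deviation (divisor 20).  Standardization is
idempotent in the sense that shifting or rescaling a raw column leaves the
standardized column — and therefore every downstream feature — unchanged;
the test suite asserts this.

A protein of length N becomes six numeric tracks X[1..N, j].  For each
track and each lag d = 1..D the auto-covariance is

    AC(d, j) = (1 / (N - d)) * sum_{i=1..N-d} (X[i,j] - m_j)(X[i+d,j] - m_j) ,

where m_j is the track mean over the *whole* sequence.  With the defaults
D = 30 and 6 descriptors this yields the 180-dimensional sequence vector,
ordered descriptor-major with lag fastest.  The lag count is read
inclusively (lags 1..30), the only reading consistent with the 30 x 6 = 180
dimensionality.  Sequences must satisfy N >= D + 1 so every lag has at least
one term; shorter sequences raise a named error rather than being silently
zero-padded, which would corrupt the feature scale.  Non-standard residues
(B, J, O, U, X, Z, gaps) follow a policy: the default `mean_impute` maps
them to the standardized column mean (exactly zero), `strict` raises, and
`drop` removes them before N is measured.

Numerical detail: tracks are anchored at their first residue before
centering (auto-covariance is shift-invariant), which makes the
homopolymer's AC vector exactly zero in floating point, not merely tiny.

## The multi-source association network

Nodes are biomolecules of five classes — proteins, miRNAs, lncRNAs, drugs,
diseases — connected by eight undirected, unweighted association types
(miRNA-disease, drug-protein, miRNA-lncRNA, lncRNA-disease, drug-disease,
protein-disease, miRNA-protein, lncRNA-protein).  Identifiers are
namespaced by class ("protein:P53"), so ids need only be unique within a
class; an optional alias-to-canonical synonym map is applied before
namespacing.  Duplicate edges collapse and self-loops are rejected.

Known protein-protein interaction edges are **excluded from the embedding
graph by default**: they are the labels of the prediction task, and
embedding them would leak the answer into the features.  A flag re-enables
them for leakage ablations only.

## Network features: DeepWalk

The network is linearized into a corpus of node "sentences": for every node,
`walks_per_node` truncated random walks of at most `walk_length` steps, each
step choosing a neighbor uniformly.  Walks that reach a neighbor-less node
stop early (the length is an upper bound).  SkipGram then maximizes the
probability of the window-w context around each walk position, with context
order ignored, factorizing each conditional over a Huffman tree built from
corpus frequencies:

    Pr(u | Phi(v)) = prod_k sigmoid(+/- Phi(v) . phi(b_k)) ,

a product over u's root-to-leaf path, the sign encoding the branch taken.
This hierarchical softmax is exactly normalized over the vocabulary by
construction (sigmoid(z) + sigmoid(-z) = 1), which the tests verify by
enumeration.  Training is plain sequential SGD, single-threaded, learning
rate decayed linearly; a fixed seed therefore reproduces embeddings bit for
bit on a given platform.  A negative-sampling objective (unigram^0.75
noise distribution) is available behind a flag but hierarchical softmax is
the default and the tested path.

Defaults: walks_per_node 30, walk_length 40, window 5, dimension 64,
5 epochs, initial learning rate 0.025 decaying to 1e-4.  These sit near the
original DeepWalk settings, scaled so that a ~700-node graph embeds in well
under a minute on one core.  The embedding dimension is a free parameter of
this package, not a reproduction claim; 64 gives near-perfect linear
recovery of planted communities on the synthetic networks (we also measured
128, which spreads the same community information over more coordinates and
slightly *hurts* the downstream forest).

## Pair assembly

Pairs are canonicalized by lexicographic id order, so (A, B) and (B, A) are
one pair.  Negatives are drawn uniformly without replacement from the
unordered pairs not listed as positive — the standard positive-unlabeled
simplification — with exactly as many negatives as positives.  Negatives
are sampled once per dataset and then split into folds, not resampled per
fold.  Each protein's vector is its 180-dim sequence part concatenated with
its 64-dim network part; a protein absent from the association network
(cold start) keeps its sequence part and receives a flagged zero network
vector instead of being dropped (a strict mode drops it).  A pair's row is
the concatenation of its two protein vectors: 2 x (180 + 64) = 488 features
in combined mode, 360 sequence-only, 128 network-only.

## Classifier and evaluation

The classifier is a Random Forest of 300 trees (the sweep over 180..340 in
steps of 20 identifies ~300 as a consistently good operating point; the
sweep utility reuses one fold assignment across the whole grid so that tree
count is the only thing varying).  Package defaults: `max_features = 0.5`
and `min_samples_leaf = 10`.  These two defaults depart from the common
sqrt-mtry/fully-grown convention deliberately: the pair vector concatenates
two blocks of very different character (360 auto-covariance dims, 128
embedding dims), and deciding whether two proteins lie in the same network
community requires conjunctions of splits on both embedding halves.  With
sqrt-mtry (22 of 488 candidates per split) those conjunctions are rarely
assembled and deep, spurious splits on uninformative dims degrade the
probability estimates — a well-documented Random-Forest failure mode in the
presence of many irrelevant features.  Raising mtry to half the features
and stopping leaves at 10 samples recovers most of the attainable margin on
the planted benchmark; both remain configurable.

Threshold metrics at a 0.5 probability cut: specificity TN/(FP+TN),
precision TP/(FP+TP), sensitivity TP/(TP+FN), accuracy (TP+TN)/total, and
the Matthews correlation coefficient, with the 0/0 -> 0 convention for MCC
and a warned 0 for precision when nothing is predicted positive.  AUC is the
trapezoid area under the ROC curve (equivalently the pairwise rank
statistic with ties at one half); AUPR uses the step-wise right-continuous
rule (average precision), never linear interpolation, which is the standard
recommendation for PR curves.  Cross-validation is stratified (the split is
only said to be "equal" in the method's origin; stratification guarantees
both classes in every fold) with the seed recorded.

## Synthetic data: what it emulates and what it does not

Real inputs for this method are a curated PPI set and eight association
databases; the generator replaces them with a seeded, self-contained bundle
at desk scale.  Defaults: 300 proteins, 100 nodes in each other class,
2,000 positive pairs, sequences 50-250 residues, seed 7.

* **Network**: every node is assigned to one of 6 blocks (communities);
  a cross-type pair gains an edge with probability p_in = 0.15 inside a
  block and p_out = 0.01 across blocks.  Six blocks of ~115 nodes at a
  15:1 density contrast give a mean degree near 15 and communities that
  random-walk embeddings recover almost perfectly — a clean, recoverable
  stand-in for the modular structure of real interactome neighborhoods.
* **Sequences**: i.i.d. uniform residues; when the sequence signal is on, a
  fixed 10-mer motif is implanted in a 30% subset of "carrier" proteins.
* **Labels**: positive pairs are drawn without replacement with weight
  `f_block * f_motif`, where each factor is `(1 - s) + s * odds *
  [indicator]` with odds 99 and s the corresponding signal dial.  At s = 0
  the factor is identically 1 (uniform sampling — the null); at s = 1 pairs
  failing the indicator have weight zero, so e.g. full network signal makes
  every positive pair block-internal.  A purely additive weight of the form
  1 + s*[indicator] was rejected at design time: it caps the planted odds
  at 2:1, for which the Bayes-optimal AUC is about 0.58 — no pipeline could
  demonstrate recovery against such a ceiling, defeating the purpose of a
  planted benchmark.

With full network signal the Bayes ceiling of the benchmark is 1 - q/2
(about 0.92 for q ~ 1/6, the chance that a random negative pair shares a
block), because a perfect block oracle still scores same-block negatives as
high as positives.  The defaults leave the sequence signal off, so the
sequence features act as realistic high-dimensional nuisance dims in
combined mode and the combined-vs-sequence-only ablation has a known
answer: combined must win, sequence-only must sit at chance.

What the generator does **not** emulate: realistic residue composition or
evolution, the degree distributions and sizes of the real databases, or
disease-ontology semantics.  Passing the planted-recovery tests shows the
pipeline's machinery extracts the structure it is designed to extract; it
does not certify performance on real interactomes.

## Problem sizes used by the test and acceptance runs

The end-to-end checks run the full default fixture (300 proteins, 2,000
positive + 2,000 negative pairs, ~700-node network) for the planted,
sequence-only and null conditions; the forest-size sweep uses a reduced
fixture (120 proteins, 400 positive pairs, sequence-only features) since it
checks the sweep's contract, not its power.  These sizes keep a complete
run in the tens of minutes on a single core while leaving the planted
signal comfortably detectable.

## Known limitations

* Hierarchical-softmax SGD uses fastmath vectorization; embeddings are
  bit-reproducible for a fixed seed on a given platform, but may differ in
  the last bits across CPU generations.  Downstream conclusions are
  insensitive to this.
* Uniform negative sampling ignores degree and localization biases of real
  non-interacting pairs; hard-negative strategies are out of scope.
* The multi-source network is unweighted and undirected; association
  confidence scores, directions and edge weights are not modeled.
* Cross-validation splits pairs, not proteins, matching the method's
  original protocol; protein-disjoint evaluation (a stricter cold-start
  test) is not implemented.
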