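# Methods

## Problem

Assigning a protein sequence to a functional family is easy when it is
similar to annotated references and notoriously hard in the *twilight
zone* — below roughly 40% (and especially 30%) identity to every
reference, where alignment-based function transfer becomes unreliable.
`famvote` implements a per-family ensemble classifier built from
homology-derived features: for each family an ensemble of three
weighted linear SVMs decides, independently of all other families,
whether a query belongs to it. A query may therefore receive several
family calls, exactly one, or none (the "novel family" signal).

## Features

For a query sequence and N families, a small reference database with
`n_ref` (default 10) sequences per family — 10N sequences in total —
is searched with affine-gap Smith–Waterman local alignment (BLOSUM62,
gap open 11 / extend 1; a gap of length L costs 11 + L). Per family,
only the best hit is kept (maximum bit-score, ties broken by E-value
and then subject id) among hits with E-value ≤ 10, yielding three
values per family:

* **bit-score** `(λS − ln K)/ln 2` with Karlin–Altschul parameters
  λ = 0.267, K = 0.041 (standard gapped BLOSUM62 constants; the raw
  score S is the dynamic-programming optimum),
* **E-value** `m·n·2^(−bit)` with m the query length and n the total
  residue count of the reference database (no finite-size edge
  correction — a documented simplification),
* **percent identity**, counted over all alignment columns including
  gapped ones.

Missing hits are imputed as (0, 0, 0): zero bits, E-value ≥ 1, zero
identity — the natural "no similarity" point. E-values enter feature
vectors as −log10(max(E, 1e−180)) because raw E-values span hundreds
of orders of magnitude; a raw mode is available.

A second block of M profile scores comes from ungapped
position-specific score models built from seed alignments: per match
column (columns >50% gaps are dropped) the log2 odds of the
pseudocounted residue frequency against a background distribution
(uniform 1/20 by default). A sequence's bit-score against a profile is
the best sum over all placements of the profile along the sequence;
E-values come from an exponential tail fitted by regression to the top
20% of scores of 1000 random background sequences of length 300. These
models deliberately omit insert/delete states: they only need to
supply a (bit-score, E-value) pair per model as classifier features,
and scores from externally built profile HMMs (hmmscan
`--domtblout`) can be substituted through a parser adapter. Likewise,
externally computed BLAST tabular output (outfmt 6) can replace the
internal aligner; both adapters produce the same in-memory shapes.

The full feature vector has length 2M + 3N. The three classifiers of
a family's ensemble see different slices: model 1 the full vector
(similarity to the target family plus *dissimilarity* to every other
family), model 2 the 2M profile features plus the target family's
triple (2M + 3), model 3 the target triple alone (3).

## Training

For a target family, all its training members are positives. Negatives
are subsampled: at most 10 per other family (seeded uniform without
replacement), which with 1000 families of 200 members shrinks the
negative pool from 199,800 to 9,990 — a factor of 20. The residual
imbalance is handled in the loss: every positive carries 9× the weight
of a negative. Each classifier is a linear SVM with squared hinge loss
and L2 penalty (C = 1 by default), fit on per-feature standardized
inputs (mean/scale estimated on its own training set and stored with
the model). Per-classifier probabilities are Platt sigmoids
σ(A·d + B) fit on decision values from an internal stratified 3-fold
split, so the calibrator never sees decisions on its own training
points (on separable data that would degenerate). The binary votes use
the raw decision sign and are therefore calibration-independent.

## Ensemble

The per-family prediction is the majority vote of the three
classifiers (no tie is possible with three voters). The ensemble
probability is the closed-form chance that at least two of three
independent Bernoulli(p_i) classifiers fire,

    Pr = p1p2p3 + p1p2q3 + p1q2p3 + q1p2p3,   q_i = 1 − p_i,

which is symmetric, monotone in each argument, and equals 1 (0) when
the votes are unanimously certain. Membership in the predicted set is
decided by the vote; the probability is reserved for ranking and ROC
analysis. For hierarchically organized data, leaf-level predictions
propagate bottom-up: the parent set is the union of predicted leaves'
parents with the maximum contributing probability (the combination
rule is our choice; only the bottom-up direction is inherent).

## Evaluation protocols

* **Identity to training.** Each test sequence is aligned against all
  training sequences plus the profile seed sequences; the identity of
  the best-bit-score hit is recorded only when the alignment spans at
  least `min_aln_len` residues (default 100, configurable because
  synthetic sequences can be shorter). Bins are half-open: (0,30],
  (30,40], (40,70], (70,100].
* **predCount accuracy.** Sequences are stratified by the size of
  their predicted set {1..5, >5, 0}; a sequence is correct iff its
  true family is in the set. In hierarchical mode, sets larger than
  `discard_over` (typically 5) count as wrong regardless of content.
  An empty set is correct only for sequences from families excluded
  from training.
* **ROC/AUC.** Per family, one-vs-rest over the ensemble probability;
  tied scores are grouped into a single threshold step so the
  trapezoidal AUC equals the Mann–Whitney concordance probability with
  half credit for ties. The novel-family protocol pools a family's
  positive test sequences with all sequences from held-out families
  and expects them to be scored low.

## Synthetic benchmark generator

Real corpus-scale benchmarks require external downloads, so the
package ships a generator whose families descend from randomized
positional profiles: each column draws a conservation weight c (by
default uniform in [0.85, 1]) and emits residues from
c·δ(consensus) + (1−c)·Dirichlet(1). Members are mutated per site —
substitution with probability r (uniform over the 19 other residues),
rare geometric indels (capped length) so alignment lengths vary — so
realized identity to the family consensus is ≈ 100·(1−r)% on conserved
columns. The default divergence mixture (weights 0.58/0.30/0.12 at
substitution rates 0.05/0.40/0.68) places about 12% of members at
≤ 40% identity, a realistic twilight fraction for orthologous-group
corpora. Sequence lengths default to 160–220 so local alignments are
cheap but still exceed a 60-residue alignment-length rule used when
binning synthetic data. Held-out ("novel") families come from freshly
drawn profiles and share no identifiers or profiles with the main
dataset; profile-model seed alignments are emitted without indels
(equal-length rows), with 20% of them derived from main-dataset family
profiles to mimic the partial overlap a public profile library has
with one's target families.

What the generator does not emulate: phylogenetic structure (no tree,
no WAG/LG rate matrices), domain architecture, length/composition
biases, or alignment heuristics' artifacts. Passing tests therefore
demonstrate the pipeline's mechanics and its qualitative
identity-vs-accuracy behaviour, not performance on real corpora.

## Numerical and design choices

* Family order is lexicographic and persisted with every artifact;
  feature columns are meaningless without it.
* Cross-validation folds are stratified per family (members dealt
  round-robin after a seeded shuffle), guaranteeing each family has
  train and test members in every fold — required by per-family
  evaluation.
* Reference sequences remain part of the SVM training set; their ids
  are recorded so they can be excluded downstream if desired.
* Best-hit tie-breaks (bit, then E-value, then subject id) make the
  reduction order-independent and idempotent.
* Profile null calibration requires ≥ 100 shuffles and raises on
  degenerate (constant) score distributions.
* All randomness flows through explicit integer seeds; identical
  inputs and seeds give byte-identical artifacts.

## Problem sizes used in the shipped analyses

The benchmark run reported by `scripts/acceptance.py` uses 20 families
of 60 members (substitution rate ≤ 0.1, 3-fold split, 400 test
sequences) plus 5 held-out novel families of 12 members, and a
twilight analysis of 5 replicates of 8 families × 24 members under the
default mixed-divergence bins. These sizes give stable statistics on a
single CPU in minutes while exercising every pipeline stage.

## Known limitations

* The alignment statistics use fixed Karlin–Altschul constants and an
  uncorrected m·n search space; E-values are comparable within a run
  but are not BLAST-identical.
* Ungapped profile models understate the sensitivity of full profile
  HMMs; the hmmscan adapter exists precisely so real scores can be
  swapped in.
* With extremely similar sibling families the per-family ensembles
  tend to abstain (empty prediction sets) rather than multi-predict;
  predCount > 1 arises mainly for moderately overlapping families.
* Single-domain assumption throughout: one family call per sequence
  region is not modelled.
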