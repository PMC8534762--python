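# Methods

This note documents the estimators, the classifier, the synthetic data
generator, and the numerical and design choices behind them.

## Soft encoding and ambiguity codes

A residue string over {A,C,G,T} ∪ {R,Y,M,K,S,W,H,B,V,D,N} is mapped to an
L×4 row-stochastic weight table: an unambiguous residue gives a unit
indicator row, a degenerate code distributes unit mass uniformly over the
nucleotides it denotes (R = {A,G} → (½,0,½,0), N → (¼,¼,¼,¼), …). This is
the contract for *all* downstream estimators: natural-vector counts are
weight sums, and joint pair counts use products w_k(s_i)·w_l(s_{i+τ}) — a
fractional co-occurrence count that reduces exactly to pair counting on
unambiguous input. Uridine is folded to T on input so RNA and DNA corpora
are treated uniformly; case is normalized (soft-masking is ignored — no
distinct treatment of lower-case residues). Gap characters are rejected
rather than skipped: the fingerprints are positional, and silently deleting
positions would distort every moment and shift.

## MIF and rMIF estimation

For shift τ, the joint p(k,l) is the plug-in estimate over the L−τ ordered
position pairs, read 5′→3′ only (no reverse-complement symmetrization).
Marginals are defined as the row/column sums of the joint — the
non-symmetric convention in which the first marginal is the nucleotide
distribution over positions 1..L−τ and the second over τ+1..L. This makes
marginal consistency an identity rather than an approximation and is the
only convention under which the resolved decomposition sums exactly to the
MIF.

Conventions and edge cases:

- Logarithm base 2 (bits) by default; `base=e` gives nats.
- 0·log 0 := 0 and 0^α := 0; terms with zero joint mass are skipped. A
  nonzero joint entry forces both of its marginals nonzero, so no division
  by zero can occur.
- The MIF scalar is computed as the sum of the four resolved entries, so
  the resolution identity Σ_x F(x,τ) = F(X,τ) holds bit-exactly by
  construction, and the Rényi and Tsallis resolved functions share one code
  path (their F-quantities are equal; only the scalar transforms differ).
- Tsallis information uses I = (F−1)/(α−1), which is non-negative for
  α > 1 because F ≥ 1 on any estimated distribution (power-mean
  inequality). The opposite affine form (1−F)/(α−1) is available as
  `convention="printed"`; it is the negation and goes negative whenever the
  sequence carries any dependence, so it is not the default.
- Feature values are the F-quantities, not the log/affine-transformed I:
  the transforms are monotone, and F is finite for every estimated
  distribution (the Rényi log diverges at F = 0).
- A sequence with L ≤ τ raises a shift-too-large error naming the sequence;
  `on_short="nan"` in the feature-table builder instead emits NaN rows so a
  heterogeneous corpus can be featurized and filtered by the caller.

The plug-in MIF estimator is positively biased at finite L (roughly
(|A|−1)²/(2 L ln 2) bits for an i.i.d. sequence); no bias correction is
applied, since features are compared across sequences processed
identically. Tests only assert the decay of this bias with L, not its
absence.

## Natural vectors

Positions are 1-based, matching the Σ_{i=1}^{n} indexing of the moment
formulas. Blocks are ordered A, C, G, T as (n_k, μ_k, D_k², …, D_k^{jmax}).
For an absent nucleotide (n_k = 0) the convention μ_k = D_k^j = 0 keeps
vectors finite and the dimension fixed at 4·(j_max+1). Moments use a
two-pass scheme (exact mean first, then centered powers). j_max is capped
at 15: with the n_k^{j−1} L^{j−1} normalization, higher moments are
numerically vanishing for realistic lengths. The first central moment is
identically zero and is therefore not stored; the vector keeps the
explicit (count, mean, central moments ≥ 2) component list.

## GLVQ / GMLVQ / limited-rank matrix LVQ

The classifier is trained by per-sample SGD on Σ f(μ) with
μ = (d⁺−d⁻)/(d⁺+d⁻) and the mapped distance d_Ω(x,w) = ‖Ω(x−w)‖².
Gradients follow the chain rule: with S = d⁺+d⁻, ∂μ/∂d^± = ±2d^∓/S²,
∂d/∂w = −2ΩᵀΩ(x−w) and ∂d/∂Ω = 2Ω(x−w)(x−w)ᵀ. Correctness is gated by a
central-finite-difference test (relative error < 1e-5 on random instances),
not by a transcribed formula.

Choices that were genuinely open, and what this package does:

- **Squashing f**: identity by default; a logistic f(μ) = 1/(1+e^{−βμ}) is
  available. Identity keeps the cost scale interpretable (mean margin) and
  trains robustly on standardized features.
- **Ω normalization**: after every epoch Ω is rescaled to
  trace(ΩᵀΩ) = 1 (default on, switchable). This fixes the metric's overall
  scale, which is otherwise unidentified, and makes CCMs comparable across
  folds — fold averaging of CCMs presupposes it.
- **Ω initialization**: seeded standard-normal entries, trace-normalized.
  Prototypes initialize as seeded random class-conditional training points.
- **Epochs**: default 100 with early stopping when the epoch cost improves
  by < 1e-6 for 10 consecutive epochs. Learning rates default to 0.01 for
  both prototypes and Ω; Ω adapts from the first epoch (no warm-up).
- **Degenerate cases**: equal winner distances give μ = 0; a sample whose
  correct and incorrect winners both sit exactly at the sample (S = 0)
  contributes no update. Ties in the argmin break toward the lowest
  prototype index. A zero Ω triggers a warning (all distances collapse).
- **CIP sign**: the influence profile is the signed row sum κ_i = Σ_j Λ_ij,
  which can cancel; an absolute-value variant is computed alongside and is
  the default ranking for top-k feature selection, because cancellation can
  hide a feature that is strongly (anti-)correlated with others.

Determinism: identical seeds and inputs give bit-identical models (one RNG
for initialization, one for per-epoch shuffling, both seeded from the model
seed). Models serialize to JSON with exact float round trip.

## Pipeline

Z-scoring uses training-fold statistics only (population standard
deviation; zero-variance columns map to 0) and is applied to held-out data
with those statistics — a leakage test poisons held-out rows and asserts
the trained fold model is unchanged. Cross-validation is stratified 3-fold
by default: with imbalanced corpora (e.g. three classes of 44/90/22
sequences) unstratified folds risk losing a class entirely, so
stratification is the safe default and is switchable. Accuracy is the plain
fraction correct; the reported spread is the standard deviation across
folds. Fold CCMs (already trace-normalized) are averaged element-wise.
Grid search is exhaustive over feature-generator settings; infeasible
points (τ_max or j_max too large for the shortest sequence) are recorded as
failed rather than aborting; ties in mean accuracy break toward the smaller
feature dimension, then the smaller complexity parameter. Fold assignment
and per-fold model seeds are derived independently from one top-level seed.

## Synthetic data generator

The generator exists so every stage is testable on corpora with *known*
correlation structure; it emulates the statistical signal the fingerprints
are designed to detect, not real genomes.

- **Markov corpora**: each class is an order-1 chain; MIF(1) is exactly the
  chain's one-step dependence. The default two-class task contrasts a
  self-persistent chain (diagonal 0.7, off-diagonal 0.1; ≈ 0.64 bits of
  shift-1 mutual information) with an i.i.d. uniform chain — classes that
  differ in correlation *strength*. Differing only by an alphabet
  relabeling would be invisible: mutual information is invariant under
  permutations of the symbol set, a property the generator's defaults
  deliberately respect. An `interleave=p` option weaves p independent
  chains, planting the dependence at shift p and its multiples while
  leaving other shifts uncorrelated — used to verify that grid search
  recovers the planted lag. Defaults: 60 sequences/class, lengths uniform
  80–120, ambiguity injection rate 0.02.
- **Motif corpora**: positives carry 4 planted G-tracts of length 3
  separated by loops of 1–7 non-G residues (an intervening G would merge
  adjacent tracts, as in real quadruplex motifs); negatives are residue
  permutations of independently generated positive-style sequences, so the
  classes match in composition and differ only in positional G structure —
  the signal the G channel of the rMIF resolves and the plain MIF averages
  over the alphabet. Defaults: 60 sequences/class, length 60.
- **Ambiguity injection** replaces a residue with a random degenerate code
  whose set contains it, preserving the underlying nucleotide in
  expectation.

Expected-accuracy bands attached to the ready-made fixtures ([0.9, 1.0] for
both tasks under the default settings) come from seeded calibration runs of
the full pipeline and are checked as band membership, not point values.

What passing on synthetic data does *not* show: robustness to the length
heterogeneity, compositional bias, and long-range structure of real
transcriptomes or viral genomes; the generator has no indel/mutation
process and its ambiguity codes are uniform noise rather than
sequencing-quality artifacts.

## Problem sizes

The test suite and the acceptance script run desk-scale problems chosen as
the package's own reference conditions: 1000 random sequences for the
resolution identity, 500 for the pair-counting oracle, 10 seeded
repetitions for relevance recovery and for the rMIF-vs-MIF comparison, and
60 sequences per class for the end-to-end corpora. All are seeded and
complete in about a minute on one CPU.

## Known limitations

- Plug-in entropy estimation only; no Miller–Madow or jackknife bias
  correction.
- Single-residue (k = 1) statistics; no k-mer generalization of the MIF.
- Cross-MIF between two distinct sequences is out of scope.
- The GLVQ trainer is plain SGD; no minibatching, momentum, or annealing.
- Accuracy is the only built-in performance metric.
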