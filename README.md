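# seqmif

Alignment-free classification of nucleotide sequences from
mutual-information-function fingerprints, with an interpretable
limited-rank matrix LVQ classifier.

## The problem

Comparing DNA/RNA sequences without alignment requires fixed-length
numerical fingerprints that capture the *spatial correlation structure* of a
sequence, not just its composition. `seqmif` implements three such
fingerprint families and a prototype-based classifier that, after training,
tells you *which* features (and which feature pairs) drive the class
decision — useful for tasks like recognizing G-quadruplex-forming sequences,
separating lncRNA from mRNA, or typing viral genomes, where a biologist
wants more than a black-box accuracy number.

## The quantities

**Mutual information function (MIF).** For a sequence over
A = {A, C, G, T}, estimate the joint distribution p(x, x(τ)) of a
nucleotide and the nucleotide τ positions downstream (3′ direction) from the
L − τ available position pairs; marginals are the joint's row/column sums
(non-symmetric convention). The Shannon MIF at shift τ is

    F(X, τ) = Σ_{x, x(τ)} p(x, x(τ)) log₂ [ p(x, x(τ)) / (p(x) p(x(τ))) ],

the information-theoretic analogue of the autocorrelation function. The
**resolved MIF (rMIF)** decomposes it per nucleotide:
F(x, τ) = Σ_{x(τ)} p(x, x(τ)) log₂ [p(x, x(τ)) / (p(x) p(x(τ)))], with
Σ_x F(x, τ) = F(X, τ) exactly. For the Rényi/Tsallis α-generalizations the
shared F-quantity is

    F_α(x, τ) = Σ_{x(τ)} p(x, x(τ))^α / (p(x) p(x(τ)))^{α−1},

with information transforms I_α^R = log₂(F_α)/(α−1) (Rényi) and
I_α^T = (F_α − 1)/(α−1) (Tsallis). Profiles over τ = 1..τ_max give τ_max
(MIF) or 4·τ_max (rMIF) features per sequence.

**Natural vectors (NV).** Per nucleotide k: count n_k, mean position μ_k,
and normalized central moments D_k^j = Σ_i (i−μ_k)^j w_k(s_i) /
(n_k^{j−1} L^{j−1}) for j = 2..j_max — a 4·(j_max+1)-dimensional baseline
fingerprint.

IUPAC ambiguity codes are handled by soft encoding: residue weights
w_k(s_i) code the *probability* of nucleotide k at position i (e.g.
w_A(R) = 1/2, w_A(N) = 1/4), and joint counts use products of weights.

**Classifier.** Generalized matrix LVQ with the mapped distance
d_Ω(x, w) = ‖Ω(x − w)‖², Ω ∈ R^{m×n}, m ≤ n (limited-rank for m < n),
trained by SGD on the GLVQ cost Σ f(μ) with
μ = (d⁺ − d⁻)/(d⁺ + d⁻) ∈ (−1, 1). After training,
**Λ = ΩᵀΩ** is the classification correlation matrix (CCM); its diagonal is
the classification relevance profile (CRP) and its row sums the
classification influence profile (CIP) — the interpretation output.

## Worked example

Generate a synthetic G-tract motif task (positives carry four planted GGG
tracts; negatives are composition-matched shuffles), featurize with the
resolved Rényi MIF, cross-validate, and refit on the seven most influential
features:

```bash
seqmif simulate  --task motif --out-dir demo --n-per-class 60 --seed 1
seqmif featurize --fasta demo/motif_corpus.fasta --labels demo/motif_labels.tsv \
                 --method rmif --family renyi --tau-max 4 --out demo/features.tsv
seqmif crossval  --features demo/features.tsv --seed 1 --out demo/cv
seqmif select    --features demo/features.tsv --top-k 7 --seed 1 --out demo/select.json
```

Output:

```
wrote 120 rows x 16 features to demo/features.tsv
mean accuracy 1.0000 +/- 0.0000 over 3 folds (seed 1)
top-7 refit: 1.0000 (delta +0.0000 vs full 1.0000)
```

The 16 rMIF features (4 nucleotides × shifts 1–4) separate the classes
perfectly in stratified 3-fold CV, and the relevance profile written to
`demo/cv.profiles.tsv` explains why — the G channel at shift 1 carries
essentially all of the relevance:

```
    feature      crp       cip
F_renyi_G_1 0.974535  1.001636
F_renyi_T_1 0.004371  0.025086
F_renyi_C_3 0.004301  0.042819
```

i.e. the model discriminates on the G–G dependence at distance 1, which is
exactly the planted tract structure. The plain (unresolved) MIF averages
this G-specific signal over the alphabet.

The same workflow is available as library calls
(`seqmif.featurize`, `seqmif.cross_validate`, `seqmif.grid_search`,
`seqmif.select_top_features`), and `seqmif gridsearch` tunes τ_max/j_max by
CV accuracy.

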