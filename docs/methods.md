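# Methods

`pplink` implements a two-stage predictor of protein functional linkage:
two proteins are *functionally linked* (related) when they participate in at
least one common metabolic/signalling pathway. Stage 1 screens candidate
pairs by the similarity of their phylogenetic profiles; stage 2 re-ranks the
survivors with a kernel-density classifier over conjoint-triad sequence
features trained on a second organism whose pathway annotations are known.

## Stage 1: real-valued phylogenetic profiles

For a query gene *a* and each reference organism *b*, the S-value `S_ab` is
the best BLAST bit score of *a* against all ORFs of *b*. Because chance
alignments between non-homologues can reach bit scores of about 50, S-values
below 50 are trimmed to zero (strictly: `S < 50 → 0`, so a score of exactly
50 survives). The R-value `R_ab = S_ab / S_aa` normalizes by the
self-alignment score so profiles are comparable across genes of different
length and composition; the ratio is clamped to 1 because a cross-organism
score exceeding the self score is pathological (clamping events are the
caller's signal of upstream alignment problems). The profile of a gene is
the vector of its R-values over the *n* reference organisms.

Per reference organism (matrix column), the non-zero R-values of all genes
are divided by their mean. Without this, a handful of phylogenetically close
organisms with uniformly high R-values would dominate every inner product.
Column normalization is defined over the genes present in the matrix (the
post-filter collection); all-zero columns are left untouched and zero
entries never become non-zero, so the presence/absence pattern is exact.

Pair similarity is the plain inner product of the two normalized profiles —
no cosine normalization — following the finding that the inner product is a
good indicator among the common profile distance functions.

**Non-zero filter.** A profile with fewer than `nz` non-zero entries bases
its similarity on too few organisms, which is as unreliable as using a tiny
reference collection. Stage 1 therefore (i) rejects a pair outright (no
prediction, "n/a") if either profile has fewer than `nz` non-zero elements,
then (ii) keeps pairs with similarity strictly above `sim_threshold`
(default 0: exactly the zero-similarity pairs are discarded). `nz = 0`
passes everything; survivor sets are nested and non-increasing in `nz`.

Order of operations is fixed: trim → R-value → column normalization →
similarity.

## Stage 2: conjoint-triad features + RVKDE

**Features.** The 20 amino acids collapse into 7 groups by dipole strength
and side-chain volume ({A,G,V}, {I,L,F,P}, {Y,M,T,S}, {H,N,Q,W}, {R,K},
{D,E}, {C}). A protein becomes a sequence over the 7 groups and every window
of three consecutive groups is counted into a 343-dimensional occurrence
vector (base-7 positional index, first residue most significant; the index
order is a convention — any bijection works as long as training and
prediction share it). Counts are raw (`Σ o_i = L − 2`), not normalized
frequencies; a config switch enables min-max scaling for experimentation.
A pair is the 686-dim concatenation of its two vectors in lexicographic
gene-id order, making the encoding orientation-free and deterministic.

**Classifier.** The relaxed variable kernel density estimator (RVKDE) builds
one density per class from the training pairs:

    f̂_j(v) = (1/n_j) Σ_{i ∈ kt-NN_j(v)} (2π)^{-m/2} σ_i^{-m} exp(−‖v−s_i‖²/(2σ_i²))

with a per-sample bandwidth driven by R(s_i), the distance from s_i to its
ks-th nearest neighbour within its own class:

    σ_i = β · R(s_i) · √π / ( Γ(m/2+1)^{1/m} · (α·ks)^{1/m} )

The constant comes from the volume of the m-ball, V_m(R) = π^{m/2} R^m /
Γ(m/2+1): the ks-NN ball around s_i is treated as holding `α·ks` samples'
worth of volume, so σ_i is the characteristic per-sample spacing
`(V_m(R)/(α·ks))^{1/m}` rescaled by β. This placement keeps kernels local in
any dimension; the inverted placement (Γ^{1/m}/√π) would inflate σ by
roughly √(m/2πe) — a factor ≈ 6.3 at m = 686 — after which the −m·log σ term
dominates every distance and the classifier degenerates (we measured ranking
AUC 0.60 vs 0.97 on the same data). In 1-D the formula reduces to
σ = 2βR/(α·ks).

Numerical choices:

- **Log-space likelihoods.** At m = 686, σ^{-m} and the kernel exponents
  under/overflow doubles by hundreds of orders of magnitude; all densities
  are computed as log-sum-exp and only exponentiated on demand. Ranking
  scores are the logistic of the log-likelihood difference, so they stay
  informative even when both densities underflow to 0.
- **Bandwidth floor.** Duplicate training vectors (real triad-count vectors
  collide) give R = 0; σ is floored at 1e-9 × the median pairwise distance
  of the class (1 if degenerate).
- **Class-conditional neighbourhoods.** Both R(s_i) and the kt-NN truncation
  are within-class: the densities are per-class objects. kt ≥ n_j recovers
  the full (properly normalized) estimator; truncation only removes terms,
  so the truncated density never exceeds the full one.
- **Neighbour search.** KD-tree for m ≤ 15; above that, blocked BLAS
  (Gram-matrix) brute force — a KD-tree is slower than brute force long
  before the 686-dim triad space.
- **Classification.** L_j(v) = (n_j/n)·f̂_j(v) (empirical prior × density);
  argmax wins, exact ties go to *unrelated* — false positives are the cost a
  precision-oriented evaluation punishes. The ranking score is
  L_related/(L_related+L_unrelated), 0 when both vanish.

**Parameter selection.** α, β, ks, kt are set by stratified 5-fold CV
maximizing the F-measure (grid search; folds from a seeded shuffle; ties
broken by the smaller (ks, kt, β, α)). Default grid: α ∈ {0.5,1,2},
β ∈ {0.5,1,2,4}, ks ∈ {5,10,20}, kt ∈ {20,50,100}. On the synthetic study
the CV objective saturates (F = 1 for many grid points), so the pipeline
protocols use fixed parameters (α=1, β=0.5, ks=5, kt=50); β=0.5 — kernels at
half the characteristic spacing — is the most ranking-robust smoothing level
we observed, and since all protocols share the one model the choice cannot
favour one protocol over another.

β is a genuine smoothing dial: at β = 1 the estimator is deliberately
narrow (kernel ≈ the inter-sample spacing), which is fine for likelihood
*ratios* but visibly undersmooths the density itself. The density-consistency
test therefore runs at β = 40 (σ = 4R at ks = 20), where the 1-D estimate
tracks a standard normal to MAE ≈ 0.03 on [−2, 2]; β ≥ 20 suffices.

## Evaluation protocols

- **Pred_both** — stage-1 survivors re-ranked by RVKDE score (the full
  predictor).
- **Pred_1st** — the same survivors ranked by profile similarity.
- **Pred_2nd** — the RVKDE alone: stratified random samples from the
  non-zero-filter passers with the same positive/negative counts as the
  stage-1 survivors, repeated (default 10×) and the precision@k curves
  averaged pointwise. RVKDE scores do not depend on the sample, so all
  candidates are scored once and repeats only resample and re-rank.

Rankings are descending by score with pair-id lexicographic tie-break, so
every run is reproducible. Metrics: precision among the top k, and the area
under the recall–precision curve up to a target recall r, computed by
trapezoidal integration over the points where a positive is retrieved,
anchored at recall 0 with the first sampled precision and linearly
interpolated to end exactly at r (a perfect ranking gives exactly r; the
step-vs-trapezoid choice is below the precision at which published AUC
tables can distinguish). The adjusted AUC divides by r, the perfect
predictor's AUC. The recall denominator is the number of related pairs in
the full evaluation universe, not just in the ranking.

## The synthetic study

The generator produces the three inputs of a real experiment with the
structure the method assumes, all randomness flowing from one seed
(bundles are bit-reproducible):

- **Co-evolution.** Each of 8 pathways occupies a clade — an independent
  random subset of the 40 reference organisms (inclusion probability
  `clade_fraction` = 0.12) — and each of its 12 member genes inherits the
  clade row with independent cell flips (`presence_noise` = 0.10).
- **Bit scores.** Self scores are uniform on (150, 600); present cells score
  `S_aa ×` a Beta(5, 2) ratio rescaled onto (50/S_aa, 1], so presence always
  survives the trim rule; absent cells are unrecorded except for spurious
  sub-threshold scores in (0, 50) at rate 0.05, which exercise the trim.
- **Sequence signal.** Each pathway draws a distribution over the 7 residue
  groups from Dirichlet(1/`group_bias_strength`) (strength 4; larger →
  sparser, more pathway-specific compositions, the infinite limit collapsing
  a pathway onto one group). Sequences of 150–300 residues are sampled
  residue-by-residue: group from the pathway distribution, residue uniform
  within the group. Lengths below ~150 make compositions too noisy for
  stable classification; 150–300 aa is also the realistic range for pathway
  enzymes.

Two organisms (query and training) share the clade matrix and the pathway
group distributions but draw genes independently, mirroring cross-organism
training without leaking sequences. `clade_fraction` and `presence_noise`
were calibrated so the profile stage operates where published studies place
it: a real filter (~20% of pairs have zero similarity) and an imperfect
ranker (top-100 precision ≈ 0.8–1.0, mean ≈ 0.93), rather than a degenerate
perfect one. `disjoint_clades=True` partitions organisms among pathways,
guaranteeing cross-pathway profiles share no organism; with zero noise this
makes similarity > 0 *exactly* characterize same-pathway pairs (stage-1
precision 1.0), the construction used by the noiseless check.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: actual sequence evolution (no substitution models
or alignments; bit scores are drawn, not computed), homology structure
between pathways, genes in multiple pathways, unbalanced pathway sizes, and
the genome scale of real collections. In particular, with 96 genes per
organism the Pred_2nd quota (matched to stage-1 survivor counts) necessarily
covers most available positives, so Pred_both-vs-Pred_2nd comparisons sit
near ties, unlike the 0.5%-coverage regime of a genome-scale study; the
qualitative ordering (two-stage ≥ each stage) is preserved, the published
margins are not. Scaled-down problem sizes are used throughout (96 genes ×
40 organisms; 10 replicates × 10 sampling repeats), chosen so a full study
runs in well under a minute per replicate on one core.

## Known limitations and open choices

- The 150-nt gene-length filter is applied as a strict inequality
  (`nt_length > 150`); when nucleotide length is unknown, `3×(protein
  length+1)` stands in (coding triplets plus stop) and the substitution is
  logged. Whether the original filter preceded or followed ORF trimming is
  unknowable from the published description; the proxy sidesteps the
  question for protein-only inputs.
- Column normalization uses the genes present in the matrix; if profiles
  are built from a pre-filter gene set the normalization constants differ
  slightly.
- The kt-nearest truncation is within-class; a pooled-set variant would
  change densities near class boundaries. Within-class is the reading
  consistent with per-class density objects.
- Only two classes are supported; the similarity measure is fixed to the
  inner product (binary and quantized profile variants are out of scope).
- BLAST is never executed; the package parses tabular output (outfmt-6
  column layout configurable) and requires a self-score for every gene —
  a missing self score is an error, not a silent skip, because the R-value
  is undefined without it.
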