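# pplink

Two-stage prediction of **protein functional linkage** — whether two
proteins participate in at least one common pathway — for systems-biology
work where a query organism has sequences but sparse annotations.

Phylogenetic profiling exploits evolutionary co-occurrence: genes whose
homologues appear and disappear together across genomes tend to work
together. Profile methods alone, however, degrade on eukaryotes, where
reference collections are small and profiles are zero-heavy. `pplink`
implements a hybrid that keeps profiling's high precision at the top of the
ranking while adding the stability of a sequence-based classifier:

1. **Stage 1 — phylogenetic profiles.** For gene *a* and reference organism
   *b*, the S-value S_ab is the best BLAST bit score of *a* vs all ORFs of
   *b*, trimmed to 0 below 50 (chance-alignment floor), normalized to
   R_ab = S_ab/S_aa by the self-alignment score, and column-normalized so
   each organism's non-zero R-values have mean 1. Pair similarity is the
   inner product of profiles. A **non-zero filter** rejects pairs where
   either profile has fewer than *nz* non-zero entries (similarity resting
   on too few organisms is unreliable); pairs with similarity ≤ threshold
   (default: exactly 0) are dropped.
2. **Stage 2 — conjoint triads + RVKDE.** Surviving pairs are encoded as
   686-dim conjoint-triad count vectors (20 amino acids → 7 physicochemical
   groups; 7³ = 343 triad types per protein, concatenated per pair) and
   ranked by a relaxed variable kernel density estimator: one Gaussian-kernel
   density per class with per-sample bandwidth
   σ_i = β·R(s_i)·√π / (Γ(m/2+1)^{1/m}·(α·ks)^{1/m}), where R(s_i) is the
   distance to the ks-th nearest within-class neighbour, evaluated over the
   kt nearest samples only. A pair's score is
   L_related/(L_related+L_unrelated) with L_j = (n_j/n)·f̂_j.

Evaluation follows the ranked-retrieval protocol: precision@k, AUC of the
recall–precision curve up to a target recall r, and the adjusted AUC (AUC/r,
i.e. relative to a perfect predictor). A seeded synthetic-data module
generates complete, file-backed studies (FASTA, BLAST-tabular hit tables,
pathway memberships) so the whole system is testable offline.

## Worked example

`examples/04_two_stage_pipeline.py` generates the default synthetic study
(8 pathways × 12 genes per organism, 40 reference organisms), trains the
RVKDE on the training organism's labeled pairs and compares the three
protocols on the query organism:

```
query organism : 96 genes, 4560 pairs (528 related)
stage-1 survivors: 3944 pairs

top-k precision:
     k  Pred_both   Pred_1st   Pred_2nd
    25      1.000      0.960      1.000
    50      1.000      0.980      1.000
   100      1.000      0.930      1.000
   250      1.000      0.732      1.000

AUC up to recall 0.05: Pred_both=0.05000 Pred_1st=0.04818 (perfect predictor: 0.05)
adjusted AUC: Pred_both=1.000 Pred_1st=0.964
```

`Pred_both` is the two-stage predictor, `Pred_1st` ranks the same stage-1
survivors by profile similarity alone, `Pred_2nd` is the classifier alone on
quota-matched random samples (averaged over 10 draws). Here the two-stage
ranking is perfect down to rank 250 while similarity alone decays — the
sequence stage repairs the ranking errors that presence/absence noise
induces in the profiles. The other examples walk through profile
construction and the stage-1 filter (01), triad encoding (02) and the RVKDE
on toy Gaussians (03).

A thin CLI covers the shell workflow:

```sh
pplink synth --seed 0 --out bundle/
pplink run --bundle bundle/ --mode both --out ranked.tsv
pplink eval --ranked ranked.tsv
```

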