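"""Build phylogenetic profiles from a tiny hit table and run the stage-1 filter.

Three genes against four reference organisms: g1 and g2 co-occur in the same
two organisms (a co-evolving pair), g3 lives elsewhere, and one of g1's hits
sits below the bit-score trim threshold of 50.
"""

import pplink as pl

hits = pl.HitTable(
    scores={
        ("g1", "orgA"): 180.0, ("g1", "orgB"): 150.0, ("g1", "orgC"): 42.0,
        ("g2", "orgA"): 120.0, ("g2", "orgB"): 200.0,
        ("g3", "orgC"): 160.0, ("g3", "orgD"): 90.0,
    },
    self_scores={"g1": 300.0, "g2": 250.0, "g3": 200.0},
)

matrix = pl.build_profile_matrix(hits, ["g1", "g2", "g3"], ["orgA", "orgB", "orgC", "orgD"])
print("R-values (trimmed, self-normalized):")
for g, row in zip(matrix.gene_ids, matrix.values):
    print(f"  {g}: {[round(float(v), 3) for v in row]}")

matrix = pl.normalize_columns(matrix)
print("after per-organism normalization (non-zero column means = 1):")
for g, row in zip(matrix.gene_ids, matrix.values):
    print(f"  {g}: {[round(float(v), 3) for v in row]}")

pairs = pl.PairSet([("g1", "g2", True), ("g1", "g3", False), ("g2", "g3", False)])
result = pl.stage_one(matrix, pairs, nz=1)
print("\nstage-1 outcome (similarity > 0 and both profiles non-empty):")
print(result.table.to_string(index=False))
print("\nThe co-evolving pair g1-g2 survives with high inner-product "
      "similarity; g1-g3 and g2-g3 share no organism and are filtered.")
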