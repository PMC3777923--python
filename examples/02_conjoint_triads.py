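"""Encode a protein sequence into conjoint-triad counts.

Residues collapse into 7 physicochemical groups; every window of three
consecutive groups is one of 7^3 = 343 triad types.
"""

import numpy as np

import pplink as pl

seq = "MKVAGTCCRKDE"
groups = pl.group_sequence(seq)
print(f"sequence     : {seq}")
print(f"group string : {''.join(map(str, groups))}")

o = pl.occurrence_vector(seq)
print(f"occurrence vector: {o.shape[0]} dims, {int(o.sum())} triads counted "
      f"(= len - 2 = {len(seq) - 2})")
for idx in np.flatnonzero(o):
    triad = tuple(int(g) for g in pl.triad_of_index(int(idx)))
    print(f"  triad {triad} (index {idx}): {int(o[idx])}x")

pair = pl.encode_pair(pl.GeneRecord("yA", seq), pl.GeneRecord("yB", seq[::-1]))
print(f"pair feature vector: {pair.shape[0]} dims "
      "(the two 343-dim vectors concatenated in gene-id order)")
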