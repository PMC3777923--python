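"""Conjoint-triad sequence features.

The 20 amino acids are collapsed into 7 physicochemical groups (dipole
strength and side-chain volume, after Shen et al.), a protein becomes a
sequence over the 7 groups, and every window of three consecutive groups is
counted into a 343-dimensional occurrence vector (7^3 triad types). A protein
pair is the 686-dimensional concatenation of its two occurrence vectors, in
canonical (lexicographic gene-id) order.
"""

from __future__ import annotations

import numpy as np

from .errors import PPLinkError
from .io import GeneRecord

N_TRIADS = 343  # 7**3
PAIR_DIM = 2 * N_TRIADS

#: Amino acid -> group number (1..7).
AA_GROUP: dict[str, int] = {
    "A": 1, "G": 1, "V": 1,
    "I": 2, "L": 2, "F": 2, "P": 2,
    "Y": 3, "M": 3, "T": 3, "S": 3,
    "H": 4, "N": 4, "Q": 4, "W": 4,
    "R": 5, "K": 5,
    "D": 6, "E": 6,
    "C": 7,
}

# Lookup table over ASCII codes for vectorized translation; 0 marks invalid.
_GROUP_LUT = np.zeros(128, dtype=np.int64)
for _aa, _g in AA_GROUP.items():
    _GROUP_LUT[ord(_aa)] = _g


def group_of(residue: str) -> int:
    """Group number (1..7) of a single amino-acid letter."""
    try:
        return AA_GROUP[residue]
    except KeyError:
        raise PPLinkError(f"non-standard residue {residue!r}") from None


def group_sequence(protein_seq: str) -> np.ndarray:
    """Translate a protein sequence into its group sequence (ints in 1..7)."""
    codes = np.frombuffer(protein_seq.encode("ascii"), dtype=np.uint8)
    if (codes >= 128).any():
        raise PPLinkError("non-ASCII character in protein sequence")
    groups = _GROUP_LUT[codes]
    if (groups == 0).any():
        bad = protein_seq[int(np.argmax(groups == 0))]
        raise PPLinkError(f"non-standard residue {bad!r}")
    return groups


def triad_index(g1: int, g2: int, g3: int) -> int:
    """Index of a triad of groups, base-7 positional (first residue most significant)."""
    for g in (g1, g2, g3):
        if not 1 <= g <= 7:
            raise PPLinkError(f"group out of range 1..7: {g}")
    return (g1 - 1) * 49 + (g2 - 1) * 7 + (g3 - 1)


def triad_of_index(i: int) -> tuple[int, int, int]:
    """Inverse of :func:`triad_index`."""
    if not 0 <= i < N_TRIADS:
        raise PPLinkError(f"triad index out of range 0..342: {i}")
    return (i // 49 + 1, (i // 7) % 7 + 1, i % 7 + 1)


def occurrence_vector(protein_seq: str) -> np.ndarray:
    """Count conjoint triads: sliding window of width 3, step 1.

    A length-L sequence contributes max(L - 2, 0) windows, so the counts sum
    to exactly that.
    """
    if len(protein_seq) < 3:
        return np.zeros(N_TRIADS, dtype=np.int64)
    g = group_sequence(protein_seq)
    idx = (g[:-2] - 1) * 49 + (g[1:-1] - 1) * 7 + (g[2:] - 1)
    return np.bincount(idx, minlength=N_TRIADS).astype(np.int64)


def _maybe_normalize(o: np.ndarray, normalize: bool) -> np.ndarray:
    if not normalize:
        return o
    o = o.astype(float)
    span = o.max()
    if span == 0:
        return o
    return (o - o.min()) / span


def encode_pair(
    rec_a: GeneRecord, rec_b: GeneRecord, normalize: bool = False
) -> np.ndarray:
    """686-dim feature vector of a pair, concatenated in canonical id order.

    ``normalize`` switches raw counts to min-max scaled frequencies (off by
    default; the counts themselves are the feature definition here).
    """
    if not rec_a.protein_seq or not rec_b.protein_seq:
        raise PPLinkError("cannot encode a pair with an empty sequence")
    first, second = sorted((rec_a, rec_b), key=lambda r: r.gene_id)
    oa = _maybe_normalize(occurrence_vector(first.protein_seq), normalize)
    ob = _maybe_normalize(occurrence_vector(second.protein_seq), normalize)
    return np.concatenate([oa, ob])


def encode_pairs(
    records: list[GeneRecord],
    pairs,
    normalize: bool = False,
) -> np.ndarray:
    """Feature matrix for many pairs; occurrence vectors are computed once per gene."""
    cache = {
        rec.gene_id: _maybe_normalize(occurrence_vector(rec.protein_seq), normalize)
        for rec in records
    }
    out = np.empty((len(pairs), PAIR_DIM))
    for k, (a, b, *_rest) in enumerate(pairs):
        first, second = (a, b) if a <= b else (b, a)
        out[k, :N_TRIADS] = cache[first]
        out[k, N_TRIADS:] = cache[second]
    return out
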