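"""Real-valued phylogenetic profiles and the stage-1 similarity filter.

A gene's phylogenetic profile is the vector of its R-values across a
reference collection of n organisms: the best BLAST bit score S_ab of gene a
against all ORFs of reference organism b, trimmed to zero below 50 (chance
alignments between non-homologues can reach bit scores of ~50), and
normalized by the self-alignment score S_aa so that profiles are comparable
across genes.  Per reference organism, the non-zero R-values of all genes are
further divided by their mean, preventing a few phylogenetically close
organisms from dominating the inner-product similarity.

Stage 1 keeps a candidate pair only if (i) both profiles have at least ``nz``
non-zero elements (the non-zero reliability filter) and (ii) their inner
product exceeds a similarity threshold (default: strictly positive).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import PPLinkError
from .io import HitTable, PairSet

#: Bit scores below this are treated as chance alignments and trimmed to zero.
TRIM_THRESHOLD = 50.0


@dataclass
class ProfileMatrix:
    """Genes x reference organisms matrix of R-values.

    Before column normalization every value lies in [0, 1]; afterwards the
    non-zero entries of each column have mean 1.
    """

    gene_ids: list[str]
    organism_ids: list[str]
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.organism_ids)):
            raise PPLinkError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.organism_ids)} organisms"
            )
        if (self.values < 0).any():
            raise PPLinkError("profile matrix contains negative values")
        self._row_of = {g: i for i, g in enumerate(self.gene_ids)}

    def row(self, gene_id: str) -> np.ndarray:
        try:
            return self.values[self._row_of[gene_id]]
        except KeyError:
            raise PPLinkError(f"gene {gene_id!r} not in profile matrix") from None


@dataclass
class StageOneResult:
    """Per-pair outcome of the stage-1 filter.

    ``table`` columns: gene_a, gene_b, related (when labels are known),
    similarity (NaN when the pair failed the non-zero filter — no prediction
    is delivered for it), passed_nz, passed_similarity.
    """

    table: pd.DataFrame
    nz: int
    sim_threshold: float

    def survivors(self) -> pd.DataFrame:
        return self.table[self.table["passed_similarity"]].reset_index(drop=True)

    @property
    def n_survivors(self) -> int:
        return int(self.table["passed_similarity"].sum())

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def trim_score(S: float) -> float:
    """Trim an S-value: scores below 50 are indistinguishable from chance."""
    if S < 0:
        raise PPLinkError(f"bit score must be non-negative, got {S}")
    return 0.0 if S < TRIM_THRESHOLD else float(S)


def r_value(S_ab: float, S_aa: float) -> float:
    """Normalize a trimmed S-value by the gene's self-alignment score.

    The ratio is clamped to 1: a cross-organism score exceeding the
    self-score is pathological and would break the documented [0, 1] range.
    """
    if S_aa <= 0:
        raise PPLinkError(f"self score must be positive, got {S_aa}")
    if S_ab < 0:
        raise PPLinkError(f"bit score must be non-negative, got {S_ab}")
    return min(S_ab / S_aa, 1.0)


def build_profile_matrix(
    hits: HitTable,
    genes: list[str],
    organisms: list[str],
    query_org: str | None = None,
    allow_query_in_reference: bool = False,
) -> ProfileMatrix:
    """Assemble the un-normalized R-value matrix from a best-hit table.

    Missing (gene, organism) entries are zeros. The query organism must not
    appear among the reference organisms (profiles describe presence in
    *other* genomes) unless explicitly overridden.
    """
    if query_org is not None and query_org in organisms and not allow_query_in_reference:
        raise PPLinkError(
            f"query organism {query_org!r} is in the reference collection; "
            "pass allow_query_in_reference=True to override"
        )
    missing = [g for g in genes if g not in hits.self_scores]
    if missing:
        raise PPLinkError(f"missing self score for genes: {missing[:10]}")
    values = np.zeros((len(genes), len(organisms)))
    org_index = {o: j for j, o in enumerate(organisms)}
    for gi, g in enumerate(genes):
        s_aa = hits.self_scores[g]
        for org, j in org_index.items():
            s_ab = hits.scores.get((g, org))
            if s_ab is not None:
                values[gi, j] = r_value(trim_score(s_ab), s_aa)
    return ProfileMatrix(
        gene_ids=list(genes), organism_ids=list(organisms), values=values
    )


def normalize_columns(matrix: ProfileMatrix) -> ProfileMatrix:
    """Divide each column's non-zero entries by their mean.

    Zero entries and all-zero columns are untouched, so the zero pattern of
    the matrix is preserved exactly. Applying this twice is an error.
    """
    if matrix.normalized:
        raise PPLinkError("profile matrix is already column-normalized")
    values = matrix.values.copy()
    for j in range(values.shape[1]):
        col = values[:, j]
        nz = col > 0
        if nz.any():
            col[nz] = col[nz] / col[nz].mean()
    return replace(matrix, values=values, normalized=True)


def profile_similarity(p_i: np.ndarray, p_j: np.ndarray) -> float:
    """Inner product of two profiles (both from the same normalized matrix)."""
    p_i = np.asarray(p_i, dtype=float)
    p_j = np.asarray(p_j, dtype=float)
    if p_i.shape != p_j.shape:
        raise PPLinkError(f"profile length mismatch: {p_i.shape} vs {p_j.shape}")
    return float(p_i @ p_j)


def nonzero_filter(p_i: np.ndarray, p_j: np.ndarray, nz: int) -> bool:
    """True iff *both* profiles have at least ``nz`` non-zero elements.

    A profile with few non-zero entries rests its similarity on very few
    organisms, which is as unreliable as using a tiny reference collection;
    ``nz = 0`` passes everything.
    """
    if nz < 0:
        raise PPLinkError(f"nz must be non-negative, got {nz}")
    return (
        int(np.count_nonzero(p_i)) >= nz and int(np.count_nonzero(p_j)) >= nz
    )


def stage_one(
    matrix: ProfileMatrix,
    pairs: PairSet,
    nz: int = 1,
    sim_threshold: float = 0.0,
) -> StageOneResult:
    """Run the stage-1 filter over a set of candidate pairs.

    Pairs failing the non-zero filter get no similarity (n/a). Surviving
    pairs must have similarity strictly above ``sim_threshold`` (the default
    0 discards exactly the zero-similarity pairs).
    """
    if not matrix.normalized:
        raise PPLinkError("stage_one requires a column-normalized matrix")
    n_nonzero = {
        g: int(np.count_nonzero(matrix.row(g))) for g in matrix.gene_ids
    }
    rows = []
    for a, b, related in pairs:
        if a not in n_nonzero or b not in n_nonzero:
            missing = a if a not in n_nonzero else b
            raise PPLinkError(f"gene {missing!r} from pair set not in profile matrix")
        passed_nz = n_nonzero[a] >= nz and n_nonzero[b] >= nz
        if passed_nz:
            sim = profile_similarity(matrix.row(a), matrix.row(b))
            passed_sim = sim > sim_threshold
        else:
            sim = np.nan
            passed_sim = False
        rows.append((a, b, related, sim, passed_nz, passed_sim))
    table = pd.DataFrame(
        rows,
        columns=[
            "gene_a",
            "gene_b",
            "related",
            "similarity",
            "passed_nz",
            "passed_similarity",
        ],
    )
    return StageOneResult(table=table, nz=nz, sim_threshold=sim_threshold)
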