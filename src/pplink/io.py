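"""File formats, dataset filters and pair labeling.

This module reads the external inputs of the predictor — protein FASTA,
BLAST tabular hit files (outfmt 6), pathway membership tables — applies the
dataset filters (minimum gene length, proteinogenic-only sequences, pathway
participation) and derives the positive/negative labels for every unordered
protein pair: two proteins are *related* iff they share at least one pathway.
"""

from __future__ import annotations

import csv
import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import ParseError, PPLinkError

logger = logging.getLogger(__name__)

#: The 20 proteinogenic amino-acid one-letter codes.
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class GeneRecord:
    """One gene/protein of an organism.

    ``nt_length`` is the nucleotide length of the gene when known; when absent,
    length-based filters fall back to ``3 * (protein length + 1)`` (coding
    triplets plus a stop codon).
    """

    gene_id: str
    protein_seq: str
    nt_length: int | None = None
    pathways: set[str] = field(default_factory=set)

    def effective_nt_length(self) -> int:
        if self.nt_length is not None:
            return self.nt_length
        return 3 * (len(self.protein_seq) + 1)


@dataclass
class HitTable:
    """Best BLAST bit score per (query gene, reference organism).

    ``scores[(gene, organism)]`` holds the best bit score of the gene against
    all ORFs of that organism (the S-value before trimming); ``self_scores``
    holds each gene's self-alignment score S_aa.
    """

    scores: dict[tuple[str, str], float] = field(default_factory=dict)
    self_scores: dict[str, float] = field(default_factory=dict)

    def organisms(self) -> list[str]:
        return sorted({org for (_, org) in self.scores})

    def merge_self_scores(self, other: dict[str, float]) -> None:
        """Fill in self scores from a separate self-alignment source."""
        for gene, s in other.items():
            self.self_scores.setdefault(gene, float(s))


@dataclass
class PairSet:
    """All unordered pairs over a set of labeled genes.

    Each element is ``(gene_a, gene_b, related)`` with ``gene_a < gene_b``
    under lexicographic gene-id order (the canonical pair order used by every
    module).
    """

    pairs: list[tuple[str, str, bool]]

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    @property
    def n_related(self) -> int:
        return sum(1 for _, _, rel in self.pairs if rel)

    @property
    def n_unrelated(self) -> int:
        return len(self.pairs) - self.n_related


def read_fasta(path) -> list[GeneRecord]:
    """Read a protein FASTA file into GeneRecords.

    The record id is the first whitespace-delimited header token; sequences
    are uppercased and multi-line bodies concatenated. A file whose first
    non-blank line is not a header is rejected with the line number.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ParseError(
                    "sequence data before any FASTA header", path=path, line=lineno
                )
            break
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        records.append(GeneRecord(gene_id=entry.id, protein_seq=str(entry.seq).upper()))
    return records


@dataclass(frozen=True)
class BlastColumns:
    """0-based column positions in a BLAST tabular file (default outfmt 6)."""

    qseqid: int = 0
    sseqid: int = 1
    bitscore: int = 11


def read_blast_tabular(
    path,
    subject_to_org: dict[str, str],
    query_org: str | None = None,
    columns: BlastColumns = BlastColumns(),
) -> HitTable:
    """Reduce a BLAST tabular file to the best hit per (gene, organism).

    ``subject_to_org`` maps every subject id in the file to its organism.
    Rows where ``qseqid == sseqid`` and the subject belongs to ``query_org``
    (or to any organism, when ``query_org`` is None) populate the
    self-alignment scores S_aa instead of cross-organism entries.
    """
    path = Path(path)
    table = HitTable()
    needed = max(columns.qseqid, columns.sseqid, columns.bitscore) + 1
    with open(path) as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (row[0].startswith("#")):
                continue
            if len(row) < needed:
                raise ParseError(
                    f"expected at least {needed} columns, got {len(row)}",
                    path=path,
                    line=lineno,
                )
            q = row[columns.qseqid].strip()
            s = row[columns.sseqid].strip()
            try:
                bit = float(row[columns.bitscore])
            except ValueError:
                raise ParseError(
                    f"non-numeric bitscore {row[columns.bitscore]!r}",
                    path=path,
                    line=lineno,
                ) from None
            if s not in subject_to_org:
                raise PPLinkError(
                    f"{path}:{lineno}: subject id {s!r} has no organism mapping"
                )
            org = subject_to_org[s]
            if q == s and (query_org is None or org == query_org):
                prev = table.self_scores.get(q, -np.inf)
                table.self_scores[q] = max(prev, bit)
                continue
            key = (q, org)
            prev = table.scores.get(key, -np.inf)
            table.scores[key] = max(prev, bit)
    return table


def read_self_scores(path) -> dict[str, float]:
    """Read a two-column TSV of (gene_id, self bit score)."""
    path = Path(path)
    out: dict[str, float] = {}
    with open(path) as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or not "".join(row).strip():
                continue
            if len(row) != 2:
                raise ParseError(
                    f"expected 2 columns, got {len(row)}", path=path, line=lineno
                )
            try:
                out[row[0].strip()] = float(row[1])
            except ValueError:
                raise ParseError(
                    f"non-numeric self score {row[1]!r}", path=path, line=lineno
                ) from None
    return out


def read_subject_map(path) -> dict[str, str]:
    """Read a two-column TSV mapping subject id -> organism id."""
    path = Path(path)
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or not "".join(row).strip():
                continue
            if len(row) != 2:
                raise ParseError(
                    f"expected 2 columns, got {len(row)}", path=path, line=lineno
                )
            out[row[0].strip()] = row[1].strip()
    return out


def filter_genes(records: list[GeneRecord], min_nt: int = 150) -> list[GeneRecord]:
    """Apply the dataset filters.

    Keeps genes strictly longer than ``min_nt`` nucleotides whose protein
    sequence uses only the 20 proteinogenic residues and that participate in
    at least one pathway. Genes without a recorded nucleotide length use the
    ``3 * (protein length + 1)`` proxy (logged).
    """
    kept = []
    for rec in records:
        if rec.nt_length is None:
            logger.debug(
                "gene %s has no nt_length; using 3*(len+1)=%d",
                rec.gene_id,
                rec.effective_nt_length(),
            )
        if rec.effective_nt_length() <= min_nt:
            continue
        if not rec.protein_seq or set(rec.protein_seq) - STANDARD_RESIDUES:
            continue
        if not rec.pathways:
            continue
        kept.append(rec)
    return kept


def read_pathway_membership(path) -> dict[str, set[str]]:
    """Read a KEGG-style two-column TSV (gene_id, pathway_id) into a mapping."""
    path = Path(path)
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or not "".join(row).strip():
                continue
            if len(row) != 2:
                raise ParseError(
                    f"expected 2 columns, got {len(row)}", path=path, line=lineno
                )
            out.setdefault(row[0].strip(), set()).add(row[1].strip())
    return out


def attach_pathways(
    records: list[GeneRecord], membership: dict[str, set[str]]
) -> list[GeneRecord]:
    """Set each record's pathway set from a membership mapping (missing -> empty)."""
    for rec in records:
        rec.pathways = set(membership.get(rec.gene_id, set()))
    return records


def derive_pair_labels(records: list[GeneRecord]) -> PairSet:
    """Enumerate all C(G,2) unordered pairs and label them.

    A pair is *related* iff the two pathway sets intersect. Pairs are emitted
    in lexicographic canonical order.
    """
    ids = [rec.gene_id for rec in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({g for g in ids if ids.count(g) > 1})
        raise PPLinkError(f"duplicate gene ids: {dupes}")
    by_id = {rec.gene_id: rec for rec in records}
    ordered = sorted(ids)
    pairs = [
        (a, b, bool(by_id[a].pathways & by_id[b].pathways))
        for a, b in itertools.combinations(ordered, 2)
    ]
    return PairSet(pairs=pairs)


def write_profile_matrix(matrix, path) -> None:
    """Write a ProfileMatrix as TSV: header row of organism ids, first column gene ids."""
    df = pd.DataFrame(
        matrix.values, index=matrix.gene_ids, columns=matrix.organism_ids
    )
    df.index.name = "#normalized=%s" % ("1" if matrix.normalized else "0")
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_profile_matrix(path):
    """Read a profile-matrix TSV written by :func:`write_profile_matrix`."""
    from .profiles import ProfileMatrix

    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ParseError(f"malformed profile matrix: {exc}", path=path) from None
    normalized = df.index.name == "#normalized=1"
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ParseError("ragged or non-numeric rows in profile matrix", path=path)
    return ProfileMatrix(
        gene_ids=[str(g) for g in df.index],
        organism_ids=[str(o) for o in df.columns],
        values=values,
        normalized=normalized,
    )
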