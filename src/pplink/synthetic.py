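"""Seeded synthetic data with the structure the two-stage predictor assumes.

The generator emulates the three inputs of a real experiment:

- *co-evolution*: each pathway occupies a clade — a random subset of the
  reference organisms — and every member gene inherits that presence row,
  flipped cell-wise with a small noise probability;
- *bit scores*: present (gene, organism) cells get a best bit score drawn as
  a Beta-distributed fraction of the gene's self score, supported above the
  trim threshold of 50; absent cells are zero, except for occasional
  sub-threshold spurious scores in (0, 50) that the trim rule must remove;
- *sequence signal*: each pathway carries its own distribution over the 7
  residue groups, and member sequences are sampled residue by residue from
  it, so conjoint-triad composition is informative about pathway membership.

Two organisms (query and training) are generated from the *shared* pathway
structure with independent gene-level draws, mirroring cross-organism
training without leaking identical sequences. All randomness flows from the
single config seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .errors import PPLinkError
from .io import GeneRecord, HitTable, PairSet, derive_pair_labels
from .pipeline import Bundle
from .profiles import build_profile_matrix, normalize_columns

_GROUP_RESIDUES = ["AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C"]


@dataclass
class SynthConfig:
    """Study conditions for a synthetic bundle.

    ``group_bias_strength`` concentrates each pathway's residue-group
    distribution: the distribution is Dirichlet(1/strength) over the 7
    groups, so larger values give sparser, more pathway-specific
    compositions (the infinite limit collapses each pathway onto a single
    group). ``disjoint_clades`` partitions the reference organisms among
    pathways instead of drawing independent clades, which guarantees
    cross-pathway profiles share no organism.
    """

    n_pathways: int = 8
    genes_per_pathway: int = 12
    n_reference_organisms: int = 40
    clade_fraction: float = 0.12
    presence_noise: float = 0.10
    selfscore_range: tuple[float, float] = (150.0, 600.0)
    hit_ratio_shape: tuple[float, float] = (5.0, 2.0)  # Beta(a, b), rescaled
    subthreshold_rate: float = 0.05
    group_bias_strength: float = 4.0
    seq_length_range: tuple[int, int] = (150, 300)
    disjoint_clades: bool = False
    seed: int = 0

    def __post_init__(self):
        for p in (self.clade_fraction, self.presence_noise, self.subthreshold_rate):
            if not 0 <= p <= 1:
                raise PPLinkError(f"probability out of [0, 1]: {p}")
        if self.selfscore_range[0] > self.selfscore_range[1]:
            raise PPLinkError("selfscore_range must be ordered")
        if self.seq_length_range[0] > self.seq_length_range[1]:
            raise PPLinkError("seq_length_range must be ordered")
        if self.selfscore_range[0] <= 50:
            raise PPLinkError("self scores must exceed the trim threshold of 50")
        if self.group_bias_strength <= 0:
            raise PPLinkError("group_bias_strength must be positive")

    @property
    def n_genes(self) -> int:
        return self.n_pathways * self.genes_per_pathway

    def pathway_ids(self) -> list[str]:
        return [f"P{i:02d}" for i in range(self.n_pathways)]

    def organism_ids(self) -> list[str]:
        return [f"org{j:02d}" for j in range(self.n_reference_organisms)]


def pathway_presence(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Pathway x organism clade matrix."""
    shape = (config.n_pathways, config.n_reference_organisms)
    if config.disjoint_clades:
        pres = np.zeros(shape, dtype=bool)
        orgs = rng.permutation(config.n_reference_organisms)
        for p, chunk in enumerate(np.array_split(orgs, config.n_pathways)):
            pres[p, chunk] = True
        return pres
    return rng.random(shape) < config.clade_fraction


def gene_presence(
    pathway_matrix: np.ndarray, assignments: np.ndarray, config: SynthConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-gene presence rows: the pathway row with independent cell flips."""
    rows = pathway_matrix[assignments]
    flips = rng.random(rows.shape) < config.presence_noise
    return rows ^ flips


def generate_presence(config: SynthConfig, rng: np.random.Generator | None = None):
    """Clade matrix, gene->pathway assignments and noisy gene presence rows."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pathway_matrix = pathway_presence(config, rng)
    assignments = np.repeat(np.arange(config.n_pathways), config.genes_per_pathway)
    genes = gene_presence(pathway_matrix, assignments, config, rng)
    return pathway_matrix, assignments, genes


def generate_hit_table(
    presence: np.ndarray,
    gene_ids: list[str],
    config: SynthConfig,
    rng: np.random.Generator,
) -> HitTable:
    """Bit scores consistent with a presence matrix.

    Present cells score S_aa * ratio with ratio ~ Beta(a, b) rescaled onto
    (50/S_aa, 1], so every present cell survives the trim rule; absent cells
    are unrecorded, or spurious sub-threshold scores in (0, 50) that the
    trim rule removes.
    """
    lo, hi = config.selfscore_range
    a, b = config.hit_ratio_shape
    orgs = config.organism_ids()
    table = HitTable()
    for gi, gene in enumerate(gene_ids):
        s_aa = float(rng.uniform(lo, hi))
        table.self_scores[gene] = s_aa
        for oj, org in enumerate(orgs):
            if presence[gi, oj]:
                low = 50.0 / s_aa
                ratio = low + (1.0 - low) * float(rng.beta(a, b))
                # keep strictly above the trim threshold
                ratio = max(ratio, np.nextafter(low, 1.0))
                table.scores[(gene, org)] = s_aa * ratio
            elif rng.random() < config.subthreshold_rate:
                table.scores[(gene, org)] = float(rng.uniform(0.0, 50.0))
    return table


def group_distributions(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """One distribution over the 7 residue groups per pathway."""
    alpha = np.full(7, 1.0 / config.group_bias_strength)
    return rng.dirichlet(alpha, size=config.n_pathways)


def generate_sequences(
    assignments: np.ndarray,
    group_dists: np.ndarray,
    gene_ids: list[str],
    config: SynthConfig,
    rng: np.random.Generator,
) -> list[GeneRecord]:
    """Sample protein sequences residue by residue from pathway group biases."""
    lo, hi = config.seq_length_range
    pathway_ids = config.pathway_ids()
    records = []
    for gid, p in zip(gene_ids, assignments):
        length = int(rng.integers(lo, hi + 1))
        groups = rng.choice(7, size=length, p=group_dists[p])
        seq = "".join(
            _GROUP_RESIDUES[g][rng.integers(len(_GROUP_RESIDUES[g]))] for g in groups
        )
        records.append(
            GeneRecord(
                gene_id=gid,
                protein_seq=seq,
                nt_length=3 * (length + 1),
                pathways={pathway_ids[int(p)]},
            )
        )
    return records


def expected_positive_fraction(config: SynthConfig) -> float:
    """Exact combinatorial fraction of related pairs in one organism."""
    g, k = config.n_genes, config.genes_per_pathway
    return config.n_pathways * math.comb(k, 2) / math.comb(g, 2)


@dataclass
class Organism:
    """One generated organism: records, labels and (for the query) hit data."""

    organism_id: str
    records: list[GeneRecord]
    pairs: PairSet
    hits: HitTable
    presence: np.ndarray


def _generate_organism(
    org_id: str,
    pathway_matrix: np.ndarray,
    group_dists: np.ndarray,
    config: SynthConfig,
    rng: np.random.Generator,
) -> Organism:
    assignments = np.repeat(np.arange(config.n_pathways), config.genes_per_pathway)
    gene_ids = [f"{org_id}_g{k:03d}" for k in range(config.n_genes)]
    presence = gene_presence(pathway_matrix, assignments, config, rng)
    hits = generate_hit_table(presence, gene_ids, config, rng)
    records = generate_sequences(assignments, group_dists, gene_ids, config, rng)
    pairs = derive_pair_labels(records)
    return Organism(
        organism_id=org_id, records=records, pairs=pairs, hits=hits, presence=presence
    )


def generate_bundle(config: SynthConfig, out_dir=None) -> Bundle:
    """Generate a full query + training bundle (optionally written to disk).

    The pathway clade matrix and the pathway group distributions are shared
    between the two organisms; gene-level presence flips, bit scores and
    sequences are independent draws.
    """
    root = np.random.SeedSequence(config.seed)
    rng_shared, rng_query, rng_train = (
        np.random.default_rng(s) for s in root.spawn(3)
    )
    pathway_matrix = pathway_presence(config, rng_shared)
    group_dists = group_distributions(config, rng_shared)
    query = _generate_organism("query", pathway_matrix, group_dists, config, rng_query)
    train = _generate_organism("train", pathway_matrix, group_dists, config, rng_train)
    matrix = build_profile_matrix(
        query.hits,
        genes=[r.gene_id for r in query.records],
        organisms=config.organism_ids(),
        query_org="query",
    )
    bundle = Bundle(
        query_records=query.records,
        query_pairs=query.pairs,
        profile=normalize_columns(matrix),
        train_records=train.records,
        train_pairs=train.pairs,
        manifest={"config": asdict(config), "seed": config.seed},
    )
    if out_dir is not None:
        _write_bundle(bundle, query, train, config, Path(out_dir))
    return bundle


# --- on-disk form ------------------------------------------------------------

def _write_fasta(records: list[GeneRecord], path: Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.gene_id} nt_length={rec.effective_nt_length()}\n")
            seq = rec.protein_seq
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def _write_membership(records: list[GeneRecord], path: Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            for p in sorted(rec.pathways):
                fh.write(f"{rec.gene_id}\t{p}\n")


def _write_hits(org: Organism, config: SynthConfig, path: Path, map_path: Path) -> None:
    """BLAST outfmt-6-shaped TSV plus the subject -> organism mapping."""
    with open(map_path, "w") as fh:
        for o in config.organism_ids():
            fh.write(f"{o}|orf\t{o}\n")
        for rec in org.records:
            fh.write(f"{rec.gene_id}\t{org.organism_id}\n")
    filler = "100.0\t0\t0\t0\t0\t0\t0\t0\t0.0"  # pident..evalue placeholders
    with open(path, "w") as fh:
        for gene, s in sorted(org.hits.self_scores.items()):
            fh.write(f"{gene}\t{gene}\t{filler}\t{s:.17g}\n")
        for (gene, o), s in sorted(org.hits.scores.items()):
            fh.write(f"{gene}\t{o}|orf\t{filler}\t{s:.17g}\n")


def _write_bundle(
    bundle: Bundle, query: Organism, train: Organism, config: SynthConfig, out: Path
) -> None:
    out.mkdir(parents=True, exist_ok=True)
    for org in (query, train):
        tag = org.organism_id
        _write_fasta(org.records, out / f"{tag}.faa")
        _write_membership(org.records, out / f"{tag}.pathways.tsv")
        _write_hits(org, config, out / f"{tag}.hits.tsv", out / f"{tag}.subjects.tsv")
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, default=str)


def load_bundle(in_dir) -> Bundle:
    """Rebuild a bundle from files written by :func:`generate_bundle`."""
    from . import io as pio

    in_dir = Path(in_dir)
    with open(in_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    cfg_dict = dict(manifest["config"])
    for key in ("selfscore_range", "hit_ratio_shape", "seq_length_range"):
        cfg_dict[key] = tuple(cfg_dict[key])
    config = SynthConfig(**cfg_dict)
    organisms = {}
    for tag in ("query", "train"):
        records = pio.read_fasta(in_dir / f"{tag}.faa")
        membership = pio.read_pathway_membership(in_dir / f"{tag}.pathways.tsv")
        pio.attach_pathways(records, membership)
        for rec in records:
            rec.nt_length = 3 * (len(rec.protein_seq) + 1)
        subject_map = pio.read_subject_map(in_dir / f"{tag}.subjects.tsv")
        hits = pio.read_blast_tabular(
            in_dir / f"{tag}.hits.tsv", subject_map, query_org=tag
        )
        organisms[tag] = (pio.filter_genes(records), hits)
    q_records, q_hits = organisms["query"]
    matrix = build_profile_matrix(
        q_hits,
        genes=[r.gene_id for r in q_records],
        organisms=config.organism_ids(),
        query_org="query",
    )
    t_records, _ = organisms["train"]
    return Bundle(
        query_records=q_records,
        query_pairs=derive_pair_labels(q_records),
        profile=normalize_columns(matrix),
        train_records=t_records,
        train_pairs=derive_pair_labels(t_records),
        manifest=manifest,
    )
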