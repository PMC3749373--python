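"""Homolog discovery, filtering, orthology by bidirectional best hits,
and gene-family assembly.

The search engine is a seed-gated local aligner: a query/subject pair is
considered only when the two sequences share an exact nucleotide word
(default 11-mer, the classic BLASTN word size), and the alignment itself is
a full Smith–Waterman local alignment with BLASTN-like scoring
(match +2, mismatch -3, affine gaps 5/2) computed by Biopython's pairwise
aligner.  E-values follow the Karlin–Altschul formula
``E = K * m * n * exp(-lambda * score)`` with configurable constants.
Users with real BLAST output can instead load hits from the standard
12-column tabular format.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd
from Bio import Align, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# ---------------------------------------------------------------------------
# domain types


@dataclass
class CodingSequence:
    """One coding sequence with optional genomic placement.

    ``order_index`` is the 1-based rank of the gene on its chromosome; it is
    the only positional information the downstream tandem-duplication
    detector uses.
    """

    id: str
    species: str
    nucleotides: str
    chromosome: str | None = None
    order_index: int | None = None

    def __post_init__(self):
        if not self.nucleotides:
            raise ValueError(f"empty sequence for {self.id}")
        if self.order_index is not None and self.order_index < 1:
            raise ValueError(f"order_index must be >= 1 for {self.id}")

    def __len__(self) -> int:
        return len(self.nucleotides)


@dataclass
class HomologyHit:
    """One pairwise similarity record, mirroring 12-column tabular output."""

    query_id: str
    subject_id: str
    pct_identity: float
    align_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float


@dataclass
class GeneFamily:
    family_id: str
    member_ids: list[str]
    species_present: set[str] = field(default_factory=set)
    anchor_ids: list[str] = field(default_factory=list)


@dataclass
class SearchConfig:
    """Scoring and statistics for the nucleotide search."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    seed_length: int = 11
    karlin_lambda: float = 0.625
    karlin_k: float = 0.41
    include_self: bool = False
    #: pairs whose fast edit-distance bound exceeds this divergence are not
    #: aligned or reported (they cannot approach the homology band); set to
    #: 1.0 to disable the pre-screen
    prescreen_max_divergence: float = 0.4


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path, species: str) -> list[CodingSequence]:
    return [
        CodingSequence(id=rec.id, species=species, nucleotides=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(sequences: list[CodingSequence], path) -> None:
    records = [
        SeqRecord(Seq(cds.nucleotides), id=cds.id, description="")
        for cds in sequences
    ]
    SeqIO.write(records, str(path), "fasta")


HIT_COLUMNS = [
    "query_id",
    "subject_id",
    "pct_identity",
    "align_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "e_value",
    "bit_score",
]


def read_hits_tsv(path) -> list[HomologyHit]:
    """Read hits from 12-column tab-separated format (BLAST outfmt-6 order)."""
    df = pd.read_csv(path, sep="\t", header=None, names=HIT_COLUMNS, comment="#")
    return [HomologyHit(**row) for row in df.to_dict("records")]


def write_hits_tsv(hits: list[HomologyHit], path) -> None:
    df = pd.DataFrame([vars(h) for h in hits], columns=HIT_COLUMNS)
    df.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def read_positions_tsv(path) -> pd.DataFrame:
    """Read the 4-column gene position table (id, species, chromosome, order_index)."""
    df = pd.read_csv(path, sep="\t")
    expected = {"id", "species", "chromosome", "order_index"}
    if not expected.issubset(df.columns):
        raise ValueError(f"positions table must have columns {sorted(expected)}")
    return df


GFF3_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


def read_gff3_positions(path, species: str, feature_type: str = "gene") -> pd.DataFrame:
    """Derive gene order from a GFF3 file.

    Gene features are ranked per seqid by their (1-based, inclusive) start
    coordinate; the rank becomes ``order_index``.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=GFF3_COLUMNS, comment="#", dtype=str
    )
    genes = df[df["type"] == feature_type].copy()
    genes["start"] = genes["start"].astype(int)

    def _gene_id(attrs: str) -> str:
        for part in attrs.split(";"):
            if part.startswith("ID="):
                return part[3:]
        return attrs

    genes["id"] = genes["attributes"].map(_gene_id)
    genes = genes.sort_values(["seqid", "start"], kind="mergesort")
    genes["order_index"] = genes.groupby("seqid").cumcount() + 1
    out = genes[["id", "seqid", "order_index"]].rename(columns={"seqid": "chromosome"})
    out.insert(1, "species", species)
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# search


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _make_aligner(config: SearchConfig) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = config.match
    aligner.mismatch_score = config.mismatch
    # a gap of length g costs gap_open + gap_extend * g
    aligner.open_gap_score = -(config.gap_open + config.gap_extend)
    aligner.extend_gap_score = -config.gap_extend
    return aligner


def _gap_opens(alignment) -> int:
    opens = 0
    for coords in (alignment.aligned[0], alignment.aligned[1]):
        for (prev, nxt) in zip(coords[:-1], coords[1:]):
            if prev[1] != nxt[0]:
                opens += 1
    return opens


def all_vs_all_search(
    db: list[CodingSequence],
    queries: list[CodingSequence],
    config: SearchConfig | None = None,
) -> list[HomologyHit]:
    """Local-alignment search of every query against a sequence collection.

    The db may mix species; Karlin–Altschul search-space sizes use the
    query length (m) and the summed length of the db sequences belonging to
    the subject's species (n).  Pairs sharing no exact seed word yield no
    hit.  Self-hits (identical ids) are excluded unless configured.

    Because the Smith–Waterman stage dominates the cost, each unordered
    sequence pair is aligned once and reused for both directions, and pairs
    whose fast edit-distance divergence bound exceeds the configured
    pre-screen level (far outside the homology band) are skipped.
    """
    if not db:
        raise ValueError("empty database")
    if not queries:
        raise ValueError("empty query set")
    config = config or SearchConfig()
    aligner = _make_aligner(config)

    db_kmers = {cds.id: _kmer_set(cds.nucleotides, config.seed_length) for cds in db}
    species_db_len: dict[str, int] = {}
    for cds in db:
        species_db_len[cds.species] = species_db_len.get(cds.species, 0) + len(cds)

    # (id_a, id_b) sorted -> alignment summary in that orientation, or None
    cache: dict[tuple[str, str], tuple | None] = {}
    seqs: dict[str, str] = {}
    for cds in list(db) + list(queries):
        seqs[cds.id] = cds.nucleotides

    def summarize(first_id: str, second_id: str):
        """Align the ordered pair (first, second); None when no local hit."""
        alignments = aligner.align(seqs[first_id], seqs[second_id])
        if len(alignments) == 0:
            return None
        aln = alignments[0]
        if aln.score <= 0:
            return None
        counts = aln.counts()
        align_length = counts.gaps + counts.identities + counts.mismatches
        if align_length == 0:
            return None
        f_blocks, s_blocks = aln.aligned
        return (
            float(aln.score),
            counts.identities,
            counts.mismatches,
            align_length,
            _gap_opens(aln),
            (int(f_blocks[0][0]) + 1, int(f_blocks[-1][1])),
            (int(s_blocks[0][0]) + 1, int(s_blocks[-1][1])),
        )

    def pair_summary(query_id: str, subject_id: str):
        key = tuple(sorted((query_id, subject_id)))
        if key not in cache:
            cache[key] = summarize(*key)
        summary = cache[key]
        if summary is None or key == (query_id, subject_id):
            return summary
        score, ident, mism, length, gopen, span_a, span_b = summary
        return (score, ident, mism, length, gopen, span_b, span_a)

    def prescreened_out(a: str, b: str) -> bool:
        if config.prescreen_max_divergence >= 1.0:
            return False
        import edlib

        shorter, longer = sorted((seqs[a], seqs[b]), key=len)
        res = edlib.align(shorter, longer, mode="HW", task="distance")
        return res["editDistance"] / len(shorter) > config.prescreen_max_divergence

    hits: list[HomologyHit] = []
    for query in queries:
        q_kmers = _kmer_set(query.nucleotides, config.seed_length)
        for subject in db:
            if subject.id == query.id and not config.include_self:
                continue
            if not (q_kmers & db_kmers[subject.id]):
                continue
            if prescreened_out(query.id, subject.id):
                continue
            summary = pair_summary(query.id, subject.id)
            if summary is None:
                continue
            score, identities, mismatches, align_length, gap_opens, q_span, s_span = summary
            m = len(query)
            n = species_db_len[subject.species]
            e_value = config.karlin_k * m * n * math.exp(-config.karlin_lambda * score)
            bit_score = (config.karlin_lambda * score - math.log(config.karlin_k)) / math.log(2)
            hits.append(
                HomologyHit(
                    query_id=query.id,
                    subject_id=subject.id,
                    pct_identity=100.0 * identities / align_length,
                    align_length=align_length,
                    mismatches=mismatches,
                    gap_opens=gap_opens,
                    q_start=q_span[0],
                    q_end=q_span[1],
                    s_start=s_span[0],
                    s_end=s_span[1],
                    e_value=e_value,
                    bit_score=bit_score,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# filtering, orthology, families


def filter_hits(
    hits: list[HomologyHit],
    min_identity: float = 70.0,
    max_e: float = 1e-50,
) -> list[HomologyHit]:
    """Keep hits with identity >= min_identity and E-value <= max_e.

    Both boundaries are inclusive; input order is preserved.
    """
    if not (math.isfinite(min_identity) and math.isfinite(max_e)):
        raise ValueError("thresholds must be finite")
    return [
        h for h in hits if h.pct_identity >= min_identity and h.e_value <= max_e
    ]


def bidirectional_best_hits(
    hits: list[HomologyHit],
    species_of: dict[str, str],
) -> list[tuple[str, str]]:
    """Reciprocal best hits between species.

    ``(a, b)`` is reported iff b is a's best hit among hits into
    species(b) and a is b's best hit among hits into species(a).  Best is
    the highest bit score; ties break by lower E-value, then higher percent
    identity, then lexicographically smaller subject id.  Output pairs are
    order-normalized, deduplicated and sorted.
    """
    for h in hits:
        for gid in (h.query_id, h.subject_id):
            if gid not in species_of:
                raise KeyError(f"id {gid!r} missing from species mapping")

    best: dict[tuple[str, str], str] = {}
    best_key: dict[tuple[str, str], tuple] = {}
    for h in hits:
        sp = species_of[h.subject_id]
        if sp == species_of[h.query_id]:
            continue
        key = (h.query_id, sp)
        rank = (-h.bit_score, h.e_value, -h.pct_identity, h.subject_id)
        if key not in best or rank < best_key[key]:
            best[key] = h.subject_id
            best_key[key] = rank

    pairs = set()
    for (query, _sp), subject in best.items():
        back = best.get((subject, species_of[query]))
        if back == query:
            pairs.add(tuple(sorted((query, subject))))
    return sorted(pairs)


def _default_species_of(gene_id: str) -> str:
    return gene_id.split("_", 1)[0]


def cluster_families(
    anchor_ids: list[str],
    hits: list[HomologyHit],
    species_of: dict[str, str] | None = None,
) -> list[GeneFamily]:
    """Assemble gene families as connected components of the filtered hit graph.

    Each family is the component containing an anchor gene; anchors falling
    in the same component are merged into a single family carrying all
    anchor labels.  Anchors with no passing hits become singleton families.
    """
    graph = nx.Graph()
    graph.add_nodes_from(anchor_ids)
    for h in hits:
        graph.add_edge(h.query_id, h.subject_id)

    component_of = {}
    for comp in nx.connected_components(graph):
        comp = frozenset(comp)
        for node in comp:
            component_of[node] = comp

    families = []
    seen: set[frozenset] = set()
    for anchor in anchor_ids:
        comp = component_of.get(anchor, frozenset({anchor}))
        if comp in seen:
            continue
        seen.add(comp)
        anchors = sorted(a for a in anchor_ids if a in comp)
        members = sorted(comp)
        if species_of is not None:
            species = {species_of[m] for m in members}
        else:
            species = {_default_species_of(m) for m in members}
        families.append(
            GeneFamily(
                family_id="+".join(anchors),
                member_ids=members,
                species_present=species,
                anchor_ids=anchors,
            )
        )
    return families


def select_qualifying_genes(
    families: list[GeneFamily],
    min_species: int = 4,
    total_species: int = 6,
) -> list[GeneFamily]:
    """Keep families whose homologs span at least ``min_species`` species."""
    if min_species > total_species:
        raise ValueError(
            f"min_species {min_species} exceeds total_species {total_species}"
        )
    return [f for f in families if len(f.species_present) >= min_species]
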