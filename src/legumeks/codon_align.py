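"""Codon-aware pairwise and progressive multiple alignment.

Coding sequences are aligned in amino-acid space (BLOSUM62, affine gaps)
and back-translated, so every gap run has a length divisible by three and
codon frames are preserved.  The progressive aligner builds a guide tree
from k-mer distances and merges profiles leaf-to-root through their
consensus translations.  Complete deletion masks whole codon columns in
which any row carries a gap or an ambiguous nucleotide; all downstream
distance and rate estimation uses only the surviving columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from . import _codons
from .homology import CodingSequence

#: amino-acid-space gap penalties (Clustal-like defaults)
GAP_OPEN = 10.0
GAP_EXTEND = 0.5

_VALID_NT = frozenset("ACGT")


@dataclass
class MultipleAlignment:
    """Gapped rows over {A,C,G,T,-}; ``kept_columns`` is set by
    :func:`complete_deletion` and lists nucleotide column indices that are
    gap- and ambiguity-free in every row (always whole codons)."""

    ids: list[str]
    rows: list[str]
    kept_columns: list[int] | None = None

    def __post_init__(self):
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows must have equal length")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must correspond")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, index: int) -> str:
        return self.rows[index].replace("-", "")

    def row_for(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]


def _coding_parts(seq) -> tuple[str, str]:
    """(id, nucleotides) from a CodingSequence or plain string."""
    if isinstance(seq, CodingSequence):
        return seq.id, seq.nucleotides.upper()
    return "seq", str(seq).upper()


def translate_cds(nucleotides: str) -> str:
    """Amino-acid translation; trailing stop trimmed, internal stop is an error."""
    codons = _codons.split_codons(nucleotides)
    codons = _codons.check_no_internal_stop(codons, allow_trailing=True)
    return "".join(_codons.translate_codon(c) for c in codons)


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -GAP_OPEN
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


def _back_translate(aa_row: str, codons: list[str]) -> str:
    out = []
    i = 0
    for aa in aa_row:
        if aa == "-":
            out.append("---")
        else:
            out.append(codons[i])
            i += 1
    return "".join(out)


def align_pair_codon_aware(a, b) -> MultipleAlignment:
    """Global codon-respecting alignment of two coding sequences.

    The alignment is computed on the translations and back-translated, so
    gaps always come in multiples of three.  Trailing stop codons are
    trimmed; internal stops raise with the offending codon index.
    """
    id_a, nt_a = _coding_parts(a)
    id_b, nt_b = _coding_parts(b)
    if id_a == id_b:
        id_a, id_b = f"{id_a}.1", f"{id_b}.2"
    codons_a = _codons.check_no_internal_stop(_codons.split_codons(nt_a))
    codons_b = _codons.check_no_internal_stop(_codons.split_codons(nt_b))
    prot_a = "".join(_codons.translate_codon(c) for c in codons_a)
    prot_b = "".join(_codons.translate_codon(c) for c in codons_b)
    aln = _protein_aligner().align(prot_a, prot_b)[0]
    row_a = _back_translate(str(aln[0]), codons_a)
    row_b = _back_translate(str(aln[1]), codons_b)
    return MultipleAlignment(ids=[id_a, id_b], rows=[row_a, row_b])


# ---------------------------------------------------------------------------
# progressive multiple alignment


def _kmer_distance(a: str, b: str, k: int = 4) -> float:
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def _guide_tree_order(seqs: list[str]) -> list[tuple[int, int]]:
    """UPGMA-style agglomeration order over k-mer distances.

    Returns merge operations on cluster indices; clusters are numbered
    0..n-1 for leaves and then n, n+1, ... for merged nodes.
    """
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _kmer_distance(seqs[i], seqs[j])
    active = {i: [i] for i in range(n)}
    dist = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    merges = []
    next_id = n
    while len(active) > 1:
        (i, j) = min(dist, key=lambda ij: (dist[ij], ij))
        merges.append((i, j))
        members = active[i] + active[j]
        del active[i], active[j]
        new_dists = {}
        for k_ in active:
            pairs = [d[p, q] for p in members for q in active[k_]]
            new_dists[tuple(sorted((k_, next_id)))] = float(np.mean(pairs))
        dist = {
            ij: v for ij, v in dist.items() if i not in ij and j not in ij
        }
        dist.update(new_dists)
        active[next_id] = members
        next_id += 1
    return merges


def _consensus_protein(rows: list[str]) -> str:
    """Majority codon translation per codon column; all-gap columns -> X."""
    n_cols = len(rows[0]) // 3
    out = []
    for c in range(n_cols):
        codons = [r[3 * c : 3 * c + 3] for r in rows]
        codons = [cd for cd in codons if "-" not in cd and set(cd) <= _VALID_NT]
        if not codons:
            out.append("X")
            continue
        values, counts = np.unique(codons, return_counts=True)
        best = values[np.argmax(counts)]
        aa = _codons.translate_codon(best)
        out.append("X" if aa == "*" else aa)
    return "".join(out)


def _merge_profiles(
    rows_a: list[str], rows_b: list[str]
) -> tuple[list[str], list[str]]:
    cons_a = _consensus_protein(rows_a)
    cons_b = _consensus_protein(rows_b)
    aln = _protein_aligner().align(cons_a, cons_b)[0]
    gapped_a, gapped_b = str(aln[0]), str(aln[1])

    def expand(rows: list[str], gapped: str) -> list[str]:
        out = []
        for row in rows:
            pieces = []
            i = 0
            for aa in gapped:
                if aa == "-":
                    pieces.append("---")
                else:
                    pieces.append(row[3 * i : 3 * i + 3])
                    i += 1
            out.append("".join(pieces))
        return out

    return expand(rows_a, gapped_a), expand(rows_b, gapped_b)


def progressive_msa(members: list) -> MultipleAlignment:
    """Progressive codon-aware multiple alignment.

    Guide tree from pairwise nucleotide k-mer distances; profiles are merged
    leaf-to-root by aligning their consensus translations.  Row order in the
    output follows the input order of ``members``.
    """
    if not members:
        raise ValueError("no sequences to align")
    parts = [_coding_parts(m) for m in members]
    ids = [p[0] for p in parts]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids in alignment input")
    seqs = [p[1] for p in parts]
    for seq_id, nt in zip(ids, seqs):
        _codons.check_no_internal_stop(_codons.split_codons(nt))
    if len(members) == 1:
        warnings.warn("single-member family returned unaligned", stacklevel=2)
        return MultipleAlignment(ids=ids, rows=[seqs[0]])

    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [seqs[i]]) for i in range(len(seqs))
    }
    next_id = len(seqs)
    for (i, j) in _guide_tree_order(seqs):
        idx_a, rows_a = clusters.pop(i)
        idx_b, rows_b = clusters.pop(j)
        rows_a, rows_b = _merge_profiles(rows_a, rows_b)
        clusters[next_id] = (idx_a + idx_b, rows_a + rows_b)
        next_id += 1
    (indices, rows) = next(iter(clusters.values()))
    ordered = [None] * len(seqs)
    for pos, row in zip(indices, rows):
        ordered[pos] = row
    return MultipleAlignment(ids=ids, rows=ordered)


def complete_deletion(msa: MultipleAlignment) -> MultipleAlignment:
    """Mask codon columns containing any gap or ambiguous nucleotide.

    Removal is by whole codons so downstream site counting stays
    codon-consistent.  Raises when no codon column survives.
    """
    n_codon_cols = msa.n_columns // 3
    kept: list[int] = []
    for c in range(n_codon_cols):
        cols = range(3 * c, 3 * c + 3)
        ok = all(
            row[i] in _VALID_NT for row in msa.rows for i in cols
        )
        if ok:
            kept.extend(cols)
    if not kept:
        raise ValueError(
            "complete deletion removed every codon column; the alignment has "
            "no gap-free codon positions"
        )
    return MultipleAlignment(ids=list(msa.ids), rows=list(msa.rows), kept_columns=kept)


def alignment_stats(msa: MultipleAlignment):
    """Per-row alignment statistics (length, gaps, kept fraction)."""
    import pandas as pd

    n_cols = msa.n_columns
    kept = len(msa.kept_columns) if msa.kept_columns is not None else None
    rows = []
    for seq_id, row in zip(msa.ids, msa.rows):
        gaps = row.count("-")
        rows.append(
            {
                "id": seq_id,
                "columns": n_cols,
                "ungapped_length": n_cols - gaps,
                "gaps": gaps,
                "kept_columns": kept,
                "kept_fraction": kept / n_cols if kept is not None else None,
            }
        )
    return pd.DataFrame(rows)


def write_aligned_fasta(msa: MultipleAlignment, path) -> None:
    with open(path, "w") as fh:
        for seq_id, row in zip(msa.ids, msa.rows):
            fh.write(f">{seq_id}\n{row}\n")


def read_aligned_fasta(path) -> MultipleAlignment:
    ids, rows = [], []
    current = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                ids.append(line[1:].split()[0])
                if current:
                    rows.append("".join(current))
                current = []
            elif line:
                current.append(line)
    if current:
        rows.append("".join(current))
    return MultipleAlignment(ids=ids, rows=rows)
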