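"""Genetic-code lookup tables shared by the rate estimator and the simulator.

Everything here is derived once from the standard nuclear genetic code
(NCBI table 1) and cached at module level: per-codon synonymous site
fractions, the list of single-nucleotide neighbours of each codon, and
pathway-averaged difference counts for codon pairs.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

from Bio.Data.CodonTable import standard_dna_table

NUCLEOTIDES = "ACGT"

#: codon -> amino acid (one letter), stop codons absent
CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a sense codon; '*' for a stop."""
    if codon in STOP_CODONS:
        return "*"
    try:
        return CODON_TO_AA[codon]
    except KeyError:
        raise ValueError(f"invalid codon {codon!r}") from None


def codon_neighbors(codon: str) -> list[tuple[int, str, str]]:
    """All nine single-nucleotide mutations of a codon.

    Returns tuples ``(position, replacement_nt, mutated_codon)``; stop-codon
    products are included (callers filter as appropriate).
    """
    out = []
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            mutated = codon[:pos] + nt + codon[pos + 1 :]
            out.append((pos, nt, mutated))
    return out


@lru_cache(maxsize=None)
def site_fractions(codon: str) -> tuple[float, float]:
    """Nei–Gojobori synonymous/nonsynonymous site counts (S, N) of one codon.

    Per codon position the synonymous fraction is the share of the single
    nucleotide alternatives that preserve the amino acid, with alternatives
    leading to a stop codon removed from both numerator and denominator.
    N is defined as ``3 - S`` with the same denominator convention, so the
    per-codon counts always sum to 3.
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} has no site counts")
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            mutated = codon[:pos] + nt + codon[pos + 1 :]
            if mutated in STOP_CODONS:
                continue
            valid += 1
            if CODON_TO_AA[mutated] == aa:
                syn += 1
        if valid:
            s += syn / valid
    return s, 3.0 - s


@lru_cache(maxsize=None)
def pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous difference counts (sd, nd) for a codon pair.

    Codons differing at k positions are connected by k! orderings of
    single-step mutational paths; sd and nd are averaged over the paths that
    avoid stop codons.  When every path crosses a stop, the k direct
    differences are all counted as nonsynonymous (the conservative reading
    of an unresolvable pathway).
    """
    if codon_a in STOP_CODONS or codon_b in STOP_CODONS:
        raise ValueError("difference counting is undefined for stop codons")
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    k = len(diff_positions)
    if k == 0:
        return 0.0, 0.0
    total_sd = total_nd = 0.0
    n_paths = 0
    for order in itertools.permutations(diff_positions):
        current = codon_a
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
                break
            if CODON_TO_AA[current] == CODON_TO_AA[nxt]:
                sd += 1
            else:
                nd += 1
            current = nxt
        if not blocked:
            total_sd += sd
            total_nd += nd
            n_paths += 1
    if n_paths == 0:
        return 0.0, float(k)
    return total_sd / n_paths, total_nd / n_paths


def split_codons(sequence: str) -> list[str]:
    """Split a CDS string into codons, validating length and characters."""
    if len(sequence) % 3 != 0:
        raise ValueError(
            f"sequence length {len(sequence)} is not divisible by 3"
        )
    seq = sequence.upper()
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    return codons


def check_no_internal_stop(codons: list[str], allow_trailing: bool = True) -> list[str]:
    """Raise if an internal stop codon is present; optionally trim a trailing stop."""
    if allow_trailing and codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    for idx, codon in enumerate(codons):
        if codon in STOP_CODONS:
            raise ValueError(f"internal stop codon {codon} at codon index {idx}")
    return codons
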