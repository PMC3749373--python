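"""Pairwise sequence distances and synonymous/nonsynonymous rates.

Implements Nei–Gojobori (1986) counting on codon-aware alignments:
synonymous and nonsynonymous site counts per sequence, pathway-averaged
difference counts per codon pair, and Jukes–Cantor-corrected per-site rates
Ks and Ka, together with the plain nucleotide p-distance and its corrected
variant d.  All estimators operate only on the alignment columns that
survive complete deletion (no gaps or ambiguity in any row).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import pandas as pd

from . import _codons

#: fewer compared codons than this raises by default; the limit exists because
#: NG86 proportions on a handful of codons are dominated by sampling noise.
DEFAULT_MIN_CODONS = 10


@dataclass
class PairwiseRates:
    """Evolutionary rate estimates for one pair of coding sequences.

    ``ks`` / ``ka`` are substitutions per synonymous / nonsynonymous site
    after Jukes–Cantor correction; they are ``None`` when the corresponding
    proportion is saturated (log argument <= 0).  ``ka_ks`` is ``None``
    whenever Ka or Ks is undefined or Ks is zero.
    """

    id_a: str
    id_b: str
    p_dist: float
    d: float | None
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    ks: float | None
    ka: float | None
    ka_ks: float | None
    saturated_s: bool
    saturated_n: bool
    n_codons: int

    def as_dict(self) -> dict:
        return {
            "id_a": self.id_a,
            "id_b": self.id_b,
            "p_dist": self.p_dist,
            "d": self.d,
            "S": self.s_sites,
            "N": self.n_sites,
            "Sd": self.sd,
            "Nd": self.nd,
            "Ks": self.ks,
            "Ka": self.ka,
            "ka_ks": self.ka_ks,
            "saturated_s": self.saturated_s,
            "saturated_n": self.saturated_n,
            "n_codons": self.n_codons,
        }


def p_distance(row_a: str, row_b: str, kept_columns) -> float:
    """Proportion of differing nucleotide positions over the kept columns."""
    cols = list(kept_columns)
    if not cols:
        raise ValueError("no compared positions: kept_columns is empty")
    diffs = sum(1 for i in cols if row_a[i] != row_b[i])
    return diffs / len(cols)


def jukes_cantor(p: float) -> float | None:
    """JC69 distance d = -(3/4) ln(1 - (4/3) p); None when saturated."""
    if p == 0.0:
        return 0.0
    arg = 1.0 - (4.0 / 3.0) * p
    if arg <= 0.0:
        return None
    return -0.75 * math.log(arg)


def count_sites(codons: list[str]) -> tuple[float, float]:
    """NG86 synonymous and nonsynonymous site counts (S, N) of one sequence."""
    s = n = 0.0
    for codon in codons:
        cs, cn = _codons.site_fractions(codon)
        s += cs
        n += cn
    return s, n


def count_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous differences of a codon pair."""
    return _codons.pathway_differences(codon_a, codon_b)


def _kept_codons(row: str, kept_columns) -> list[str]:
    cols = sorted(kept_columns)
    if len(cols) % 3 != 0:
        raise ValueError("kept_columns must cover whole codons")
    return ["".join(row[c] for c in cols[i : i + 3]) for i in range(0, len(cols), 3)]


def ng86(
    row_a: str,
    row_b: str,
    kept_columns=None,
    *,
    id_a: str = "a",
    id_b: str = "b",
    min_codons: int = DEFAULT_MIN_CODONS,
) -> PairwiseRates:
    """Nei–Gojobori rates for one aligned, gap-masked sequence pair.

    ``kept_columns`` defaults to every column (the rows must then be gap
    free).  Proportions use the mean site counts of the two sequences:
    ps = sum(sd)/mean(S), pn = sum(nd)/mean(N), each corrected with the
    Jukes–Cantor transform on its own scale.
    """
    if kept_columns is None:
        kept_columns = range(len(row_a))
    codons_a = _kept_codons(row_a, kept_columns)
    codons_b = _kept_codons(row_b, kept_columns)
    n_codons = len(codons_a)
    if n_codons < min_codons:
        raise ValueError(
            f"only {n_codons} compared codons; at least {min_codons} required "
            "(pass min_codons to relax)"
        )
    s_a, n_a = count_sites(codons_a)
    s_b, n_b = count_sites(codons_b)
    s_mean = (s_a + s_b) / 2.0
    n_mean = (n_a + n_b) / 2.0
    sd = nd = 0.0
    n_diff_nt = 0
    for ca, cb in zip(codons_a, codons_b):
        csd, cnd = count_differences(ca, cb)
        sd += csd
        nd += cnd
        n_diff_nt += sum(1 for x, y in zip(ca, cb) if x != y)

    ps = sd / s_mean if s_mean > 0 else 0.0
    pn = nd / n_mean if n_mean > 0 else 0.0
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    saturated_s = ks is None
    saturated_n = ka is None
    ka_ks = None
    if ks is not None and ka is not None and ks > 0:
        ka_ks = ka / ks

    cols = sorted(kept_columns)
    p = p_distance(row_a, row_b, cols)
    return PairwiseRates(
        id_a=id_a,
        id_b=id_b,
        p_dist=p,
        d=jukes_cantor(p),
        s_sites=s_mean,
        n_sites=n_mean,
        sd=sd,
        nd=nd,
        ks=ks,
        ka=ka,
        ka_ks=ka_ks,
        saturated_s=saturated_s,
        saturated_n=saturated_n,
        n_codons=n_codons,
    )


def compute_all_pairs(
    msa,
    *,
    species_of: dict[str, str] | None = None,
    family_id: str | None = None,
    min_codons: int = DEFAULT_MIN_CODONS,
) -> pd.DataFrame:
    """Rates for every unordered pair of rows in a multiple alignment.

    ``msa`` is any object with ``ids``, ``rows`` and ``kept_columns``
    attributes (see :mod:`legumeks.codon_align`).  Returns one record per
    unordered pair, symmetric by construction.
    """
    if len(msa.ids) < 2:
        raise ValueError("need at least two rows to form pairs")
    records = []
    for (i, ida), (j, idb) in itertools.combinations(enumerate(msa.ids), 2):
        rates = ng86(
            msa.rows[i],
            msa.rows[j],
            msa.kept_columns,
            id_a=ida,
            id_b=idb,
            min_codons=min_codons,
        )
        rec = rates.as_dict()
        if family_id is not None:
            rec["family"] = family_id
        if species_of is not None:
            rec["species_a"] = species_of[ida]
            rec["species_b"] = species_of[idb]
        records.append(rec)
    df = pd.DataFrame(records)
    lead = [c for c in ("family", "id_a", "id_b", "species_a", "species_b") if c in df]
    return df[lead + [c for c in df.columns if c not in lead]]


def write_rates_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_rates_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
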