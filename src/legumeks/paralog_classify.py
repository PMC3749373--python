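"""Ortholog / inparalog / outparalog labelling and tandem detection.

A within-family gene pair is classified from three signals: whether the two
genes share a species, which side of the gene tree's two-cluster partition
each falls on, and the synonymous divergence Ks.  Same-species pairs inside
one cluster are inparalogs (duplication after speciation); pairs split
across clusters, or same-species pairs with deep Ks when no partition
exists, are outparalogs (duplication before speciation); cross-species
pairs in one cluster are orthologs.  Tandem arrangement is approximated by
gene-order adjacency on the same chromosome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

#: same-species pairs above this Ks are called outparalogs when the tree
#: offers only a single cluster; sits between the speciation-peak scale
#: (~0.4) and the outparalog average (~0.5)
DEFAULT_KS_OUTPARALOG_THRESHOLD = 0.40

RELATIONS = ("ortholog", "inparalog", "outparalog")


@dataclass
class ClassifiedPair:
    id_a: str
    id_b: str
    relation: str
    tandem: bool
    same_species: bool
    same_cluster: bool | None
    ks: float | None
    order_gap: int | None

    def __post_init__(self):
        if self.relation not in RELATIONS:
            raise ValueError(f"unknown relation {self.relation!r}")
        if not self.same_species and self.relation == "inparalog":
            raise ValueError("cross-species pairs cannot be inparalogs")
        if self.same_species and self.relation == "ortholog":
            raise ValueError("same-species pairs cannot be orthologs")


def classify_pair(
    *,
    id_a: str,
    id_b: str,
    same_species: bool,
    same_cluster: bool | None,
    ks: float | None,
    ks_outparalog_threshold: float = DEFAULT_KS_OUTPARALOG_THRESHOLD,
    tandem: bool = False,
    order_gap: int | None = None,
) -> ClassifiedPair:
    """Label one pair.

    ``same_cluster`` is None when the gene tree offered no two-cluster
    partition; in that case same-species pairs fall back to the Ks
    threshold.  A pair with neither cluster evidence nor Ks is an error.
    """
    if same_cluster is None and ks is None:
        raise ValueError(
            f"pair ({id_a}, {id_b}): no cluster partition and no defined Ks"
        )
    if same_cluster is not None:
        if same_species:
            relation = "inparalog" if same_cluster else "outparalog"
        else:
            relation = "ortholog" if same_cluster else "outparalog"
    else:
        if same_species:
            relation = (
                "outparalog" if ks > ks_outparalog_threshold else "inparalog"
            )
        else:
            relation = "ortholog"
    return ClassifiedPair(
        id_a=id_a,
        id_b=id_b,
        relation=relation,
        tandem=tandem,
        same_species=same_species,
        same_cluster=same_cluster,
        ks=ks,
        order_gap=order_gap,
    )


def detect_tandem(
    pairs: list[tuple[str, str]],
    positions: dict[str, tuple[str, str | None, int | None]],
    max_order_gap: int = 1,
) -> dict[tuple[str, str], tuple[bool, int | None]]:
    """Tandem flags for id pairs.

    ``positions`` maps id -> (species, chromosome, order_index).  A pair is
    tandem when both genes share species and chromosome and their gene-order
    indices differ by at most ``max_order_gap``.  Pairs with missing
    positional data are flagged False with a warning.
    """
    flags = {}
    for a, b in pairs:
        key = tuple(sorted((a, b)))
        pa, pb = positions.get(a), positions.get(b)
        if pa is None or pb is None or pa[1] is None or pb[1] is None or \
                pa[2] is None or pb[2] is None:
            warnings.warn(
                f"missing position for pair ({a}, {b}); tandem set to False",
                stacklevel=2,
            )
            flags[key] = (False, None)
            continue
        gap = abs(pa[2] - pb[2])
        tandem = pa[0] == pb[0] and pa[1] == pb[1] and gap <= max_order_gap
        flags[key] = (tandem, gap)
    return flags


def classify_family(
    rates: pd.DataFrame,
    partition: list[set[str]] | None,
    species_of: dict[str, str],
    positions: dict[str, tuple[str, str | None, int | None]] | None = None,
    *,
    ks_outparalog_threshold: float = DEFAULT_KS_OUTPARALOG_THRESHOLD,
    max_order_gap: int = 1,
) -> pd.DataFrame:
    """Classify every pair in one family's rates table.

    ``partition`` is the one- or two-set output of
    :func:`legumeks.nj_phylo.split_two_clusters`; ``positions`` feeds tandem
    detection (no positions -> all tandem flags False).
    """
    cluster_of: dict[str, int] | None = None
    if partition is not None and len(partition) == 2:
        cluster_of = {}
        for idx, side in enumerate(partition):
            for tip in side:
                cluster_of[tip] = idx

    pair_ids = [(row.id_a, row.id_b) for row in rates.itertuples()]
    if positions:
        tandem_flags = detect_tandem(pair_ids, positions, max_order_gap)
    else:
        tandem_flags = {tuple(sorted(p)): (False, None) for p in pair_ids}

    records = []
    for row in rates.itertuples():
        a, b = row.id_a, row.id_b
        same_species = species_of[a] == species_of[b]
        same_cluster = None
        if cluster_of is not None and a in cluster_of and b in cluster_of:
            same_cluster = cluster_of[a] == cluster_of[b]
        ks = None if pd.isna(row.Ks) else float(row.Ks)
        tandem, gap = tandem_flags[tuple(sorted((a, b)))]
        cp = classify_pair(
            id_a=a,
            id_b=b,
            same_species=same_species,
            same_cluster=same_cluster,
            ks=ks,
            ks_outparalog_threshold=ks_outparalog_threshold,
            tandem=tandem,
            order_gap=gap,
        )
        records.append(
            {
                "id_a": min(a, b),
                "id_b": max(a, b),
                "relation": cp.relation,
                "tandem": cp.tandem,
                "same_species": cp.same_species,
                "same_cluster": cp.same_cluster,
                "Ks": cp.ks,
                "order_gap": cp.order_gap,
            }
        )
    return pd.DataFrame(records)


def evaluate_against_truth(
    classified: pd.DataFrame, truth: pd.DataFrame
) -> dict:
    """Confusion summary of predicted vs true pair relations.

    Pairs are joined on order-normalized (id_a, id_b).  Returns overall
    accuracy, per-relation precision/recall, and tandem-flag accuracy when
    both tables carry tandem columns.
    """
    def normalized(df):
        df = df.copy()
        lo = df[["id_a", "id_b"]].min(axis=1)
        hi = df[["id_a", "id_b"]].max(axis=1)
        df["pair"] = list(zip(lo, hi))
        return df

    c = normalized(classified)
    t = normalized(truth)
    merged = c.merge(t, on="pair", suffixes=("_pred", "_true"))
    if merged.empty:
        raise ValueError("no shared pairs between classification and truth")

    pred = merged["relation_pred"]
    true = merged["relation_true"]
    summary: dict = {
        "n_pairs": int(len(merged)),
        "accuracy": float((pred == true).mean()),
        "per_relation": {},
    }
    for rel in RELATIONS:
        tp = int(((pred == rel) & (true == rel)).sum())
        fp = int(((pred == rel) & (true != rel)).sum())
        fn = int(((pred != rel) & (true == rel)).sum())
        summary["per_relation"][rel] = {
            "precision": tp / (tp + fp) if tp + fp else None,
            "recall": tp / (tp + fn) if tp + fn else None,
            "support": tp + fn,
        }
    if "tandem_pred" in merged and "tandem_true" in merged:
        summary["tandem_accuracy"] = float(
            (merged["tandem_pred"].astype(bool) == merged["tandem_true"].astype(bool)).mean()
        )
    return summary
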