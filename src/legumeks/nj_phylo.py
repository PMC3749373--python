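"""Neighbor-joining gene trees, codon bootstrap supports, and the
one-vs-two-cluster partition used to separate orthologs from outparalogs.

The NJ agglomeration follows the standard Q-criterion with a deterministic
tie-break (smallest active index pair) and clamps negative estimated branch
lengths to zero.  Bootstrap resampling draws codon columns (not single
nucleotides) with replacement, so the coding structure of the data is
respected.  The partition rule formalizes the visual one-vs-two-cluster
reading of a gene tree: the longest internal edge splits the tree when its
bootstrap support passes a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import evol_rates

#: distance assigned to a saturated (undefined) Jukes-Cantor estimate
SATURATION_CAP = 5.0


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape must match ids")
        if not np.all(np.isfinite(v)):
            raise ValueError("distance matrix must be finite")
        if np.any(v < 0):
            raise ValueError("distance matrix must be non-negative")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix must have a zero diagonal")
        self.values = v


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class GeneTree:
    """Unrooted tree represented with a (usually trifurcating) root node."""

    root: TreeNode
    partition: list[set[str]] | None = None

    @property
    def tip_names(self) -> list[str]:
        return sorted(leaf.name for leaf in self.root.leaves())

    # -- splits ------------------------------------------------------------

    def _split_key(self, tips_below: set[str]) -> frozenset:
        all_tips = set(self.tip_names)
        ref = min(all_tips)
        side = tips_below if ref not in tips_below else all_tips - tips_below
        return frozenset(side)

    def internal_edges(self) -> list[tuple[TreeNode, frozenset]]:
        """Internal (non-trivial) edges as (child node, normalized split)."""
        all_tips = set(self.tip_names)
        out = []

        def walk(node: TreeNode):
            for child in node.children:
                below = {leaf.name for leaf in child.leaves()}
                if 2 <= len(below) <= len(all_tips) - 2:
                    out.append((child, self._split_key(below)))
                walk(child)

        walk(self.root)
        return out

    def split_keys(self) -> set[frozenset]:
        return {key for _node, key in self.internal_edges()}

    # -- newick ------------------------------------------------------------

    def newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = "" if node.support is None else f"{node.support:g}"
            return f"({inner}){label}:{node.length:.6f}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"


def read_newick(text: str) -> GeneTree:
    """Parse newick (supports stored as internal node labels)."""
    import dendropy

    dtree = dendropy.Tree.get(
        data=text, schema="newick", suppress_internal_node_taxa=True
    )

    def convert(dnode) -> TreeNode:
        name = dnode.taxon.label.replace(" ", "_") if dnode.taxon else None
        support = None
        if dnode.label is not None and not dnode.is_leaf():
            try:
                support = float(dnode.label)
            except ValueError:
                support = None
        return TreeNode(
            name=name,
            length=float(dnode.edge.length or 0.0),
            support=support,
            children=[convert(c) for c in dnode.child_nodes()],
        )

    return GeneTree(root=convert(dtree.seed_node))


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(dm: DistanceMatrix) -> GeneTree:
    """Neighbor joining on the Q-criterion.

    Deterministic: among equal Q values the smallest active index pair is
    joined.  Negative branch-length estimates are clamped to zero.  The
    final three lineages are joined at a trifurcating root using the
    three-point formulas, giving an unrooted tree; two taxa yield a single
    edge split evenly.
    """
    n = len(dm.ids)
    if n < 2:
        raise ValueError("need at least two taxa")
    nodes = [TreeNode(name=i) for i in dm.ids]
    if n == 2:
        d = dm.values[0, 1]
        for node in nodes:
            node.length = d / 2.0
        return GeneTree(root=TreeNode(children=nodes))

    d = dm.values.copy()
    active = list(range(n))
    all_nodes = {i: nodes[i] for i in range(n)}
    next_id = n
    d_store = {(min(i, j), max(i, j)): d[i, j] for i in range(n) for j in range(n) if i < j}

    def dist(i, j):
        return d_store[(min(i, j), max(i, j))] if i != j else 0.0

    while len(active) > 3:
        m = len(active)
        r = {i: sum(dist(i, k) for k in active if k != i) for i in active}
        best = None
        best_q = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * dist(i, j) - r[i] - r[j]
                if best_q is None or q < best_q:
                    best_q, best = q, (i, j)
        i, j = best
        dij = dist(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        node_i, node_j = all_nodes[i], all_nodes[j]
        node_i.length = max(li, 0.0)
        node_j.length = max(lj, 0.0)
        parent = TreeNode(children=[node_i, node_j])
        all_nodes[next_id] = parent
        for k in active:
            if k in (i, j):
                continue
            d_store[(min(k, next_id), max(k, next_id))] = 0.5 * (
                dist(i, k) + dist(j, k) - dij
            )
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    a, b, c = active
    la = 0.5 * (dist(a, b) + dist(a, c) - dist(b, c))
    lb = 0.5 * (dist(a, b) + dist(b, c) - dist(a, c))
    lc = 0.5 * (dist(a, c) + dist(b, c) - dist(a, b))
    for k, lk in zip((a, b, c), (la, lb, lc)):
        all_nodes[k].length = max(lk, 0.0)
    root = TreeNode(children=[all_nodes[a], all_nodes[b], all_nodes[c]])
    return GeneTree(root=root)


# ---------------------------------------------------------------------------
# distances from alignments


def _encoded_columns(msa) -> tuple[np.ndarray, int]:
    """Kept columns of an alignment as a (n_rows, n_cols) uint8 array."""
    cols = msa.kept_columns
    if cols is None:
        raise ValueError("alignment has no kept_columns; run complete_deletion")
    arr = np.array(
        [[ord(row[i]) for i in cols] for row in msa.rows], dtype=np.uint8
    )
    return arr, len(cols)


def distance_matrix_from_msa(msa, model: str = "jc") -> DistanceMatrix:
    """Pairwise p- or JC-corrected distances over the kept columns."""
    arr, _ = _encoded_columns(msa)
    return _distance_matrix_from_array(msa.ids, arr, model)


def _distance_matrix_from_array(ids, arr: np.ndarray, model: str) -> DistanceMatrix:
    n = arr.shape[0]
    values = np.zeros((n, n))
    for i in range(n):
        diff = (arr[i + 1 :] != arr[i]).mean(axis=1)
        for off, p in enumerate(diff):
            j = i + 1 + off
            if model == "p":
                dv = p
            else:
                dv = evol_rates.jukes_cantor(float(p))
                if dv is None:
                    dv = SATURATION_CAP
            values[i, j] = values[j, i] = dv
    return DistanceMatrix(ids=list(ids), values=values)


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_supports(
    msa,
    n_replicates: int = 1000,
    seed: int | None = None,
    model: str = "jc",
) -> GeneTree:
    """NJ tree with bootstrap supports from codon-column resampling.

    Codon columns of the complete-deletion mask are resampled with
    replacement; each replicate rebuilds the distance matrix and NJ tree,
    and support is the percentage of replicates containing each internal
    split of the tree built on the original columns.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    arr, n_cols = _encoded_columns(msa)
    if n_cols % 3 != 0:
        raise ValueError("kept_columns must cover whole codons")
    n_codons = n_cols // 3

    tree = nj_tree(_distance_matrix_from_array(msa.ids, arr, model))
    edges = tree.internal_edges()
    counts = {key: 0 for _node, key in edges}
    if len(msa.ids) >= 4 and counts:
        codon_view = arr.reshape(arr.shape[0], n_codons, 3)
        for _ in range(n_replicates):
            draw = rng.integers(0, n_codons, size=n_codons)
            rep = codon_view[:, draw, :].reshape(arr.shape[0], n_cols)
            rep_tree = nj_tree(_distance_matrix_from_array(msa.ids, rep, model))
            for key in rep_tree.split_keys():
                if key in counts:
                    counts[key] += 1
    for node, key in edges:
        node.support = 100.0 * counts[key] / n_replicates
    return tree


# ---------------------------------------------------------------------------
# cluster partition


def split_two_clusters(
    tree: GeneTree,
    min_support: float = 50.0,
    species_of: dict[str, str] | None = None,
) -> list[set[str]]:
    """One- or two-cluster partition of a gene tree.

    The candidate split is the longest internal edge (ties: higher support,
    then lexicographically smallest tip set).  It is accepted when its
    support reaches ``min_support`` and either both sides hold at least two
    tips or the split separates a same-species duplicate pair.
    """
    all_tips = set(tree.tip_names)
    edges = tree.internal_edges()
    if not edges:
        tree.partition = [all_tips]
        return tree.partition

    def sort_key(item):
        node, key = item
        support = node.support if node.support is not None else 0.0
        return (-node.length, -support, tuple(sorted(key)))

    node, key = min(edges, key=sort_key)
    side_a = set(key)
    side_b = all_tips - side_a

    if species_of is None:
        species_of = {t: t.split("_", 1)[0] for t in all_tips}
    spans_duplicate = bool(
        {species_of[t] for t in side_a} & {species_of[t] for t in side_b}
    )
    support_ok = node.support is None or node.support >= min_support
    size_ok = (len(side_a) >= 2 and len(side_b) >= 2) or spans_duplicate
    if support_ok and size_ok:
        tree.partition = sorted([side_a, side_b], key=lambda s: tuple(sorted(s)))
    else:
        tree.partition = [all_tips]
    return tree.partition


def write_distance_tsv(dm: DistanceMatrix, path) -> None:
    import pandas as pd

    pd.DataFrame(dm.values, index=dm.ids, columns=dm.ids).to_csv(path, sep="\t")
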