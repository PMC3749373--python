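"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive results by brute force (explicit
dynamic programming, recursive path enumeration, exhaustive scans) so the
package implementations are checked against an independent route.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings as _hsettings

from legumeks import _codons

_hsettings.register_profile("suite", deadline=None, derandomize=True)
_hsettings.load_profile("suite")

# ---------------------------------------------------------------------------
# oracle: affine-gap global alignment score on protein strings


def nw_affine_score(a: str, b: str, matrix, gap_open: float, gap_extend: float) -> float:
    """Plain Needleman–Wunsch with affine gaps (Gotoh three-state DP).

    Gap of length g costs gap_open + gap_extend * (g - 1) in the Biopython
    convention (open charged on the first gapped residue).
    """
    neg = -1e30
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in b (a consumed)
    Y = np.full((n + 1, m + 1), neg)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - gap_extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend)
            Y[i, j] = max(M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend)
    return float(max(M[n, m], X[n, m], Y[n, m]))


# ---------------------------------------------------------------------------
# oracle: codon mutational-path enumeration


def enumerate_codon_paths(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Recursive enumeration of single-step mutational paths between codons,
    averaging synonymous/nonsynonymous step counts over stop-free paths."""
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    results = []

    def recurse(current: str, remaining: list[int], sd: float, nd: float):
        if not remaining:
            results.append((sd, nd))
            return
        for pos in remaining:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if _codons.is_stop(nxt):
                continue
            syn = _codons.translate_codon(current) == _codons.translate_codon(nxt)
            recurse(
                nxt,
                [p for p in remaining if p != pos],
                sd + (1 if syn else 0),
                nd + (0 if syn else 1),
            )

    recurse(codon_a, diff, 0.0, 0.0)
    if not results:
        return 0.0, float(len(diff))
    arr = np.array(results)
    return float(arr[:, 0].mean()), float(arr[:, 1].mean())


# ---------------------------------------------------------------------------
# oracle: random additive trees and their path metrics


def random_additive_tree(rng: np.random.Generator, n_tips: int):
    """Random unrooted binary tree as nested structure with positive branch
    lengths; returns (tips, distance_matrix) of its exact path metric."""
    # grow by splitting random edges of a 3-star
    # edges: dict id -> (a, b, length); nodes are ints, tips carry names
    next_node = n_tips
    edges = {}
    center = next_node
    next_node += 1
    for t in range(3):
        edges[t] = (t, center, rng.uniform(0.1, 1.0))
    eid = 3
    for t in range(3, n_tips):
        split = rng.choice(list(edges))
        a, b, ln = edges.pop(split)
        mid = next_node
        next_node += 1
        f = rng.uniform(0.2, 0.8)
        edges[eid] = (a, mid, ln * f)
        edges[eid + 1] = (mid, b, ln * (1 - f))
        edges[eid + 2] = (t, mid, rng.uniform(0.1, 1.0))
        eid += 3

    # path metric by BFS over adjacency
    adj: dict[int, list[tuple[int, float]]] = {}
    for a, b, ln in edges.values():
        adj.setdefault(a, []).append((b, ln))
        adj.setdefault(b, []).append((a, ln))
    d = np.zeros((n_tips, n_tips))
    for src in range(n_tips):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, ln in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + ln
                    stack.append(v)
        for t in range(n_tips):
            d[src, t] = dist[t]
    np.fill_diagonal(d, 0.0)
    tips = [f"t{i}" for i in range(n_tips)]
    return tips, d


def tree_path_matrix(tree, ids: list[str]) -> np.ndarray:
    """Tip-to-tip path-length matrix of a GeneTree (independent traversal)."""
    index = {name: i for i, name in enumerate(ids)}
    n = len(ids)
    out = np.zeros((n, n))

    def walk(node):
        """Return {tip: depth below node}; fill cross-child distances."""
        if node.is_leaf:
            return {node.name: node.length}
        below = {}
        child_maps = [walk(c) for c in node.children]
        for i in range(len(child_maps)):
            for j in range(i + 1, len(child_maps)):
                for ta, da in child_maps[i].items():
                    for tb, db in child_maps[j].items():
                        out[index[ta], index[tb]] = out[index[tb], index[ta]] = da + db
        for cm in child_maps:
            for t, dep in cm.items():
                below[t] = dep + node.length
        return below

    walk(tree.root)
    return out


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """Three simulated families with the default event set, on disk."""
    from legumeks.synthetic_evolution import SimulationSpec, generate_dataset

    out = tmp_path_factory.mktemp("sim_small")
    spec = SimulationSpec(n_families=3, seed=11)
    manifest = generate_dataset(spec, out)
    return spec, out, manifest
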