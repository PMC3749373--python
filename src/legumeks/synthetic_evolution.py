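"""Simulation of legume gene-family evolution with known truth.

Gene families evolve along a six-species legume tree (warm-season
Phaseoloid clade Gm/Cc/Pv against cool-season Hologalegina clade
Mt/Ca/Lj) in units of expected synonymous substitutions per synonymous
site (dS).  Duplication events — an ancient pre-speciation duplication,
a whole-genome duplication confined to one lineage, and tandem
duplications — are layered onto the species tree, and each duplicate
lineage can be lost.  The generator emits per-species CDS FASTA, a gene
position table and a full truth table of pair relations (ortholog /
inparalog / outparalog, tandem flags, true dS/dN), so every downstream
stage of the package can be scored by recovery of simulated truth.

The default species-tree branch lengths are least-squares fitted so that
tip-to-tip dS matches the ortholog Ks medians observed between the six
real legume genomes (e.g. Gm–Cc 0.212, Gm–Mt 0.398, Mt–Ca 0.282); they
are defaults for realism, not assertions about any particular dataset.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _codons
from .homology import CodingSequence, write_fasta

# ---------------------------------------------------------------------------
# species tree

#: six-legume topology in dS units, fitted to observed ortholog Ks medians
DEFAULT_SPECIES_NEWICK = (
    "((Gm:0.100,(Cc:0.101,Pv:0.099):0.012):0.030,"
    "(Lj:0.165,(Mt:0.167,Ca:0.115):0.064):0.034);"
)


@dataclass
class SpeciesNode:
    name: str | None
    length: float  # branch above this node, dS units
    children: list["SpeciesNode"] = field(default_factory=list)

    def tips(self) -> list["SpeciesNode"]:
        if not self.children:
            return [self]
        out = []
        for child in self.children:
            out.extend(child.tips())
        return out


def parse_species_tree(newick: str) -> SpeciesNode:
    """Parse a rooted newick string with branch lengths into SpeciesNode."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")

    def convert(node) -> SpeciesNode:
        name = node.taxon.label if node.taxon else node.label
        length = node.edge.length or 0.0
        if length < 0:
            raise ValueError("negative branch length in species tree")
        return SpeciesNode(
            name=name,
            length=float(length),
            children=[convert(c) for c in node.child_nodes()],
        )

    root = convert(tree.seed_node)
    names = [t.name for t in root.tips()]
    if len(set(names)) != len(names):
        raise ValueError("tip names must be unique")
    return root


def tip_depths(root: SpeciesNode) -> dict[str, float]:
    """Root-to-tip path length per species, dS units."""
    depths = {}

    def walk(node: SpeciesNode, acc: float):
        acc += node.length
        if not node.children:
            depths[node.name] = acc
        for child in node.children:
            walk(child, acc)

    walk(root, -root.length)  # root's own edge does not count
    return depths


def expected_ortholog_ds(root: SpeciesNode) -> dict[tuple[str, str], float]:
    """Tip-to-tip path lengths: the expected ortholog dS per species pair."""
    depths = tip_depths(root)

    # depth of the MRCA for each pair
    def pair_paths(node: SpeciesNode, acc: float, out):
        acc += node.length
        groups = [set(t.name for t in c.tips()) for c in node.children]
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                for a in groups[i]:
                    for b in groups[j]:
                        key = tuple(sorted((a, b)))
                        out[key] = depths[a] + depths[b] - 2 * acc
        for child in node.children:
            pair_paths(child, acc, out)

    out: dict[tuple[str, str], float] = {}
    pair_paths(root, -root.length, out)
    return out


# ---------------------------------------------------------------------------
# spec types


@dataclass
class DuplicationEvent:
    """One duplication layered onto the species tree.

    kind 'ancient' duplicates the family before the first speciation
    (lineage must be 'root'); 'wgd' and 'tandem' duplicate on a single
    named tip lineage.  ``age_ds`` is the expected dS separating the two
    copies at the end of the simulation; tandem duplicates are placed at
    the adjacent gene-order index.
    """

    kind: str
    lineage: str
    age_ds: float

    def __post_init__(self):
        if self.kind not in ("ancient", "wgd", "tandem"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.age_ds < 0:
            raise ValueError("age_ds must be >= 0")
        if self.kind == "ancient" and self.lineage != "root":
            raise ValueError("ancient events must use lineage 'root'")


def default_events() -> list[DuplicationEvent]:
    """The study conditions: ancient duplication at dS 0.65, a recent WGD
    in the Gm lineage at dS 0.1, and a tandem duplication in Mt."""
    return [
        DuplicationEvent("ancient", "root", 0.65),
        DuplicationEvent("wgd", "Gm", 0.10),
        DuplicationEvent("tandem", "Mt", 0.05),
    ]


@dataclass
class SimulationSpec:
    species_newick: str = DEFAULT_SPECIES_NEWICK
    events: list[DuplicationEvent] = field(default_factory=default_events)
    n_families: int = 20
    codon_length: int = 300
    omega: float = 0.2
    loss_prob: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.codon_length < 30:
            raise ValueError("codon_length must be >= 30")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if not 0.0 <= self.loss_prob <= 1.0:
            raise ValueError("loss_prob must be in [0, 1]")
        self.species_tree = parse_species_tree(self.species_newick)
        tips = {t.name for t in self.species_tree.tips()}
        for ev in self.events:
            if ev.kind != "ancient" and ev.lineage not in tips:
                raise ValueError(f"event names unknown lineage {ev.lineage!r}")

    def to_dict(self) -> dict:
        return {
            "species_newick": self.species_newick,
            "events": [vars(e) for e in self.events],
            "n_families": self.n_families,
            "codon_length": self.codon_length,
            "omega": self.omega,
            "loss_prob": self.loss_prob,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationSpec":
        d = dict(d)
        d["events"] = [DuplicationEvent(**e) for e in d.get("events", [])]
        return cls(**d)


@dataclass
class SimulatedFamily:
    family_id: str
    sequences: list[CodingSequence]
    truth_pairs: pd.DataFrame  # id_a, id_b, relation, tandem, true_ds, true_dn


# ---------------------------------------------------------------------------
# codon evolution

# per-codon mutation menu: codon -> (synonymous, nonsynonymous) lists of
# (position, replacement_nt, resulting codon); stop-producing changes excluded
_CHANGE_MENU: dict[str, tuple[list, list]] = {}


def _menu(codon: str):
    entry = _CHANGE_MENU.get(codon)
    if entry is None:
        syn, non = [], []
        aa = _codons.translate_codon(codon)
        for pos, nt, mutated in _codons.codon_neighbors(codon):
            if _codons.is_stop(mutated):
                continue
            if _codons.translate_codon(mutated) == aa:
                syn.append((pos, nt, mutated))
            else:
                non.append((pos, nt, mutated))
        entry = (syn, non)
        _CHANGE_MENU[codon] = entry
    return entry


def evolve_codons(
    sequence: str,
    target_ds: float,
    omega: float,
    rng: np.random.Generator,
) -> str:
    """Evolve a CDS by a fixed expected synonymous divergence.

    Applies ``round(target_ds * S)`` synonymous and
    ``round(omega * target_ds * N)`` nonsynonymous single-nucleotide
    substitutions, where S and N are the NG86 site counts of the input
    sequence.  Substitution sites are drawn uniformly over the eligible
    (codon, position, replacement) choices of the current sequence; changes
    that would create a stop codon are never eligible, so coding integrity
    is preserved.  Repeated hits at one site are allowed — that is the
    multiple-substitution process the downstream Jukes–Cantor correction
    undoes on average.
    """
    if target_ds < 0:
        raise ValueError("target_ds must be >= 0")
    codons = _codons.check_no_internal_stop(
        _codons.split_codons(sequence), allow_trailing=False
    )
    if target_ds == 0:
        return sequence
    s_sites = n_sites = 0.0
    for codon in codons:
        cs, cn = _codons.site_fractions(codon)
        s_sites += cs
        n_sites += cn
    if s_sites == 0:
        raise ValueError(
            "sequence too short to realize a synonymous divergence target: "
            f"0 synonymous sites for target_ds={target_ds} "
            f"(deficit {target_ds * len(codons):.2f} expected substitutions)"
        )
    n_syn = int(round(target_ds * s_sites))
    n_non = int(round(omega * target_ds * n_sites))
    if n_syn == 0 and n_non == 0:
        return sequence

    kinds = np.array([0] * n_syn + [1] * n_non)
    rng.shuffle(kinds)

    codons = list(codons)
    syn_counts = np.array([len(_menu(c)[0]) for c in codons], dtype=float)
    non_counts = np.array([len(_menu(c)[1]) for c in codons], dtype=float)

    for kind in kinds:
        counts = syn_counts if kind == 0 else non_counts
        total = counts.sum()
        if total == 0:
            deficit = int(np.sum(kinds == kind))
            label = "synonymous" if kind == 0 else "nonsynonymous"
            raise ValueError(
                f"sequence too short: no eligible {label} site for "
                f"{deficit} remaining substitution(s)"
            )
        idx = int(np.searchsorted(np.cumsum(counts), rng.random() * total, side="right"))
        options = _menu(codons[idx])[kind]
        _pos, _nt, mutated = options[rng.integers(len(options))]
        codons[idx] = mutated
        syn_counts[idx] = len(_menu(mutated)[0])
        non_counts[idx] = len(_menu(mutated)[1])
    return "".join(codons)


def random_root_sequence(codon_length: int, rng: np.random.Generator) -> str:
    """Random CDS of sense codons (never a stop)."""
    sense = _codons.SENSE_CODONS
    return "".join(sense[i] for i in rng.integers(len(sense), size=codon_length))


# ---------------------------------------------------------------------------
# gene-tree simulation


@dataclass
class _GeneNode:
    kind: str  # root | speciation | dup_ancient | dup_wgd | dup_tandem | tip
    length: float  # branch above, dS
    children: list["_GeneNode"] = field(default_factory=list)
    species: str | None = None
    tip_id: str | None = None
    duplicate_side: bool = False  # second child of a duplication node
    tandem_source: "_GeneNode | None" = None
    sequence: str | None = None


def _build_gene_tree(spec: SimulationSpec) -> _GeneNode:
    """Gene-tree topology (no sequences, no loss yet) for one family."""
    stree = spec.species_tree
    depths = tip_depths(stree)
    mean_depth = float(np.mean(list(depths.values())))

    tip_events: dict[str, list[DuplicationEvent]] = {}
    for ev in spec.events:
        if ev.kind in ("wgd", "tandem"):
            tip_events.setdefault(ev.lineage, []).append(ev)

    def descend(snode: SpeciesNode, branch: float, duplicate_side: bool) -> _GeneNode:
        if snode.children:
            gnode = _GeneNode("speciation", branch, duplicate_side=duplicate_side)
            for child in snode.children:
                gnode.children.append(descend(child, child.length, False))
            return gnode
        # terminal species branch: apply wgd/tandem events ordered oldest first
        events = sorted(
            tip_events.get(snode.name, []), key=lambda e: -e.age_ds
        )
        top = None
        attach = None  # node whose last child is the continuing lineage
        consumed = 0.0
        for ev in events:
            split_at = max(branch - ev.age_ds / 2.0, 0.0)
            seg = max(split_at - consumed, 0.0)
            kind = "dup_wgd" if ev.kind == "wgd" else "dup_tandem"
            dup = _GeneNode(kind, seg, duplicate_side=duplicate_side if top is None else False)
            copy_tip = _GeneNode(
                "tip", ev.age_ds / 2.0, species=snode.name, duplicate_side=True
            )
            dup.children.append(copy_tip)
            if top is None:
                top = dup
            else:
                attach.children.append(dup)
            attach = dup
            consumed = split_at
        main_tip = _GeneNode(
            "tip",
            max(branch - consumed, 0.0) if events else branch,
            species=snode.name,
            duplicate_side=duplicate_side if top is None else False,
        )
        if top is None:
            return main_tip
        attach.children.append(main_tip)
        # tandem copies sit adjacent to the continuing lineage's gene
        node = top
        while node is not None:
            if node.kind == "dup_tandem":
                node.children[0].tandem_source = main_tip
            node = node.children[-1] if node.children and node.children[-1].kind in (
                "dup_wgd", "dup_tandem") else None
        return main_tip if top is None else top

    ancient = [e for e in spec.events if e.kind == "ancient"]

    def species_root(branch: float, duplicate_side: bool) -> _GeneNode:
        node = _GeneNode("speciation", branch, duplicate_side=duplicate_side)
        for child in stree.children:
            node.children.append(descend(child, child.length, False))
        return node

    if not ancient:
        root = species_root(0.0, False)
        root.kind = "root"
        return root

    root = _GeneNode("root", 0.0)
    heads = [root]
    for ev in ancient:
        new_heads = []
        delta = max(ev.age_ds - 2.0 * mean_depth, 0.0)
        for head in heads:
            dup = _GeneNode("dup_ancient", 0.0)
            a = _GeneNode("speciation", delta / 2.0)
            b = _GeneNode("speciation", delta / 2.0, duplicate_side=True)
            dup.children = [a, b]
            head.children.append(dup)
            new_heads.extend([a, b])
        heads = new_heads
    for head in heads:
        for child in stree.children:
            head.children.append(descend(child, child.length, False))
    return root


def _collect_tips(root: _GeneNode) -> list[tuple[_GeneNode, bool]]:
    """Depth-first tips with a flag: does the path pass a duplicate side?"""
    out = []

    def walk(node: _GeneNode, on_duplicate: bool):
        on_duplicate = on_duplicate or node.duplicate_side
        if node.kind == "tip":
            out.append((node, on_duplicate))
        for child in node.children:
            walk(child, on_duplicate)

    walk(root, False)
    return out


def _pairwise_truth(root: _GeneNode, omega: float) -> pd.DataFrame:
    """Replay the gene tree into per-pair relation labels and true distances."""
    # path from root for every surviving tip: list of (node, cumulative dS)
    paths: dict[int, list[tuple[_GeneNode, float]]] = {}
    tips: list[_GeneNode] = []

    def walk(node: _GeneNode, path: list, acc: float):
        acc += node.length
        path = path + [(node, acc)]
        if node.kind == "tip" and node.tip_id is not None:
            paths[id(node)] = path
            tips.append(node)
        for child in node.children:
            walk(child, path, acc)

    walk(root, [], -root.length)

    rows = []
    for i in range(len(tips)):
        for j in range(i + 1, len(tips)):
            a, b = tips[i], tips[j]
            pa, pb = paths[id(a)], paths[id(b)]
            shared = 0
            while (
                shared < min(len(pa), len(pb)) and pa[shared][0] is pb[shared][0]
            ):
                shared += 1
            mrca, mrca_depth = pa[shared - 1]
            true_ds = (pa[-1][1] - mrca_depth) + (pb[-1][1] - mrca_depth)
            if mrca.kind in ("speciation", "root"):
                relation = "ortholog"
            elif mrca.kind == "dup_ancient":
                relation = "outparalog"
            else:
                relation = "inparalog"
            tandem = mrca.kind == "dup_tandem"
            ida, idb = sorted((a.tip_id, b.tip_id))
            rows.append(
                {
                    "id_a": ida,
                    "id_b": idb,
                    "relation": relation,
                    "tandem": tandem,
                    "true_ds": true_ds,
                    "true_dn": omega * true_ds,
                }
            )
    return pd.DataFrame(rows)


def simulate_family(spec: SimulationSpec, family_index: int) -> SimulatedFamily:
    """Simulate one gene family: topology, loss, sequences, truth labels.

    Deterministic given (spec.seed, family_index).
    """
    rng = np.random.default_rng([spec.seed % 2**31, family_index])
    family = f"f{family_index:03d}"
    root = _build_gene_tree(spec)

    # loss: each duplicate-derived tip is dropped with probability loss_prob
    tips = _collect_tips(root)
    for tip, on_duplicate in tips:
        tip.sequence = None
        keep = True
        if on_duplicate and rng.random() < spec.loss_prob:
            keep = False
        tip.tip_id = "KEEP" if keep else None

    # prune: ensure at least the non-duplicate complement survives (it always
    # does: primary-lineage tips are never droppable)

    # assign copy indices per species in traversal order over surviving tips
    counters: dict[str, int] = {}
    for tip, _dup in tips:
        if tip.tip_id is None:
            continue
        c = counters.get(tip.species, 0)
        counters[tip.species] = c + 1
        tip.tip_id = f"{tip.species}_{family}_c{c}"

    # evolve sequences along the gene tree
    root_seq = random_root_sequence(spec.codon_length, rng)

    def evolve(node: _GeneNode, parent_seq: str):
        seq = evolve_codons(parent_seq, node.length, spec.omega, rng)
        if node.kind == "tip":
            node.sequence = seq
        for child in node.children:
            evolve(child, seq)

    evolve(root, root_seq)

    # genomic placement: base chromosome per family, ancient/wgd copies on
    # shifted chromosomes, tandem copies adjacent to their source gene
    base_chr = (family_index % 7) + 1
    sequences = []
    order_counter: dict[tuple[str, int], int] = {}
    placed: dict[int, tuple[int, int]] = {}  # id(tip) -> (chrom, order)

    surviving = [(tip, dup) for tip, dup in tips if tip.tip_id is not None]
    # place non-tandem genes first, then tandem copies beside their sources
    for tip, _dup in surviving:
        if tip.tandem_source is not None:
            continue
        chrom = base_chr
        node_path_kinds = _tip_origin_kinds(root, tip)
        if "dup_ancient" in node_path_kinds:
            chrom += 3
        if "dup_wgd" in node_path_kinds and tip.duplicate_side:
            chrom += 1
        key = (tip.species, chrom)
        order = order_counter.get(key, family_index * 20 + 1)
        order_counter[key] = order + 5
        placed[id(tip)] = (chrom, order)
    for tip, _dup in surviving:
        if tip.tandem_source is None:
            continue
        src = placed.get(id(tip.tandem_source))
        if src is None:  # source lost: place independently
            chrom, order = base_chr, family_index * 20 + 11
        else:
            chrom, order = src[0], src[1] + 1
        placed[id(tip)] = (chrom, order)

    for tip, _dup in surviving:
        chrom, order = placed[id(tip)]
        sequences.append(
            CodingSequence(
                id=tip.tip_id,
                species=tip.species,
                nucleotides=tip.sequence,
                chromosome=f"chr{chrom}",
                order_index=order,
            )
        )

    truth = _pairwise_truth(root, spec.omega)
    return SimulatedFamily(family_id=family, sequences=sequences, truth_pairs=truth)


def _tip_origin_kinds(root: _GeneNode, target: _GeneNode) -> set[str]:
    """Kinds of duplication nodes on the root-to-tip path where the path
    takes the duplicate side."""
    result: set[str] = set()

    def walk(node: _GeneNode, acc: set[str]) -> bool:
        if node is target:
            result.update(acc)
            return True
        for child in node.children:
            extra = {node.kind} if child.duplicate_side else set()
            if walk(child, acc | extra):
                return True
        return False

    walk(root, set())
    return result


# ---------------------------------------------------------------------------
# dataset generation


def simulate_dataset(spec: SimulationSpec) -> list[SimulatedFamily]:
    return [simulate_family(spec, i) for i in range(spec.n_families)]


def generate_dataset(spec: SimulationSpec, out_dir) -> dict:
    """Write FASTA per species, positions TSV, truth TSV and a manifest.

    Re-running with the same spec (including seed) reproduces byte-identical
    outputs.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    families = simulate_dataset(spec)

    by_species: dict[str, list[CodingSequence]] = {}
    pos_rows = []
    truth_frames = []
    for fam in families:
        for cds in fam.sequences:
            by_species.setdefault(cds.species, []).append(cds)
            pos_rows.append(
                {
                    "id": cds.id,
                    "species": cds.species,
                    "chromosome": cds.chromosome,
                    "order_index": cds.order_index,
                }
            )
        truth = fam.truth_pairs.copy()
        truth.insert(0, "family", fam.family_id)
        truth_frames.append(truth)

    files = {}
    for species in sorted(by_species):
        seqs = sorted(by_species[species], key=lambda c: c.id)
        path = out / f"{species}.cds.fasta"
        write_fasta(seqs, path)
        files[path.name] = len(seqs)

    positions = pd.DataFrame(pos_rows).sort_values("id", kind="mergesort")
    positions.to_csv(out / "positions.tsv", sep="\t", index=False)
    files["positions.tsv"] = len(positions)

    truth_all = pd.concat(truth_frames, ignore_index=True)
    truth_all.to_csv(out / "truth_pairs.tsv", sep="\t", index=False, float_format="%.6f")
    files["truth_pairs.tsv"] = len(truth_all)

    manifest = {
        "seed": spec.seed,
        "spec": spec.to_dict(),
        "files": files,
        "n_families": spec.n_families,
    }
    manifest["checksum"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
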