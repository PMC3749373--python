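"""End-to-end orchestration: simulate -> search -> families -> align ->
rates -> trees -> classify -> landscape.

Each stage writes its table under the output directory and is logged with
row counts; the final manifest records versions, the seed and per-stage
row counts so a run can be audited and reproduced.  Identical config and
seed give byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import platform
import re
import sys
import time
import warnings
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import pandas as pd

from . import (
    codon_align,
    evol_rates,
    homology,
    ks_landscape,
    nj_phylo,
    paralog_classify,
    synthetic_evolution as synth,
)

logger = logging.getLogger("legumeks")

STAGES = (
    "simulate",
    "search",
    "families",
    "align",
    "rates",
    "trees",
    "classify",
    "landscape",
)


@dataclass
class PipelineConfig:
    """All thresholds of the analysis in one serializable record."""

    out_dir: str = "legumeks_run"
    input_dir: str | None = None  # pre-existing FASTA dir; None -> simulate
    simulation: dict = field(default_factory=lambda: synth.SimulationSpec().to_dict())
    min_identity: float = 70.0
    max_e: float = 1e-50
    min_species: int = 4
    total_species: int = 6
    bootstrap_replicates: int = 1000
    min_support: float = 50.0
    ks_outparalog_threshold: float = 0.40
    max_order_gap: int = 1
    bin_width: float = 0.1
    ks_max: float = 2.0
    min_peak_proportion: float = 0.10
    # peak-typing windows on the Ks axis (inclusive upper bounds)
    recent_wgd_max: float = 0.15
    speciation_max: float = 0.50
    ancient_max: float = 0.80
    min_codons: int = 10
    seed: int = 0
    threads: int = 1  # scheduling only; never affects results
    plot: bool = False

    def __post_init__(self):
        if not 0 <= self.min_identity <= 100:
            raise ValueError("min_identity must be a percentage")
        if self.max_e < 0:
            raise ValueError("max_e must be non-negative")
        if self.bootstrap_replicates < 1:
            raise ValueError("bootstrap_replicates must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def simulation_spec(self) -> synth.SimulationSpec:
        sim = dict(self.simulation)
        sim["seed"] = self.seed
        return synth.SimulationSpec.from_dict(sim)


def _stage(manifest, name, t0, **counts):
    elapsed = time.perf_counter() - t0
    record = {"stage": name, "elapsed_s": round(elapsed, 3), **counts}
    manifest["stages"].append(record)
    logger.info("stage=%s elapsed=%.2fs %s", name, elapsed,
                " ".join(f"{k}={v}" for k, v in counts.items()))
    return time.perf_counter()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    if not any(isinstance(h, logging.StreamHandler) and h.stream is sys.stderr
               for h in logger.handlers):
        logger.addHandler(logging.StreamHandler(sys.stderr))
    logger.setLevel(logging.INFO)

    manifest: dict = {
        "seed": config.seed,
        "config": config.to_dict(),
        "versions": _versions(),
        "stages": [],
    }
    t0 = time.perf_counter()
    try:
        # -- simulate (or load) --------------------------------------------
        truth = None
        if config.input_dir is None:
            spec = config.simulation_spec()
            sim_dir = out / "sim"
            synth.generate_dataset(spec, sim_dir)
            truth = pd.read_csv(sim_dir / "truth_pairs.tsv", sep="\t")
            input_dir = sim_dir
        else:
            input_dir = Path(config.input_dir)
            truth_path = input_dir / "truth_pairs.tsv"
            if truth_path.exists():
                truth = pd.read_csv(truth_path, sep="\t")
        sequences = []
        for fasta in sorted(input_dir.glob("*.fasta")):
            species = fasta.name.split(".")[0]
            sequences.extend(homology.read_fasta(fasta, species))
        positions_path = input_dir / "positions.tsv"
        positions_df = (
            homology.read_positions_tsv(positions_path)
            if positions_path.exists()
            else None
        )
        t0 = _stage(manifest, "simulate", t0, sequences=len(sequences))

        # -- search --------------------------------------------------------
        hits = homology.all_vs_all_search(sequences, sequences)
        homology.write_hits_tsv(hits, out / "hits.tsv")
        t0 = _stage(manifest, "search", t0, hits=len(hits))

        # -- families ------------------------------------------------------
        species_of = {cds.id: cds.species for cds in sequences}
        filtered = homology.filter_hits(hits, config.min_identity, config.max_e)
        bbh_pairs = homology.bidirectional_best_hits(filtered, species_of)
        pd.DataFrame(bbh_pairs, columns=["id_a", "id_b"]).to_csv(
            out / "bbh_pairs.tsv", sep="\t", index=False
        )
        families = homology.cluster_families(
            sorted(species_of), filtered, species_of
        )
        for fam in families:
            fam.family_id = f"fam_{min(fam.member_ids)}"
        families = homology.select_qualifying_genes(
            families, config.min_species, config.total_species
        )
        families = [f for f in families if len(f.member_ids) >= 2]
        fam_rows = [
            {"family": f.family_id, "n_members": len(f.member_ids),
             "n_species": len(f.species_present),
             "members": ",".join(f.member_ids)}
            for f in families
        ]
        pd.DataFrame(fam_rows).to_csv(out / "families.tsv", sep="\t", index=False)
        t0 = _stage(manifest, "families", t0,
                    filtered_hits=len(filtered), bbh=len(bbh_pairs),
                    families=len(families))

        # -- align ---------------------------------------------------------
        seq_by_id = {cds.id: cds for cds in sequences}
        alignments = {}
        for fam in families:
            members = [seq_by_id[m] for m in fam.member_ids]
            msa = codon_align.progressive_msa(members)
            alignments[fam.family_id] = codon_align.complete_deletion(msa)
        align_dir = out / "alignments"
        align_dir.mkdir(exist_ok=True)
        for fam_id, msa in alignments.items():
            codon_align.write_aligned_fasta(msa, align_dir / f"{fam_id}.aln.fasta")
        t0 = _stage(manifest, "align", t0, alignments=len(alignments))

        # -- rates ---------------------------------------------------------
        rate_frames = []
        for fam_id, msa in alignments.items():
            rate_frames.append(
                evol_rates.compute_all_pairs(
                    msa, species_of=species_of, family_id=fam_id,
                    min_codons=config.min_codons,
                )
            )
        rates = pd.concat(rate_frames, ignore_index=True)
        evol_rates.write_rates_tsv(rates, out / "rates.tsv")
        t0 = _stage(manifest, "rates", t0, pairs=len(rates))

        # -- trees ---------------------------------------------------------
        trees = {}
        tree_dir = out / "trees"
        tree_dir.mkdir(exist_ok=True)
        for idx, (fam_id, msa) in enumerate(alignments.items()):
            tree = nj_phylo.bootstrap_supports(
                msa,
                n_replicates=config.bootstrap_replicates,
                seed=(config.seed + idx) % 2**31,
            )
            trees[fam_id] = tree
            (tree_dir / f"{fam_id}.nwk").write_text(tree.newick() + "\n")
        t0 = _stage(manifest, "trees", t0, trees=len(trees))

        # -- classify ------------------------------------------------------
        positions = None
        if positions_df is not None:
            positions = {
                r.id: (r.species, r.chromosome, int(r.order_index))
                for r in positions_df.itertuples()
            }
        class_frames = []
        for fam_id, msa in alignments.items():
            partition = nj_phylo.split_two_clusters(
                trees[fam_id], config.min_support, species_of
            )
            fam_rates = rates[rates["family"] == fam_id]
            cls = paralog_classify.classify_family(
                fam_rates, partition, species_of, positions,
                ks_outparalog_threshold=config.ks_outparalog_threshold,
                max_order_gap=config.max_order_gap,
            )
            cls.insert(0, "family", fam_id)
            class_frames.append(cls)
        classified = pd.concat(class_frames, ignore_index=True)
        classified.to_csv(out / "classification.tsv", sep="\t", index=False,
                          float_format="%.6g")
        evaluation = None
        if truth is not None:
            evaluation = paralog_classify.evaluate_against_truth(
                classified.rename(columns={"tandem": "tandem_pred"}),
                truth.rename(columns={"tandem": "tandem_true"}),
            )
            with open(out / "truth_evaluation.json", "w") as fh:
                json.dump(evaluation, fh, indent=2)
        t0 = _stage(manifest, "classify", t0, pairs=len(classified),
                    accuracy=(evaluation or {}).get("accuracy"))

        # -- landscape -----------------------------------------------------
        merged = rates.merge(
            classified[["family", "id_a", "id_b", "relation", "tandem"]],
            on=["family", "id_a", "id_b"], how="left",
        )
        species_pairs = sorted(
            {tuple(sorted((a, b))) for a, b in zip(merged["species_a"], merged["species_b"])}
        )
        dists = []
        peaks_by_pair = {}
        for pair in species_pairs:
            dist = ks_landscape.build_distribution(
                merged, pair, config.bin_width, config.ks_max
            )
            dists.append(dist)
            peaks_by_pair[pair] = ks_landscape.typed_peaks(
                dist, config.min_peak_proportion,
                config.recent_wgd_max, config.speciation_max, config.ancient_max,
            )
        ks_landscape.distribution_table(dists).to_csv(
            out / "ks_distributions.tsv", sep="\t", index=False
        )
        ks_landscape.peaks_table(peaks_by_pair).to_csv(
            out / "ks_peaks.tsv", sep="\t", index=False
        )
        summaries, relationship = ks_landscape.summarize_species_pairs(merged)
        selection = ks_landscape.selection_pressure_summary(merged)
        summary = {
            "species_pairs": [
                {
                    "pair": "-".join(s.species_pair),
                    "ks_median": s.ks_median,
                    "mean_ka_ks": s.mean_ka_ks,
                    "n_pairs": s.n_pairs,
                    "n_genes_lowest_ks": s.n_genes_lowest_ks,
                    "n_genes_highest_ks": s.n_genes_highest_ks,
                }
                for s in summaries
            ],
            "relationship_report": relationship,
            "selection": selection,
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        if config.plot:
            ks_landscape.plot_distributions(dists, out / "ks_landscape.png")
        t0 = _stage(manifest, "landscape", t0, distributions=len(dists))
    except Exception as exc:
        stage = STAGES[len(manifest["stages"])] if len(manifest["stages"]) < len(STAGES) else "?"
        logger.error("pipeline aborted in stage %s: %s", stage, exc)
        raise RuntimeError(f"pipeline aborted in stage {stage!r}: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()

    manifest["completed_stages"] = len(manifest["stages"])
    if truth is not None and evaluation is not None:
        manifest["truth_evaluation"] = evaluation
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _versions() -> dict:
    import Bio
    import numpy

    return {
        "python": platform.python_version(),
        "numpy": numpy.__version__,
        "pandas": pd.__version__,
        "biopython": Bio.__version__,
    }


# ---------------------------------------------------------------------------
# gene-table fixture and chromosome counting

_CHROMOSOME_PATTERNS = {
    "Mt": re.compile(r"^Medtr(\d+)g"),
    "Gm": re.compile(r"^Glyma(\d+)g"),
    "Lj": re.compile(r"^Lj(\d+)\."),
}


def load_nf_gene_table() -> pd.DataFrame:
    """Bundled table of nodulation/nitrogen-fixation gene identifiers for
    the six legume species (columns: gene, species, rank, gene_id)."""
    with resources.files("legumeks.data").joinpath("nf_gene_table.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def parse_chromosome(gene_id: str, species: str) -> str | None:
    """Chromosome encoded in a gene identifier (Medtr5g... -> '5')."""
    pattern = _CHROMOSOME_PATTERNS.get(species)
    if pattern is None:
        return None
    m = pattern.match(gene_id)
    if m is None:
        return None
    return str(int(m.group(1)))


def count_genes_on_chromosome(
    gene_table: pd.DataFrame,
    species: str,
    chromosome: str | int,
    primary_only: bool = True,
) -> int:
    """Distinct gene families whose member for ``species`` lies on
    ``chromosome``.

    Uses a ``chromosome`` column when present, otherwise parses the
    chromosome from the identifier prefix (Mt/Gm/Lj naming schemes).
    ``primary_only`` restricts to each family's first-listed (rank-1)
    member.  Unparseable identifiers are excluded with a warning.
    """
    df = gene_table[gene_table["species"] == species].copy()
    if primary_only and "rank" in df.columns:
        df = df[df["rank"] == 1]
    if df.empty:
        return 0
    target = str(chromosome)
    families = set()
    for row in df.itertuples():
        if "chromosome" in df.columns and pd.notna(getattr(row, "chromosome", None)):
            chrom = str(row.chromosome)
        else:
            chrom = parse_chromosome(row.gene_id, species)
            if chrom is None:
                warnings.warn(
                    f"cannot parse chromosome from {row.gene_id!r}; excluded",
                    stacklevel=2,
                )
                continue
        if chrom == target or chrom == target.removeprefix("chr"):
            families.add(row.gene)
    return len(families)
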