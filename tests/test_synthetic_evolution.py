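"""Simulator: codon evolution, family histories, dataset generation."""

import json

import numpy as np
import pandas as pd
import pytest

from legumeks import _codons, evol_rates as er
from legumeks import synthetic_evolution as se


class TestEvolveCodons:
    def test_zero_divergence_is_identity(self, rng):
        seq = se.random_root_sequence(60, rng)
        for omega in (0.0, 0.5, 2.0):
            for seed in range(3):
                out = se.evolve_codons(seq, 0.0, omega, np.random.default_rng(seed))
                assert out == seq

    def test_omega_zero_makes_only_synonymous_changes(self, rng):
        seq = se.random_root_sequence(120, rng)
        child = se.evolve_codons(seq, 0.3, 0.0, rng)
        r = er.ng86(seq, child)
        assert r.nd == 0.0
        assert r.ka == 0.0
        assert r.sd > 0

    def test_no_stop_codons_ever_created(self, rng):
        seq = se.random_root_sequence(80, rng)
        for _ in range(5):
            seq = se.evolve_codons(seq, 0.2, 1.0, rng)
            codons = _codons.split_codons(seq)
            assert not any(_codons.is_stop(c) for c in codons)

    def test_length_preserved(self, rng):
        seq = se.random_root_sequence(50, rng)
        child = se.evolve_codons(seq, 0.4, 0.7, rng)
        assert len(child) == len(seq)

    def test_mean_estimated_ks_near_target(self):
        """20 seeds at target dS 0.2: NG86 estimate within +-0.05."""
        root = se.random_root_sequence(300, np.random.default_rng(77))
        estimates = []
        for seed in range(20):
            child = se.evolve_codons(root, 0.2, 0.5, np.random.default_rng(seed))
            estimates.append(er.ng86(root, child).ks)
        assert float(np.mean(estimates)) == pytest.approx(0.2, abs=0.05)

    def test_non_codon_length_rejected(self, rng):
        with pytest.raises(ValueError, match="divisible"):
            se.evolve_codons("ATGGC", 0.1, 0.5, rng)

    def test_impossible_budget_names_deficit(self, rng):
        # ten methionines: zero synonymous opportunities
        with pytest.raises(ValueError, match="synonymous"):
            se.evolve_codons("ATG" * 10, 1.0, 0.0, rng)

    def test_monotone_in_target_ds(self):
        """Expected NG86 Ks is non-decreasing in target dS (averaged)."""
        root = se.random_root_sequence(300, np.random.default_rng(5))
        means = []
        for target in (0.05, 0.15, 0.3, 0.5):
            vals = [
                er.ng86(
                    root,
                    se.evolve_codons(root, target, 0.2, np.random.default_rng(s)),
                ).ks
                for s in range(6)
            ]
            means.append(np.mean(vals))
        assert all(b >= a - 1e-9 for a, b in zip(means, means[1:]))


class TestSimulateFamily:
    def test_no_events_all_orthologs(self):
        spec = se.SimulationSpec(events=[], n_families=1, seed=4)
        fam = se.simulate_family(spec, 0)
        assert len(fam.sequences) == 6
        assert len(fam.truth_pairs) == 15
        assert set(fam.truth_pairs["relation"]) == {"ortholog"}

    def test_wgd_event_marks_exactly_one_gm_inparalog_pair(self):
        spec = se.SimulationSpec(
            events=[se.DuplicationEvent("wgd", "Gm", 0.1)],
            n_families=1,
            loss_prob=0.0,
            seed=4,
        )
        fam = se.simulate_family(spec, 0)
        inpar = fam.truth_pairs[fam.truth_pairs["relation"] == "inparalog"]
        assert len(inpar) == 1
        row = inpar.iloc[0]
        assert row.id_a.startswith("Gm") and row.id_b.startswith("Gm")
        assert row.true_ds == pytest.approx(0.1)

    def test_ancient_event_bookkeeping_replayed(self):
        """Cross-copy same-species pairs are outparalogs whose true dS is
        the duplication offset plus both root-to-tip depths."""
        spec = se.SimulationSpec(
            events=[se.DuplicationEvent("ancient", "root", 0.65)],
            n_families=1,
            loss_prob=0.0,
            seed=9,
        )
        fam = se.simulate_family(spec, 0)
        truth = fam.truth_pairs
        outpar = truth[truth["relation"] == "outparalog"]
        assert len(outpar) > 0
        depths = se.tip_depths(spec.species_tree)
        mean_depth = np.mean(list(depths.values()))
        delta = 0.65 - 2 * mean_depth
        same_species = outpar[
            outpar["id_a"].str.split("_").str[0]
            == outpar["id_b"].str.split("_").str[0]
        ]
        for row in same_species.itertuples():
            sp = row.id_a.split("_")[0]
            expected = delta + 2 * depths[sp]
            assert row.true_ds == pytest.approx(expected, abs=1e-9)
        # overall mean sits near the nominal event age
        assert same_species["true_ds"].mean() == pytest.approx(0.65, abs=0.12)

    def test_same_species_pairs_never_orthologs(self, small_dataset):
        _spec, out, _m = small_dataset
        truth = pd.read_csv(out / "truth_pairs.tsv", sep="\t")
        sp_a = truth["id_a"].str.split("_").str[0]
        sp_b = truth["id_b"].str.split("_").str[0]
        same = truth[sp_a == sp_b]
        cross = truth[sp_a != sp_b]
        assert set(same["relation"]) <= {"inparalog", "outparalog"}
        assert "inparalog" not in set(cross["relation"])

    def test_true_dn_proportional_to_omega(self):
        spec = se.SimulationSpec(events=[], n_families=1, omega=0.4, seed=2)
        fam = se.simulate_family(spec, 0)
        assert fam.truth_pairs["true_dn"].to_numpy() == pytest.approx(
            0.4 * fam.truth_pairs["true_ds"].to_numpy()
        )

    def test_unknown_lineage_rejected(self):
        with pytest.raises(ValueError, match="unknown lineage"):
            se.SimulationSpec(events=[se.DuplicationEvent("wgd", "Zz", 0.1)])

    def test_tandem_copies_adjacent(self):
        spec = se.SimulationSpec(
            events=[se.DuplicationEvent("tandem", "Mt", 0.05)],
            n_families=1,
            loss_prob=0.0,
            seed=6,
        )
        fam = se.simulate_family(spec, 0)
        mt = [c for c in fam.sequences if c.species == "Mt"]
        assert len(mt) == 2
        assert mt[0].chromosome == mt[1].chromosome
        assert abs(mt[0].order_index - mt[1].order_index) == 1


class TestOmegaRecovery:
    @pytest.mark.parametrize("omega", [0.2, 0.7, 1.0])
    def test_mean_ka_ks_tracks_omega(self, omega):
        """Mean Ka/Ks over simulated ortholog pairs within +-0.15 of omega
        for histories with dS <= 0.5."""
        spec = se.SimulationSpec(
            events=[], n_families=4, omega=omega, codon_length=300, seed=31
        )
        ratios = []
        for i in range(spec.n_families):
            fam = se.simulate_family(spec, i)
            seqs = {c.id: c.nucleotides for c in fam.sequences}
            for row in fam.truth_pairs.itertuples():
                r = er.ng86(seqs[row.id_a], seqs[row.id_b])
                if r.ka_ks is not None:
                    ratios.append(r.ka_ks)
        assert float(np.mean(ratios)) == pytest.approx(omega, abs=0.15)


class TestGenerateDataset:
    def test_file_bookkeeping(self, small_dataset):
        _spec, out, manifest = small_dataset
        fastas = sorted(p.name for p in out.glob("*.fasta"))
        assert len(fastas) == 6
        truth = pd.read_csv(out / "truth_pairs.tsv", sep="\t")
        truth_ids = set(truth["id_a"]) | set(truth["id_b"])
        fasta_ids = set()
        for fasta in out.glob("*.fasta"):
            for line in fasta.read_text().splitlines():
                if line.startswith(">"):
                    fasta_ids.add(line[1:])
        assert truth_ids <= fasta_ids
        positions = pd.read_csv(out / "positions.tsv", sep="\t")
        assert set(positions.columns) == {"id", "species", "chromosome", "order_index"}
        assert (positions["order_index"] >= 1).all()

    def test_same_seed_byte_identical(self, tmp_path):
        spec = se.SimulationSpec(n_families=2, seed=42)
        se.generate_dataset(spec, tmp_path / "a")
        se.generate_dataset(spec, tmp_path / "b")
        for name in ("Gm.cds.fasta", "positions.tsv", "truth_pairs.tsv", "manifest.json"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_manifest_echoes_spec(self, small_dataset):
        spec, out, manifest = small_dataset
        on_disk = json.loads((out / "manifest.json").read_text())
        assert on_disk["seed"] == spec.seed
        assert on_disk["spec"]["n_families"] == spec.n_families


class TestSpecValidation:
    def test_codon_length_floor(self):
        with pytest.raises(ValueError):
            se.SimulationSpec(codon_length=10)

    def test_negative_omega(self):
        with pytest.raises(ValueError):
            se.SimulationSpec(omega=-0.1)

    def test_loss_prob_range(self):
        with pytest.raises(ValueError):
            se.SimulationSpec(loss_prob=1.5)

    def test_round_trip_dict(self):
        spec = se.SimulationSpec(n_families=5, omega=0.3, seed=8)
        again = se.SimulationSpec.from_dict(spec.to_dict())
        assert again.to_dict() == spec.to_dict()

    def test_default_tree_matches_fitted_pair_targets(self):
        """Tip-to-tip dS of the default tree approximates the calibrated
        ortholog Ks medians (Gm-Cc 0.212, Gm-Mt 0.398, Mt-Ca 0.282)."""
        tree = se.parse_species_tree(se.DEFAULT_SPECIES_NEWICK)
        dists = se.expected_ortholog_ds(tree)
        assert dists[("Cc", "Gm")] == pytest.approx(0.212, abs=0.01)
        assert dists[("Gm", "Mt")] == pytest.approx(0.398, abs=0.01)
        assert dists[("Ca", "Mt")] == pytest.approx(0.282, abs=0.01)
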