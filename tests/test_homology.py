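"""Homology search, hit filtering, BBH orthology and family assembly."""

import itertools

import numpy as np
import pytest

from legumeks import homology as hm


def _cds(seq_id, species, nt):
    return hm.CodingSequence(id=seq_id, species=species, nucleotides=nt)


def _random_cds(rng, seq_id, species, length=500):
    return _cds(seq_id, species, "".join(rng.choice(list("ACGT"), length)))


def _hit(q, s, ident=90.0, e=1e-80, bits=500.0):
    return hm.HomologyHit(
        query_id=q, subject_id=s, pct_identity=ident, align_length=100,
        mismatches=5, gap_opens=0, q_start=1, q_end=100, s_start=1, s_end=100,
        e_value=e, bit_score=bits,
    )


class TestSearch:
    def test_identical_sequence_is_a_perfect_hit(self, rng):
        db_seq = _random_cds(rng, "target", "Sp2", 500)
        query = _cds("probe", "Sp1", db_seq.nucleotides)
        hits = hm.all_vs_all_search([db_seq], [query])
        assert len(hits) == 1
        top = hits[0]
        assert top.pct_identity == 100.0
        assert top.e_value < 1e-50
        assert (top.q_start, top.q_end) == (1, 500)

    def test_no_shared_seed_no_hits(self):
        # alternating patterns share no 11-mer
        a = _cds("a", "Sp1", "ACACACACACAC" * 30)
        b = _cds("b", "Sp2", "GTGTGTGTGTGT" * 30)
        assert hm.all_vs_all_search([b], [a]) == []

    def test_ninety_percent_identity_recovered(self, rng):
        nt = list("".join(rng.choice(list("ACGT"), 300)))
        other = nt.copy()
        positions = rng.choice(300, size=30, replace=False)
        for p in positions:
            other[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[other[p]]
        a = _cds("a", "Sp1", "".join(nt))
        b = _cds("b", "Sp2", "".join(other))
        config = hm.SearchConfig(prescreen_max_divergence=1.0)
        hits = hm.all_vs_all_search([b], [a], config)
        assert hits, "homologous pair must be found"
        # full-length ungapped alignment: identity 90 +- rounding
        assert hits[0].pct_identity == pytest.approx(90.0, abs=1.0)

    def test_alignment_score_matches_dp_oracle(self, rng):
        """Seed-gated search scores equal full Smith-Waterman DP scores."""
        from Bio import Align

        nt = list("".join(rng.choice(list("ACGT"), 240)))
        other = nt.copy()
        for p in rng.choice(240, size=20, replace=False):
            other[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[other[p]]
        a, b = "".join(nt), "".join(other)

        # independent plain DP oracle (quadratic, no seeding, no pruning)
        def sw_oracle(x, y, match=2, mismatch=-3, open_=7, ext=2):
            n, m = len(x), len(y)
            best = 0.0
            M = np.zeros((n + 1, m + 1))
            X = np.full((n + 1, m + 1), -1e30)
            Y = np.full((n + 1, m + 1), -1e30)
            for i in range(1, n + 1):
                for j in range(1, m + 1):
                    s = match if x[i - 1] == y[j - 1] else mismatch
                    M[i, j] = max(0.0, M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
                    X[i, j] = max(M[i - 1, j] - open_, X[i - 1, j] - ext)
                    Y[i, j] = max(M[i, j - 1] - open_, Y[i, j - 1] - ext)
                    best = max(best, M[i, j])
            return best

        config = hm.SearchConfig(prescreen_max_divergence=1.0)
        hits = hm.all_vs_all_search(
            [_cds("s", "Sp2", b)], [_cds("q", "Sp1", a)], config
        )
        assert hits
        # invert the bit-score transform to recover the raw score
        raw = (hits[0].bit_score * np.log(2) + np.log(config.karlin_k)) / config.karlin_lambda
        assert raw == pytest.approx(sw_oracle(a, b), abs=1e-6)

    def test_empty_query_errors(self, rng):
        with pytest.raises(ValueError):
            hm.all_vs_all_search([_random_cds(rng, "x", "Sp1")], [])


class TestFilter:
    def test_boundary_below_identity_removed(self):
        assert hm.filter_hits([_hit("a", "b", ident=69.9, e=1e-80)]) == []

    def test_inclusive_boundaries_kept(self):
        kept = hm.filter_hits([_hit("a", "b", ident=70.0, e=1e-50)])
        assert len(kept) == 1

    def test_evalue_boundary(self):
        assert hm.filter_hits([_hit("a", "b", ident=95.0, e=1.1e-50)]) == []

    def test_subset_preserves_order(self):
        hits = [
            _hit("a", "b", ident=95, e=1e-60),
            _hit("a", "c", ident=60, e=1e-60),
            _hit("a", "d", ident=95, e=1e-10),
            _hit("a", "e", ident=80, e=1e-55),
            _hit("a", "f", ident=71, e=1e-49),
        ]
        kept = hm.filter_hits(hits)
        expected = [h for h in hits if h.pct_identity >= 70 and h.e_value <= 1e-50]
        assert kept == expected
        assert [h.subject_id for h in kept] == ["b", "e"]

    def test_idempotence(self):
        hits = [_hit("a", "b", ident=75), _hit("a", "c", ident=65)]
        once = hm.filter_hits(hits)
        assert hm.filter_hits(once) == once


class TestBBH:
    def test_reciprocal_single_pair(self):
        hits = [_hit("a1", "b1"), _hit("b1", "a1")]
        species = {"a1": "A", "b1": "B"}
        assert hm.bidirectional_best_hits(hits, species) == [("a1", "b1")]

    def test_non_reciprocal_rejected(self):
        hits = [
            _hit("a", "b", bits=100),
            _hit("b", "c", bits=200),
            _hit("b", "a", bits=100),
            _hit("c", "b", bits=50),
        ]
        species = {"a": "S1", "c": "S1", "b": "S2"}
        # a's best in S2 is b, but b's best in S1 is c != a
        assert ("a", "b") not in hm.bidirectional_best_hits(hits, species)

    def test_missing_species_mapping_names_id(self):
        with pytest.raises(KeyError, match="mystery"):
            hm.bidirectional_best_hits([_hit("a", "mystery")], {"a": "A"})

    def test_matches_brute_force_on_random_matrix(self, rng):
        """BBH set equals the 16-condition reciprocity check on a 4x4
        bit-score matrix between two species."""
        ids_a = [f"a{i}" for i in range(4)]
        ids_b = [f"b{i}" for i in range(4)]
        species = {**{a: "A" for a in ids_a}, **{b: "B" for b in ids_b}}
        scores = rng.uniform(50, 500, size=(4, 4))
        hits = []
        for i, a in enumerate(ids_a):
            for j, b in enumerate(ids_b):
                hits.append(_hit(a, b, bits=scores[i, j], e=1e-60))
                hits.append(_hit(b, a, bits=scores[i, j], e=1e-60))
        result = set(hm.bidirectional_best_hits(hits, species))
        brute = set()
        for i, a in enumerate(ids_a):
            for j, b in enumerate(ids_b):
                if scores[i, :].argmax() == j and scores[:, j].argmax() == i:
                    brute.add(tuple(sorted((a, b))))
        assert result == brute


class TestFamilies:
    def test_anchor_with_no_hits_is_singleton(self):
        fams = hm.cluster_families(["Aa_lonely"], [])
        assert len(fams) == 1
        assert fams[0].member_ids == ["Aa_lonely"]

    def test_transitive_chain_merges(self):
        hits = [_hit("Sp1_a", "Sp2_b"), _hit("Sp2_b", "Sp3_c")]
        fams = hm.cluster_families(["Sp1_a"], hits)
        assert fams[0].member_ids == ["Sp1_a", "Sp2_b", "Sp3_c"]
        assert fams[0].species_present == {"Sp1", "Sp2", "Sp3"}

    def test_two_anchors_one_component_merged_once(self):
        hits = [_hit("Sp1_a", "Sp2_b")]
        fams = hm.cluster_families(["Sp1_a", "Sp2_b"], hits)
        assert len(fams) == 1
        assert fams[0].anchor_ids == ["Sp1_a", "Sp2_b"]

    def test_each_id_in_at_most_one_family(self, rng):
        ids = [f"Sp{i%3}_g{i}" for i in range(12)]
        hits = []
        for _ in range(10):
            q, s = rng.choice(ids, 2, replace=False)
            hits.append(_hit(q, s))
        fams = hm.cluster_families(ids, hits)
        seen = list(itertools.chain.from_iterable(f.member_ids for f in fams))
        assert len(seen) == len(set(seen))


class TestSelection:
    def _family(self, n_species):
        species = [f"S{i}" for i in range(n_species)]
        return hm.GeneFamily(
            family_id="f", member_ids=[f"{s}_g" for s in species],
            species_present=set(species),
        )

    def test_four_of_six_kept(self):
        assert hm.select_qualifying_genes([self._family(4)]) != []

    def test_three_of_six_dropped(self):
        assert hm.select_qualifying_genes([self._family(3)]) == []

    def test_zero_threshold_is_identity(self):
        fams = [self._family(1), self._family(2)]
        assert hm.select_qualifying_genes(fams, min_species=0) == fams

    def test_min_exceeding_total_errors(self):
        with pytest.raises(ValueError):
            hm.select_qualifying_genes([], min_species=7, total_species=6)


class TestIO:
    def test_hits_tsv_round_trip(self, tmp_path):
        hits = [_hit("a", "b"), _hit("b", "c", ident=75.5, e=1e-60)]
        path = tmp_path / "hits.tsv"
        hm.write_hits_tsv(hits, path)
        back = hm.read_hits_tsv(path)
        assert [h.query_id for h in back] == ["a", "b"]
        assert back[1].pct_identity == pytest.approx(75.5)

    def test_gff3_order_index_by_start(self, tmp_path):
        gff = tmp_path / "genes.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t5000\t6000\t.\t+\t.\tID=g2\n"
            "chr1\tsrc\tgene\t100\t900\t.\t+\t.\tID=g1\n"
            "chr2\tsrc\tgene\t10\t90\t.\t-\t.\tID=g3\n"
            "chr1\tsrc\tmRNA\t100\t900\t.\t+\t.\tID=t1\n"
        )
        df = hm.read_gff3_positions(gff, species="Mt")
        by_id = df.set_index("id")
        assert by_id.loc["g1", "order_index"] == 1
        assert by_id.loc["g2", "order_index"] == 2
        assert by_id.loc["g3", "order_index"] == 1
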