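"""Greedy clustering thresholds, the coverage gate, capped expansion."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import mutate, random_protein, record
from oracle_align import biopython_identity_overlap
from siftsforge.errors import InvalidInputError
from siftsforge.seq import AlignmentParams, SequenceCollection
from siftsforge.structure import ChainModel, ResidueRef
from siftsforge.uniref import (
    Cluster,
    admit_sequence,
    expand_cluster,
    expansion_gate,
    greedy_cluster,
    read_cluster_table,
    score_expansion,
    write_cluster_table,
)


class TestAdmitSequence:
    @pytest.mark.parametrize("length,admitted", [(11, True), (10, False), (1, False)])
    def test_strict_length_threshold(self, length, admitted):
        assert admit_sequence(record("A1", "A" * length)) is admitted


class TestGreedyCluster:
    def test_identical_pair_one_cluster(self):
        recs = [record("A1", "MKTAYIAKQRQISFVK"), record("A2", "MKTAYIAKQRQISFVK")]
        (cluster,) = greedy_cluster(recs)
        assert cluster.seed_accession == "A1"
        assert set(cluster.members) == {"A1", "A2"}
        assert cluster.cluster_id == "UR90_A1"

    def test_low_identity_founds_new_cluster(self):
        rng = np.random.default_rng(31)
        seed = random_protein(rng, 100)
        diverged = mutate(rng, seed, 15)  # 85% identity
        clusters = greedy_cluster([record("A1", seed), record("A2", diverged)])
        assert len(clusters) == 2

    def test_borderline_identity_admitted(self):
        rng = np.random.default_rng(32)
        seed = random_protein(rng, 100)
        member = mutate(rng, seed, 10)  # exactly 90%
        clusters = greedy_cluster([record("A1", seed), record("A2", member)])
        assert len(clusters) == 1

    def test_short_fragment_fails_overlap(self):
        # 95%-identical fragment covering 75% of the seed: overlap to the
        # longest sequence is below 80%, so it founds its own cluster
        rng = np.random.default_rng(33)
        seed = random_protein(rng, 200)
        frag = mutate(rng, seed[:150], 7)
        clusters = greedy_cluster([record("A1", seed), record("A2", frag)])
        assert len(clusters) == 2

    def test_long_fragment_passes_overlap(self):
        rng = np.random.default_rng(34)
        seed = random_protein(rng, 200)
        frag = mutate(rng, seed[:170], 8)  # 85% of seed length, ~95% identity
        clusters = greedy_cluster([record("A1", seed), record("A2", frag)])
        assert len(clusters) == 1

    def test_shorter_denominator_config_switch(self):
        rng = np.random.default_rng(35)
        seed = random_protein(rng, 200)
        frag = mutate(rng, seed[:150], 7)
        clusters = greedy_cluster(
            [record("A1", seed), record("A2", frag)],
            overlap_denominator="shorter",
        )
        assert len(clusters) == 1  # fragment fully aligned to the seed

    def test_too_short_sequence_rejected(self):
        with pytest.raises(InvalidInputError):
            greedy_cluster([record("A1", "MKTAYIAKQRQ"), record("A2", "MKTAY")])

    def test_empty_input(self):
        assert greedy_cluster([]) == []

    def test_order_invariant(self):
        rng = np.random.default_rng(36)
        recs = []
        for i in range(6):
            seed = random_protein(rng, int(rng.integers(80, 140)))
            recs.append(record(f"S{i}", seed))
            recs.append(record(f"S{i}M", mutate(rng, seed, 4)))
        ref = greedy_cluster(recs)
        perm = [recs[i] for i in rng.permutation(len(recs))]
        assert greedy_cluster(perm) == ref

    def test_members_verified_by_independent_recompute(self):
        """Every emitted member re-checked against 90/80 with a library
        aligner (all-pairs identity recomputation)."""
        rng = np.random.default_rng(37)
        recs = []
        for i in range(5):
            seed = random_protein(rng, int(rng.integers(120, 180)))
            recs.append(record(f"S{i}", seed))
            for j in range(3):
                n_sub = int(rng.integers(0, 25))
                recs.append(record(f"S{i}M{j}", mutate(rng, seed, n_sub)))
        params = AlignmentParams()
        by_acc = {r.accession: r for r in recs}
        for cluster in greedy_cluster(recs):
            seed_rec = by_acc[cluster.seed_accession]
            assert seed_rec.length == max(by_acc[m].length for m in cluster.members)
            for m in cluster.members:
                if m == cluster.seed_accession:
                    continue
                ident, n_cols = biopython_identity_overlap(
                    by_acc[m].sequence, seed_rec.sequence, params)
                assert ident >= 0.90
                assert n_cols / seed_rec.length >= 0.80


class TestExpansionGate:
    @pytest.mark.parametrize("cov,expected", [
        (0.71, True), (0.70, False), (0.0, False), (1.0, True),
    ])
    def test_strictly_greater_than_70(self, cov, expected):
        assert expansion_gate(cov) is expected

    @pytest.mark.parametrize("cov", [-0.1, 1.1])
    def test_out_of_range_rejected(self, cov):
        with pytest.raises(InvalidInputError):
            expansion_gate(cov)


def _dummy_collection(n, taxa):
    coll = SequenceCollection()
    for i in range(n):
        coll.add(record(f"D{i:05d}", "MKTAYIAKQRQIS",
                        taxonomy_id=9000 + i % taxa))
    return coll


class TestExpandCluster:
    def test_at_cap_returns_all_members(self):
        coll = _dummy_collection(5000, 3)
        members = tuple(sorted(r.accession for r in coll))
        cluster = Cluster("UR90_D00000", "D00000", members)
        assert expand_cluster(cluster, coll, seed=5) == sorted(members)

    def test_above_cap_one_per_taxon(self):
        coll = _dummy_collection(5001, 7)
        members = tuple(sorted(r.accession for r in coll))
        cluster = Cluster("UR90_D00000", "D00000", members)
        chosen = expand_cluster(cluster, coll, seed=5)
        assert len(chosen) == 7
        taxa = [coll.get(a).taxonomy_id for a in chosen]
        assert sorted(taxa) == sorted(set(taxa))  # exactly one per taxon

    def test_subsampling_reproducible(self):
        coll = _dummy_collection(5001, 7)
        members = tuple(sorted(r.accession for r in coll))
        cluster = Cluster("UR90_D00000", "D00000", members)
        assert expand_cluster(cluster, coll, seed=9) == \
            expand_cluster(cluster, coll, seed=9)

    def test_empty_cluster(self):
        cluster = Cluster("UR90_X", "X", ())
        assert expand_cluster(cluster, SequenceCollection(), seed=1) == []


class TestScoreExpansion:
    def make_chain(self, seq):
        residues = tuple(ResidueRef("A", i, "", i, True)
                         for i in range(1, len(seq) + 1))
        return ChainModel("1abc", "A", seq, residues)

    def test_identical_member_scores_one(self):
        rng = np.random.default_rng(41)
        seq = random_protein(rng, 80)
        coll = SequenceCollection([record("M1", seq)])
        chain = self.make_chain(seq)
        (res,) = score_expansion(chain, [("M1", "UR90_M1")], coll)
        assert res.identity_to_query == 1.0
        assert res.cluster_id == "UR90_M1"

    def test_substituted_member_identity(self):
        rng = np.random.default_rng(42)
        seq = random_protein(rng, 100)
        coll = SequenceCollection([record("M1", mutate(rng, seq, 5))])
        (res,) = score_expansion(self.make_chain(seq), [("M1", "C")], coll)
        assert res.identity_to_query == pytest.approx(0.95)

    def test_empty_accession_set(self):
        assert score_expansion(self.make_chain("MKTAY"), [],
                               SequenceCollection()) == []

    def test_sorted_by_identity_then_accession(self):
        rng = np.random.default_rng(43)
        seq = random_protein(rng, 100)
        coll = SequenceCollection([
            record("B", mutate(rng, seq, 10)),
            record("A", mutate(rng, seq, 10)),
            record("C", seq),
        ])
        results = score_expansion(
            self.make_chain(seq), [("B", "X"), ("A", "X"), ("C", "X")], coll)
        assert results[0].accession == "C"
        assert [r.accession for r in results[1:]] == \
            sorted(r.accession for r in results[1:])


class TestClusterTable:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(44)
        recs = []
        for i in range(3):
            seed = random_protein(rng, 100)
            recs.append(record(f"S{i}", seed, taxonomy_id=9000 + i))
            recs.append(record(f"S{i}M", mutate(rng, seed, 3),
                               taxonomy_id=9000 + i))
        coll = SequenceCollection(recs)
        clusters = greedy_cluster(recs)
        path = tmp_path / "clusters.tsv"
        write_cluster_table(clusters, coll, path)
        assert read_cluster_table(path) == clusters
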