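"""Isoform expansion, best-candidate selection, residue-level mappings."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from conftest import mutate, random_protein, record
from siftsforge.errors import (
    ConsistencyError,
    InvalidInputError,
    MissingAccessionError,
)
from siftsforge.mapping import (
    ManualXref,
    MappingCandidate,
    best_mapping,
    build_residue_mapping,
    detect_chimera,
    expand_isoform_set,
    map_chain,
    observed_only,
)
from siftsforge.seq import SequenceCollection, align_pair
from siftsforge.structure import ChainModel, ResidueRef


def make_chain(seq, unobserved=(), entry="1abc", chain="A"):
    residues = tuple(
        ResidueRef(chain, i, "", i, i not in unobserved)
        for i in range(1, len(seq) + 1)
    )
    return ChainModel(entry, chain, seq, residues)


@pytest.fixture(scope="module")
def isoform_collection():
    """One protein group: canonical (200 aa) + 3 isoforms, plus an unrelated
    protein for chimera tests."""
    rng = np.random.default_rng(21)
    canon = random_protein(rng, 200)
    iso2 = canon[:80] + canon[110:]          # exon-skip deletion
    iso3 = mutate(rng, canon, 6)             # substitutions only
    iso4 = mutate(rng, canon[:60] + canon[75:], 3)
    other = random_protein(rng, 150)
    coll = SequenceCollection([
        record("P10000", canon, is_canonical=True, taxonomy_id=9606),
        record("P10000-2", iso2, is_canonical=False,
               parent_accession="P10000", taxonomy_id=9606),
        record("P10000-3", iso3, is_canonical=False,
               parent_accession="P10000", taxonomy_id=9606),
        record("P10000-4", iso4, is_canonical=False,
               parent_accession="P10000", taxonomy_id=9606),
        record("Q20000", other, is_canonical=True, taxonomy_id=10090),
    ])
    coll.validate()
    return coll


class TestDetectChimera:
    def test_single_accession_whole_chain(self):
        assert detect_chimera([ManualXref("1abc", "A", "P10000")]) is False

    def test_two_accessions_on_distinct_segments(self):
        xrefs = [
            ManualXref("1abc", "A", "P10000", 1, 100),
            ManualXref("1abc", "A", "Q20000", 101, 180),
        ]
        assert detect_chimera(xrefs) is True

    def test_same_accession_overlapping_segments(self):
        xrefs = [
            ManualXref("1abc", "A", "P10000", 1, 100),
            ManualXref("1abc", "A", "P10000", 50, 180),
        ]
        assert detect_chimera(xrefs) is False

    def test_isoforms_of_same_parent_not_chimeric(self):
        xrefs = [
            ManualXref("1abc", "A", "P10000-2", 1, 100),
            ManualXref("1abc", "A", "P10000-3", 101, 180),
        ]
        assert detect_chimera(xrefs) is False

    def test_empty_list_rejected(self):
        with pytest.raises(InvalidInputError):
            detect_chimera([])

    def test_mixed_chains_rejected(self):
        with pytest.raises(InvalidInputError):
            detect_chimera([
                ManualXref("1abc", "A", "P10000"),
                ManualXref("1abc", "B", "Q20000"),
            ])


class TestExpandIsoformSet:
    def test_non_chimeric_pulls_whole_group(self, isoform_collection):
        recs = expand_isoform_set(
            [ManualXref("1abc", "A", "P10000")], isoform_collection, False
        )
        assert [r.accession for r in recs] == \
            ["P10000", "P10000-2", "P10000-3", "P10000-4"]

    def test_isoform_xref_also_pulls_whole_group(self, isoform_collection):
        recs = expand_isoform_set(
            [ManualXref("1abc", "A", "P10000-3")], isoform_collection, False
        )
        assert len(recs) == 4

    def test_chimeric_keeps_only_curated(self, isoform_collection):
        xrefs = [
            ManualXref("1abc", "A", "P10000", 1, 100),
            ManualXref("1abc", "A", "Q20000", 101, 175),
        ]
        recs = expand_isoform_set(xrefs, isoform_collection, True)
        assert {r.accession for r in recs} == {"P10000", "Q20000"}

    def test_unknown_accession_named_in_error(self, isoform_collection):
        with pytest.raises(MissingAccessionError, match="P99999"):
            expand_isoform_set(
                [ManualXref("1abc", "A", "P99999")], isoform_collection, False
            )


def _candidate(acc, identity, canonical=False):
    aln = align_pair("ACDEF", "ACDEF")
    return MappingCandidate(accession=acc, is_canonical=canonical,
                           alignment=aln, identity=identity, coverage=None)


class TestBestMapping:
    def test_highest_identity_wins(self):
        best = best_mapping([
            _candidate("P1", 0.95, canonical=True),
            _candidate("P1-2", 0.98),
        ])
        assert best.accession == "P1-2"

    def test_exact_tie_prefers_canonical(self):
        best = best_mapping([
            _candidate("P1-2", 0.97),
            _candidate("P1", 0.97, canonical=True),
        ])
        assert best.accession == "P1"

    def test_tie_among_isoforms_breaks_lexicographically(self):
        best = best_mapping([
            _candidate("P1-3", 0.97),
            _candidate("P1-2", 0.97),
        ])
        assert best.accession == "P1-2"

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            best_mapping([])

    def test_permutation_invariant(self):
        cands = [
            _candidate("P1", 0.90, canonical=True),
            _candidate("P1-2", 0.95),
            _candidate("P1-3", 0.95),
            _candidate("P1-4", 0.80),
        ]
        winners = {best_mapping(list(p)).accession
                   for p in itertools.permutations(cands)}
        assert winners == {"P1-2"}


class TestBuildResidueMapping:
    def test_perfect_alignment_single_segment(self):
        chain = make_chain("MKTAYIAKQR")
        aln = align_pair(chain.construct_sequence, "MKTAYIAKQR")
        m = build_residue_mapping(chain, aln)
        assert len(m.pairs) == len(aln.pairs) == 10
        assert m.segments == ((1, 10, 1, 10),)

    def test_target_deletion_splits_segments(self):
        chain = make_chain("MKTAYIAKQRQISFVKSHFS")
        target = chain.construct_sequence[:8] + chain.construct_sequence[11:]
        aln = align_pair(chain.construct_sequence, target)
        m = build_residue_mapping(chain, aln)
        assert len(m.segments) == 2
        assert m.segments[0][:2] == (1, 8)
        assert m.segments[1][:2] == (12, 20)
        # within every segment both coordinates advance in lock-step
        for rb, re_, ub, ue in m.segments:
            assert re_ - rb == ue - ub

    def test_query_mismatch_with_chain_rejected(self):
        chain = make_chain("MKTAY")
        aln = align_pair("MKTAYIAKQR", "MKTAYIAKQR")
        with pytest.raises(ConsistencyError):
            build_residue_mapping(chain, aln)


class TestObservedOnly:
    def test_all_observed_is_identity(self):
        chain = make_chain("MKTAYIAKQR")
        m = build_residue_mapping(
            chain, align_pair(chain.construct_sequence, "MKTAYIAKQR"))
        assert observed_only(m) == m

    def test_internal_loop_splits_segment(self):
        chain = make_chain("MKTAYIAKQR", unobserved={5, 6, 7})
        m = build_residue_mapping(
            chain, align_pair(chain.construct_sequence, "MKTAYIAKQR"))
        mo = observed_only(m)
        assert [seg[:2] for seg in mo.segments] == [(1, 4), (8, 10)]
        assert len(mo.pairs) == 7

    def test_idempotent(self):
        chain = make_chain("MKTAYIAKQR", unobserved={2, 9})
        m = build_residue_mapping(
            chain, align_pair(chain.construct_sequence, "MKTAYIAKQR"))
        assert observed_only(observed_only(m)) == observed_only(m)

    def test_nothing_observed_empty_mapping(self):
        chain = make_chain("MKTAY", unobserved={1, 2, 3, 4, 5})
        m = build_residue_mapping(
            chain, align_pair(chain.construct_sequence, "MKTAY"))
        mo = observed_only(m)
        assert mo.pairs == ()
        assert mo.segments == ()


class TestMapChain:
    def test_recovers_planted_isoform(self, isoform_collection):
        # chain cut verbatim from isoform 3 (substitutions distinguish it)
        iso3 = isoform_collection.get("P10000-3")
        chain = make_chain(iso3.sequence[10:190])
        xrefs = [ManualXref("1abc", "A", "P10000")]
        best, mapping, cands = map_chain(chain, xrefs, isoform_collection)
        assert best.accession == "P10000-3"
        assert best.identity == 1.0
        assert len(cands) == 4
        assert mapping.accession == "P10000-3"

    def test_coverage_only_on_canonical_candidates(self, isoform_collection):
        iso3 = isoform_collection.get("P10000-3")
        chain = make_chain(iso3.sequence[10:190])
        _, _, cands = map_chain(
            chain, [ManualXref("1abc", "A", "P10000")], isoform_collection)
        for c in cands:
            assert (c.coverage is not None) == c.is_canonical

    def test_chimeric_chain_candidates_not_expanded(self, isoform_collection):
        canon = isoform_collection.get("P10000").sequence
        other = isoform_collection.get("Q20000").sequence
        construct = canon[:100] + other[:75]
        chain = make_chain(construct)
        xrefs = [
            ManualXref("1abc", "A", "P10000", 1, 100),
            ManualXref("1abc", "A", "Q20000", 101, 175),
        ]
        _, _, cands = map_chain(chain, xrefs, isoform_collection)
        assert {c.accession for c in cands} == {"P10000", "Q20000"}

    def test_chain_without_xref_is_lookup_error(self, isoform_collection):
        chain = make_chain("MKTAYIAKQR", entry="9zzz")
        with pytest.raises(MissingAccessionError):
            map_chain(chain, [ManualXref("1abc", "A", "P10000")],
                      isoform_collection)

    def test_pair_count_conserved(self, isoform_collection):
        iso2 = isoform_collection.get("P10000-2")
        chain = make_chain(iso2.sequence)
        best, mapping, _ = map_chain(
            chain, [ManualXref("1abc", "A", "P10000")], isoform_collection)
        assert len(mapping.pairs) == len(best.alignment.pairs)
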