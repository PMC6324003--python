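"""UniRef90-style clustering and the chain-to-cluster expansion route.

A cluster groups sequences at >= 90% identity and >= 80% overlap to its
*seed*, the longest member.  Expansion for a chain works in three steps:

1. compute the coverage of the chain's canonical accession by the chain;
2. if that coverage exceeds 70% (strictly), pull every accession from the
   cluster(s) containing the canonical accession — clusters above 5000
   members are thinned to one randomly chosen accession per taxonomy id;
3. align the chain against every pulled accession and report its identity.

Clustering is an incremental greedy scheme over length-sorted input with
exact dynamic-programming identity to the seed (no k-mer prefilter): inputs
at desk scale are small enough that exactness is affordable, and it matches
the printed thresholds with no heuristic slack.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

import numpy as np

from .errors import InvalidInputError, ParseError
from .seq import (
    AlignmentParams,
    SequenceCollection,
    SequenceRecord,
    align_pair,
)
from .structure import ChainModel

MIN_LENGTH = 10  # sequences must be strictly longer than this to be clustered
IDENTITY_THRESHOLD = 0.90
OVERLAP_THRESHOLD = 0.80
CLUSTER_SIZE_CAP = 5000  # full expansion up to this size; beyond it, subsample
COVERAGE_GATE = 0.70


@dataclass(frozen=True, slots=True)
class Cluster:
    """A seed-anchored sequence cluster (seed included in ``members``)."""

    cluster_id: str
    seed_accession: str
    members: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True, slots=True)
class ExpansionResult:
    """One accession reachable from a chain through a cluster, with its
    identity to the chain's construct sequence."""

    entry_id: str
    chain_id: str
    accession: str
    cluster_id: str
    identity_to_query: float


def admit_sequence(rec: SequenceRecord) -> bool:
    """Clustering admission filter: strictly more than ``MIN_LENGTH`` residues."""
    return rec.length > MIN_LENGTH


def member_overlap(aln_pairs_count: int, member_length: int, seed_length: int,
                   denominator: str = "seed") -> float:
    """Overlap fraction of a member against its seed.

    ``denominator`` selects the convention: ``seed`` divides the aligned
    column count by the seed (longest-sequence) length — the definition used
    for membership — while ``shorter`` divides by the shorter of the two.
    """
    if denominator == "seed":
        return aln_pairs_count / seed_length
    if denominator == "shorter":
        return aln_pairs_count / min(member_length, seed_length)
    raise InvalidInputError(f"unknown overlap denominator {denominator!r}")


def greedy_cluster(
    records: Iterable[SequenceRecord],
    id_thresh: float = IDENTITY_THRESHOLD,
    overlap_thresh: float = OVERLAP_THRESHOLD,
    params: AlignmentParams | None = None,
    overlap_denominator: str = "seed",
) -> list[Cluster]:
    """Incremental greedy clustering against cluster seeds.

    Records are sorted by length descending (ties by accession); each joins
    the first existing cluster whose seed it matches at ``>= id_thresh``
    identity and ``>= overlap_thresh`` overlap, else founds a new cluster.
    The length sort makes the outcome invariant to input order.  Records
    failing :func:`admit_sequence` are rejected with an error.
    """
    params = params or AlignmentParams(mode="semiglobal")
    recs = sorted(records, key=lambda r: (-r.length, r.accession))
    if not recs:
        return []
    short = [r.accession for r in recs if not admit_sequence(r)]
    if short:
        raise InvalidInputError(
            f"sequences too short to cluster (need > {MIN_LENGTH} residues): {short}"
        )
    seeds: list[SequenceRecord] = []
    members: list[list[str]] = []
    for rec in recs:
        placed = False
        for k, seed in enumerate(seeds):
            if rec.accession == seed.accession:
                continue
            aln = align_pair(rec, seed, params)
            overlap = member_overlap(len(aln.pairs), rec.length, seed.length,
                                     overlap_denominator)
            if aln.identity >= id_thresh and overlap >= overlap_thresh:
                members[k].append(rec.accession)
                placed = True
                break
        if not placed:
            seeds.append(rec)
            members.append([rec.accession])
    return [
        Cluster(
            cluster_id=f"UR90_{seed.accession}",
            seed_accession=seed.accession,
            members=tuple(mem),
        )
        for seed, mem in zip(seeds, members)
    ]


def expansion_gate(coverage: float) -> bool:
    """True iff canonical coverage strictly exceeds the 70% gate."""
    if not (0.0 <= coverage <= 1.0):
        raise InvalidInputError(f"coverage {coverage} outside [0, 1]")
    return coverage > COVERAGE_GATE


def expand_cluster(
    cluster: Cluster,
    records: SequenceCollection,
    cap: int = CLUSTER_SIZE_CAP,
    seed: int = 0,
) -> list[str]:
    """Accessions contributed by a cluster.

    Clusters of at most ``cap`` members contribute everything; larger ones
    contribute exactly one uniformly chosen member per distinct taxonomy id
    (seeded, hence reproducible).  Output sorted by accession.
    """
    if cluster.size <= cap:
        return sorted(cluster.members)
    by_taxon: dict[int, list[str]] = {}
    for acc in cluster.members:
        by_taxon.setdefault(records.get(acc).taxonomy_id, []).append(acc)
    rng = np.random.default_rng(seed)
    chosen = []
    for taxon in sorted(by_taxon):
        accs = sorted(by_taxon[taxon])
        chosen.append(accs[int(rng.integers(len(accs)))])
    return sorted(chosen)


def score_expansion(
    chain: ChainModel,
    accessions: Iterable[tuple[str, str]],
    records: SequenceCollection,
    params: AlignmentParams | None = None,
) -> list[ExpansionResult]:
    """Align the chain against ``(accession, cluster_id)`` pairs and score.

    Sorted by identity descending, then accession ascending.
    """
    params = params or AlignmentParams()
    out = []
    for acc, cluster_id in accessions:
        rec = records.get(acc)
        aln = align_pair(chain.construct_sequence, rec, params)
        out.append(ExpansionResult(
            entry_id=chain.entry_id,
            chain_id=chain.chain_id,
            accession=acc,
            cluster_id=cluster_id,
            identity_to_query=aln.identity,
        ))
    out.sort(key=lambda r: (-r.identity_to_query, r.accession))
    return out


def clusters_by_member(clusters: Iterable[Cluster]) -> dict[str, list[Cluster]]:
    """Member accession -> clusters containing it (one-to-many lookup)."""
    index: dict[str, list[Cluster]] = {}
    for cl in clusters:
        for acc in cl.members:
            index.setdefault(acc, []).append(cl)
    return index


def expand_for_chain(
    chain: ChainModel,
    canonical_accession: str,
    canonical_coverage: float,
    member_index: dict[str, list[Cluster]],
    records: SequenceCollection,
    params: AlignmentParams | None = None,
    cap: int = CLUSTER_SIZE_CAP,
    seed: int = 0,
) -> list[ExpansionResult]:
    """Full expansion route for one chain; empty when the gate fails or the
    canonical accession is unclustered."""
    if not expansion_gate(canonical_coverage):
        return []
    pulled: dict[str, str] = {}
    for cl in member_index.get(canonical_accession, []):
        for acc in expand_cluster(cl, records, cap=cap, seed=seed):
            pulled.setdefault(acc, cl.cluster_id)
    return score_expansion(chain, sorted(pulled.items()), records, params)


# ---------------------------------------------------------------------------
# cluster table TSV I/O

CLUSTER_COLUMNS = ("cluster_id", "seed_accession", "member_accession", "taxonomy_id")


def write_cluster_table(
    clusters: Iterable[Cluster],
    records: SequenceCollection,
    path: Union[str, Path],
) -> None:
    lines = ["\t".join(CLUSTER_COLUMNS)]
    for cl in clusters:
        for acc in cl.members:
            taxid = records.get(acc).taxonomy_id if acc in records else 0
            lines.append(f"{cl.cluster_id}\t{cl.seed_accession}\t{acc}\t{taxid}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_cluster_table(path: Union[str, Path]) -> list[Cluster]:
    """Read precomputed cluster memberships (alternative to clustering)."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or tuple(lines[0].split("\t")) != CLUSTER_COLUMNS:
        raise ParseError(f"{path}: expected header {CLUSTER_COLUMNS}")
    seeds: dict[str, str] = {}
    members: dict[str, list[str]] = {}
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise ParseError(f"{path}:{ln}: expected 4 tab-separated fields")
        cid, seed_acc, member, _taxid = fields
        if cid in seeds and seeds[cid] != seed_acc:
            raise ParseError(f"{path}:{ln}: conflicting seed for cluster {cid!r}")
        seeds[cid] = seed_acc
        members.setdefault(cid, []).append(member)
    return [
        Cluster(cluster_id=cid, seed_accession=seeds[cid], members=tuple(mem))
        for cid, mem in members.items()
    ]
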