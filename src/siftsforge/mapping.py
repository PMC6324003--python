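"""Chain-to-sequence mapping: isoform expansion, best-candidate selection,
and residue-level mapping construction.

The per-chain procedure is:

1. start from the manually curated cross-reference(s) of the chain;
2. expand the candidate set with every isoform of the referenced
   accession(s) — unless the chain is a chimeric construct, in which case
   the set stays exactly the curated accessions;
3. align the chain construct sequence against every candidate and compute
   sequence identity (plus coverage, for canonical candidates only);
4. pick the best candidate: highest identity, ties going to the canonical
   accession;
5. turn the winning alignment into a residue-level mapping partitioned into
   segments contiguous in both coordinate systems.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Union

from .errors import ConsistencyError, InvalidInputError, MissingAccessionError, ParseError
from .seq import (
    AlignmentParams,
    PairwiseAlignment,
    SequenceCollection,
    SequenceRecord,
    align_pair,
    coverage_of,
)
from .structure import ChainModel, ResidueRef


@dataclass(frozen=True, slots=True)
class ManualXref:
    """A curated chain-to-accession cross-reference.

    ``start``/``end`` restrict it to a seqres-index range of the chain;
    both ``None`` means the whole chain.
    """

    entry_id: str
    chain_id: str
    accession: str
    start: Optional[int] = None
    end: Optional[int] = None

    def segment(self, chain_length: int) -> tuple[int, int]:
        s = 1 if self.start is None else self.start
        e = chain_length if self.end is None else self.end
        if not (1 <= s <= e <= chain_length):
            raise InvalidInputError(
                f"xref segment ({s},{e}) outside chain of length {chain_length}"
            )
        return s, e


@dataclass(frozen=True, slots=True)
class MappingCandidate:
    """One scored candidate accession for a chain."""

    accession: str
    is_canonical: bool
    alignment: PairwiseAlignment
    identity: float
    coverage: Optional[float]  # canonical targets only


@dataclass(frozen=True, slots=True)
class ResidueMapping:
    """Residue-level chain-to-sequence correspondence.

    ``pairs`` maps each aligned construct residue to its 1-based sequence
    position; ``segments`` are maximal runs contiguous in *both* coordinates,
    given as ``(seqres_start, seqres_end, uniprot_start, uniprot_end)``.
    """

    entry_id: str
    chain_id: str
    accession: str
    pairs: tuple[tuple[ResidueRef, int], ...]
    segments: tuple[tuple[int, int, int, int], ...]


def _segments_from_pairs(
    pairs: Iterable[tuple[ResidueRef, int]],
) -> tuple[tuple[int, int, int, int], ...]:
    segs = []
    cur = None
    for ref, upos in pairs:
        q = ref.seqres_index
        if cur is not None and q == cur[1] + 1 and upos == cur[3] + 1:
            cur = (cur[0], q, cur[2], upos)
        else:
            if cur is not None:
                segs.append(cur)
            cur = (q, q, upos, upos)
    if cur is not None:
        segs.append(cur)
    return tuple(segs)


def _parent_of(accession: str, collection: SequenceCollection | None) -> str:
    if collection is not None and accession in collection:
        return collection.get(accession).parent_accession
    # UniProt-style isoform suffix: P12345-2 -> P12345
    return accession.split("-", 1)[0]


def detect_chimera(
    xrefs: list[ManualXref],
    collection: SequenceCollection | None = None,
) -> bool:
    """True iff the curated xrefs place >= 2 distinct parent accessions on
    non-identical chain segments (the operational reading of an engineered
    chimeric construct).

    Parent accessions resolve through ``collection`` when given, else by the
    UniProt-style ``-N`` isoform suffix convention.
    """
    if not xrefs:
        raise InvalidInputError("empty manual cross-reference list")
    if len({(x.entry_id, x.chain_id) for x in xrefs}) != 1:
        raise InvalidInputError("manual xrefs reference more than one chain")
    parents = {_parent_of(x.accession, collection) for x in xrefs}
    if len(parents) < 2:
        return False
    spans = {(x.start, x.end) for x in xrefs}
    return len(spans) > 1


def expand_isoform_set(
    xrefs: list[ManualXref],
    collection: SequenceCollection,
    chimeric: bool,
) -> list[SequenceRecord]:
    """Candidate sequence set for a chain.

    Chimeric chains keep exactly the curated accessions; otherwise each
    curated accession pulls in its whole isoform group (canonical + all
    isoforms).  Output is deterministic: canonical records first, then by
    accession.
    """
    out: dict[str, SequenceRecord] = {}
    for x in xrefs:
        if chimeric:
            rec = collection.get(x.accession)
            out[rec.accession] = rec
        else:
            for rec in collection.isoform_group(x.accession):
                out[rec.accession] = rec
    recs = list(out.values())
    recs.sort(key=lambda r: (not r.is_canonical, r.accession))
    return recs


def best_mapping(candidates: list[MappingCandidate]) -> MappingCandidate:
    """Highest-identity candidate; exact ties prefer the canonical accession,
    then the lexicographically smallest accession.  Permutation-invariant."""
    if not candidates:
        raise InvalidInputError("no mapping candidates")
    return min(
        candidates,
        key=lambda c: (-c.identity, not c.is_canonical, c.accession),
    )


def build_residue_mapping(chain: ChainModel, aln: PairwiseAlignment) -> ResidueMapping:
    """Lift an alignment of the construct sequence into residue space."""
    if aln.query_length != len(chain.construct_sequence):
        raise ConsistencyError(
            f"alignment query length {aln.query_length} != construct length "
            f"{len(chain.construct_sequence)} for {chain.entry_id}/{chain.chain_id}"
        )
    by_idx = {r.seqres_index: r for r in chain.residues}
    pairs = []
    for qpos, tpos in aln.pairs:
        if qpos not in by_idx:
            raise ConsistencyError(
                f"alignment references seqres index {qpos} with no residue in "
                f"{chain.entry_id}/{chain.chain_id}"
            )
        pairs.append((by_idx[qpos], tpos))
    return ResidueMapping(
        entry_id=chain.entry_id,
        chain_id=chain.chain_id,
        accession=aln.target_id,
        pairs=tuple(pairs),
        segments=_segments_from_pairs(pairs),
    )


def observed_only(mapping: ResidueMapping) -> ResidueMapping:
    """Restrict a mapping to observed residues and recompute segments.

    Idempotent: applying it twice equals applying it once.
    """
    pairs = tuple(p for p in mapping.pairs if p[0].observed)
    return replace(mapping, pairs=pairs, segments=_segments_from_pairs(pairs))


def map_chain(
    chain: ChainModel,
    xrefs: list[ManualXref],
    collection: SequenceCollection,
    params: AlignmentParams | None = None,
) -> tuple[MappingCandidate, ResidueMapping, list[MappingCandidate]]:
    """Full per-chain mapping: expansion, scoring, selection, residue mapping.

    Returns ``(best, residue_mapping, all_candidates)``.  Candidates whose
    alignment has no aligned pairs are dropped before selection.
    """
    params = params or AlignmentParams()
    mine = [x for x in xrefs
            if (x.entry_id, x.chain_id) == (chain.entry_id, chain.chain_id)]
    if not mine:
        raise MissingAccessionError(
            f"no manual cross-reference for chain {chain.entry_id}/{chain.chain_id}"
        )
    chimeric = detect_chimera(mine, collection)
    records = expand_isoform_set(mine, collection, chimeric)
    candidates = []
    for rec in records:
        aln = align_pair(chain.construct_sequence, rec, params)
        aln = replace(aln, query_id=f"{chain.entry_id}_{chain.chain_id}",
                      target_id=rec.accession)
        if not aln.pairs:
            continue
        cov = coverage_of(aln, rec.length) if rec.is_canonical else None
        candidates.append(MappingCandidate(
            accession=rec.accession,
            is_canonical=rec.is_canonical,
            alignment=aln,
            identity=aln.identity,
            coverage=cov,
        ))
    best = best_mapping(candidates)
    mapping = build_residue_mapping(chain, best.alignment)
    return best, mapping, candidates


# ---------------------------------------------------------------------------
# manual cross-reference TSV I/O

XREF_COLUMNS = ("entry", "chain", "accession", "start", "end")


def read_manual_xrefs(path: Union[str, Path]) -> list[ManualXref]:
    """Read the curated cross-reference table (blank start/end = whole chain)."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or tuple(lines[0].split("\t")) != XREF_COLUMNS:
        raise ParseError(f"{path}: expected header {XREF_COLUMNS}")
    out = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise ParseError(f"{path}:{ln}: expected 5 tab-separated fields")
        entry, chain, acc, start, end = fields
        out.append(ManualXref(
            entry_id=entry,
            chain_id=chain,
            accession=acc,
            start=int(start) if start else None,
            end=int(end) if end else None,
        ))
    return out


def write_manual_xrefs(xrefs: Iterable[ManualXref], path: Union[str, Path]) -> None:
    lines = ["\t".join(XREF_COLUMNS)]
    for x in xrefs:
        lines.append("\t".join([
            x.entry_id, x.chain_id, x.accession,
            "" if x.start is None else str(x.start),
            "" if x.end is None else str(x.end),
        ]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
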