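"""Sequence records, collections, and the pairwise alignment engine.

Every downstream stage (isoform mapping, cluster building, cluster
expansion) consumes the two statistics defined here:

* **sequence identity** — identical aligned residue pairs over all aligned
  (non-gap) pairs; ambiguity letters (X/B/Z/U) never count as identical.
* **coverage of the target** — distinct aligned target positions over the
  full target length, i.e. what fraction of a UniProt-style sequence the
  query (a structure chain) accounts for.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from . import _align
from .errors import InvalidInputError, MissingAccessionError, ParseError

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUOUS_AA = "XUBZ"
ALPHABET = frozenset(STANDARD_AA + AMBIGUOUS_AA)

METADATA_COLUMNS = ("accession", "parent_accession", "is_canonical", "taxonomy_id")


def _check_sequence(seq: str, *, who: str = "sequence") -> None:
    if not seq:
        raise InvalidInputError(f"{who} is empty")
    for ch in seq:
        if ch not in ALPHABET:
            raise InvalidInputError(f"{who} contains invalid amino-acid symbol {ch!r}")


@dataclass(frozen=True, slots=True)
class SequenceRecord:
    """A protein sequence with its canonical/isoform bookkeeping.

    ``parent_accession`` names the canonical record of the isoform group;
    canonical records point at themselves.  ``xrefs`` carries pass-through
    cross-references (see :mod:`siftsforge.annotations`).
    """

    accession: str
    sequence: str
    is_canonical: bool = True
    parent_accession: str = ""
    taxonomy_id: int = 0
    xrefs: tuple = ()

    def __post_init__(self) -> None:
        _check_sequence(self.sequence, who=f"sequence of {self.accession!r}")
        if not self.accession:
            raise InvalidInputError("accession must be non-empty")
        if not self.parent_accession:
            object.__setattr__(self, "parent_accession", self.accession)

    @property
    def length(self) -> int:
        return len(self.sequence)


class SequenceCollection:
    """Accession-keyed set of :class:`SequenceRecord` with isoform grouping.

    Enforces accession uniqueness on insert; :meth:`validate` additionally
    checks that every isoform group has exactly one canonical member.
    """

    def __init__(self, records: Iterable[SequenceRecord] = ()) -> None:
        self._records: dict[str, SequenceRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: SequenceRecord) -> None:
        if rec.accession in self._records:
            raise InvalidInputError(f"duplicate accession {rec.accession!r}")
        self._records[rec.accession] = rec

    def get(self, accession: str) -> SequenceRecord:
        try:
            return self._records[accession]
        except KeyError:
            raise MissingAccessionError(
                f"accession {accession!r} not found in collection"
            ) from None

    def __contains__(self, accession: str) -> bool:
        return accession in self._records

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self._records.values())

    def __len__(self) -> int:
        return len(self._records)

    def isoform_group(self, accession: str) -> list[SequenceRecord]:
        """Canonical + all isoforms of the group containing ``accession``.

        Sorted canonical-first, then by accession, so expansion is
        deterministic regardless of insertion order.
        """
        parent = self.get(accession).parent_accession
        group = [r for r in self._records.values() if r.parent_accession == parent]
        group.sort(key=lambda r: (not r.is_canonical, r.accession))
        return group

    def validate(self) -> None:
        groups: dict[str, int] = {}
        for rec in self._records.values():
            groups.setdefault(rec.parent_accession, 0)
            if rec.is_canonical:
                groups[rec.parent_accession] += 1
        for parent, n_canon in sorted(groups.items()):
            if n_canon != 1:
                raise InvalidInputError(
                    f"isoform group {parent!r} has {n_canon} canonical records "
                    "(expected exactly 1)"
                )


@dataclass(frozen=True, slots=True)
class AlignmentParams:
    """Scoring scheme for :func:`align_pair`.

    Scores follow the maximisation convention: ``match_score`` positive,
    ``mismatch_score``/``gap_open``/``gap_extend`` non-positive; a gap of
    length L costs ``gap_open + L * gap_extend``.  ``semiglobal`` mode makes
    end gaps free in both sequences (constructs are routinely truncations of
    the full sequence, and carry tags the full sequence lacks).
    """

    match_score: float = 2.0
    mismatch_score: float = -1.0
    gap_open: float = -10.0
    gap_extend: float = -0.5
    mode: str = "semiglobal"

    def __post_init__(self) -> None:
        if self.mode not in ("global", "semiglobal"):
            raise InvalidInputError(f"unknown alignment mode {self.mode!r}")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise InvalidInputError("gap penalties must be <= 0 under the score convention")


@dataclass(frozen=True, slots=True)
class PairwiseAlignment:
    """Aligned position pairs plus the derived identity/coverage statistics.

    ``pairs`` holds 1-based ``(query_pos, target_pos)`` aligned columns,
    strictly increasing in both coordinates (gap positions are simply
    absent).  ``identity`` is identical pairs / aligned pairs (0 with no
    pairs); ``coverage_of_target`` is distinct target positions / target
    length.
    """

    query_id: str
    target_id: str
    pairs: tuple[tuple[int, int], ...]
    identity: float
    coverage_of_target: float
    score: float
    n_identical: int
    query_length: int
    target_length: int


def _encode(seq: str) -> tuple[np.ndarray, np.ndarray]:
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    amb = np.zeros(len(seq), dtype=np.bool_)
    for ch in AMBIGUOUS_AA:
        amb |= codes == ord(ch)
    return codes, amb


def _as_seq(obj: Union[SequenceRecord, str], default_id: str) -> tuple[str, str]:
    if isinstance(obj, SequenceRecord):
        return obj.accession, obj.sequence
    return default_id, obj


def align_pair(
    query: Union[SequenceRecord, str],
    target: Union[SequenceRecord, str],
    params: AlignmentParams | None = None,
) -> PairwiseAlignment:
    """Optimal pairwise alignment of ``query`` against ``target``.

    Affine-gap dynamic programming (Gotoh); deterministic traceback with a
    fixed tie-break (match/mismatch preferred over gap moves, gap-in-query
    over gap-in-target).  Accepts :class:`SequenceRecord` or bare strings.

    Raises
    ------
    InvalidInputError
        On empty sequences or characters outside the amino-acid alphabet.
    """
    params = params or AlignmentParams()
    qid, qseq = _as_seq(query, "query")
    tid, tseq = _as_seq(target, "target")
    _check_sequence(qseq, who=f"query {qid!r}")
    _check_sequence(tseq, who=f"target {tid!r}")

    q_codes, q_amb = _encode(qseq)
    t_codes, _ = _encode(tseq)
    score, pairs = _align.align_core(
        q_codes, t_codes, q_amb,
        params.match_score, params.mismatch_score,
        params.gap_open, params.gap_extend,
        params.mode == "semiglobal",
    )
    n_ident = sum(
        1 for (i, j) in pairs
        if qseq[i - 1] == tseq[j - 1] and qseq[i - 1] not in AMBIGUOUS_AA
    )
    n_pairs = len(pairs)
    return PairwiseAlignment(
        query_id=qid,
        target_id=tid,
        pairs=tuple(pairs),
        identity=(n_ident / n_pairs) if n_pairs else 0.0,
        coverage_of_target=(n_pairs / len(tseq)) if n_pairs else 0.0,
        score=score,
        n_identical=n_ident,
        query_length=len(qseq),
        target_length=len(tseq),
    )


def sequence_identity(aln: PairwiseAlignment) -> float:
    """Identical-pair fraction over aligned (non-gap) pairs; 0 when empty."""
    if not aln.pairs:
        return 0.0
    return aln.n_identical / len(aln.pairs)


def coverage_of(aln: PairwiseAlignment, target_length: int) -> float:
    """Fraction of a ``target_length``-residue sequence covered by the alignment."""
    if target_length <= 0:
        raise InvalidInputError("target_length must be positive")
    if aln.pairs and aln.pairs[-1][1] > target_length:
        raise InvalidInputError(
            f"target_length {target_length} smaller than max aligned target "
            f"position {aln.pairs[-1][1]}"
        )
    distinct = len({j for _, j in aln.pairs})
    return distinct / target_length


# ---------------------------------------------------------------------------
# FASTA + sidecar metadata I/O


def write_fasta(records: Iterable[SequenceRecord], path: Union[str, Path]) -> None:
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.accession, description="")
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def write_metadata(records: Iterable[SequenceRecord], path: Union[str, Path]) -> None:
    lines = ["\t".join(METADATA_COLUMNS)]
    for r in records:
        lines.append(
            f"{r.accession}\t{r.parent_accession}\t{int(r.is_canonical)}\t{r.taxonomy_id}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_collection(fasta_path: Union[str, Path], meta_path: Union[str, Path]) -> SequenceCollection:
    """Load a collection from a FASTA file and its sidecar metadata TSV."""
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    lines = Path(meta_path).read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ParseError(f"{meta_path}: empty metadata table")
    header = tuple(lines[0].rstrip("\n").split("\t"))
    if header != METADATA_COLUMNS:
        raise ParseError(
            f"{meta_path}: expected header {METADATA_COLUMNS}, got {header}"
        )
    coll = SequenceCollection()
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise ParseError(f"{meta_path}:{ln}: expected 4 tab-separated fields")
        acc, parent, canon, taxid = fields
        if acc not in seqs:
            raise ParseError(f"{meta_path}:{ln}: accession {acc!r} absent from FASTA")
        coll.add(SequenceRecord(
            accession=acc,
            sequence=seqs[acc],
            is_canonical=canon in ("1", "true", "True"),
            parent_accession=parent,
            taxonomy_id=int(taxid),
        ))
    missing = sorted(set(seqs) - {r.accession for r in coll})
    if missing:
        raise ParseError(f"{meta_path}: FASTA records without metadata: {missing}")
    coll.validate()
    return coll
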