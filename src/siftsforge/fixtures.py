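"""Seeded generator of toy archives with machine-readable ground truth.

The generator emulates the inputs the pipeline consumes in production-like
form — structure files with construct sequences and unobserved loops, a
FASTA + metadata sequence collection with canonical/isoform groups, curated
chain cross-references, chimeric constructs, and sequence sets at
controlled divergence for clustering — while planting the truth needed to
verify every stage: which isoform each chain was cut from, which residues
were left unmodelled, and which seed each cluster member descends from.

Everything is deterministic per seed: one global seed fans out to
per-component substreams, so regenerating any piece reproduces it byte for
byte.

What it does *not* emulate: realistic evolutionary divergence (substitutions
are uniform), splice-site biology (isoform deletions are uniform internal
spans), experimental noise in the construct sequence, or non-monotone author
numbering beyond a constant offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np

from .errors import InvalidInputError
from .mapping import ManualXref, write_manual_xrefs
from .seq import (
    STANDARD_AA,
    SequenceCollection,
    SequenceRecord,
    write_fasta,
    write_metadata,
)
from .structure import ChainModel, ResidueRef, observed_segments, write_pdb_min

_AA = np.frombuffer(STANDARD_AA.encode(), dtype=np.uint8)


@dataclass
class FixtureSpec:
    """Parameters of a synthetic archive.

    Defaults describe a mid-sized toy archive: 50 proteins of 150-250
    residues, one to three alternative isoforms each (internal exon-skip
    deletions of 10-30 residues plus sparse substitutions), chains cut
    verbatim from a randomly chosen isoform spanning 60-100% of it, up to
    two unobserved loops per chain, and a 10% chimera fraction.
    """

    seed: int = 0
    n_proteins: int = 50
    length_range: tuple[int, int] = (150, 250)
    isoforms_per_protein: tuple[int, int] = (1, 3)
    exon_skip_length: tuple[int, int] = (10, 30)
    exon_skips_per_isoform: tuple[int, int] = (1, 2)
    substitution_rate: float = 0.005
    chain_span_fraction: tuple[float, float] = (0.6, 1.0)
    unobserved_loops: tuple[int, int] = (0, 2)
    loop_length: tuple[int, int] = (2, 8)
    chimera_fraction: float = 0.1
    taxonomy_pool: int = 5

    def __post_init__(self) -> None:
        if not (0.0 <= self.chimera_fraction <= 1.0):
            raise InvalidInputError("chimera_fraction must lie in [0, 1]")
        if not (0.0 <= self.substitution_rate <= 1.0):
            raise InvalidInputError("substitution_rate must lie in [0, 1]")
        if self.length_range[0] < 30:
            raise InvalidInputError("canonical sequences must be >= 30 residues")


@dataclass(frozen=True, slots=True)
class ChainTruth:
    entry_id: str
    chain_id: str
    source_accession: str  # empty for chimeras
    chimeric: bool
    observed_segments: tuple[tuple[int, int], ...]
    xref_accessions: tuple[str, ...]


@dataclass
class GroundTruth:
    archive_id: str
    chains: dict[tuple[str, str], ChainTruth] = field(default_factory=dict)
    #: member accession -> (seed accession, exact planted identity)
    cluster_members: dict[str, tuple[str, float]] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return bytes(_AA[rng.integers(0, len(_AA), size=length)]).decode()


def _substitute(rng: np.random.Generator, seq: str, positions: np.ndarray) -> str:
    out = bytearray(seq.encode())
    for pos in positions:
        old = out[pos]
        choices = _AA[_AA != old]
        out[pos] = int(choices[rng.integers(len(choices))])
    return out.decode()


def _make_isoform(rng: np.random.Generator, canonical: str, spec: FixtureSpec) -> str:
    seq = canonical
    n_skips = int(rng.integers(spec.exon_skips_per_isoform[0],
                               spec.exon_skips_per_isoform[1] + 1))
    for _ in range(n_skips):
        if len(seq) <= spec.exon_skip_length[1] + 20:
            break
        dlen = int(rng.integers(spec.exon_skip_length[0],
                                spec.exon_skip_length[1] + 1))
        start = int(rng.integers(5, len(seq) - dlen - 5))
        seq = seq[:start] + seq[start + dlen:]
    n_sub = rng.binomial(len(seq), spec.substitution_rate)
    if n_sub:
        pos = rng.choice(len(seq), size=n_sub, replace=False)
        seq = _substitute(rng, seq, pos)
    return seq


def _plant_loops(rng: np.random.Generator, n: int, spec: FixtureSpec) -> list[tuple[int, int]]:
    """Unobserved loops as disjoint internal (start, end) seqres spans."""
    n_loops = int(rng.integers(spec.unobserved_loops[0],
                               spec.unobserved_loops[1] + 1))
    loops: list[tuple[int, int]] = []
    for _ in range(n_loops):
        llen = int(rng.integers(spec.loop_length[0], spec.loop_length[1] + 1))
        if n - llen - 4 <= 2:
            continue
        for _attempt in range(20):
            start = int(rng.integers(2, n - llen - 2))
            span = (start, start + llen - 1)
            if all(span[1] < s - 1 or span[0] > e + 1 for s, e in loops):
                loops.append(span)
                break
    return sorted(loops)


def _build_chain(entry_id: str, chain_id: str, construct: str,
                 loops: list[tuple[int, int]], author_offset: int) -> ChainModel:
    unobserved = {i for s, e in loops for i in range(s, e + 1)}
    residues = tuple(
        ResidueRef(chain_id, i + author_offset, "", i, i not in unobserved)
        for i in range(1, len(construct) + 1)
    )
    return ChainModel(entry_id=entry_id, chain_id=chain_id,
                      construct_sequence=construct, residues=residues)


def generate_archive(
    spec: FixtureSpec,
    out_dir: Union[str, Path],
) -> GroundTruth:
    """Write a complete toy archive and return its ground truth.

    Layout under ``out_dir``: ``structures/<entry>.pdb``, ``sequences.fasta``,
    ``sequences_meta.tsv``, ``xrefs.tsv`` and ``ground_truth.tsv``.
    """
    out = Path(out_dir)
    (out / "structures").mkdir(parents=True, exist_ok=True)
    root_ss = np.random.SeedSequence(spec.seed)
    seq_rng, chain_rng = (np.random.default_rng(s) for s in root_ss.spawn(2))

    records: list[SequenceRecord] = []
    groups: list[list[SequenceRecord]] = []
    for i in range(spec.n_proteins):
        parent = f"P{i:05d}"
        taxid = 9000 + int(seq_rng.integers(spec.taxonomy_pool))
        length = int(seq_rng.integers(spec.length_range[0],
                                      spec.length_range[1] + 1))
        canonical = SequenceRecord(
            accession=parent, sequence=_random_seq(seq_rng, length),
            is_canonical=True, parent_accession=parent, taxonomy_id=taxid,
        )
        group = [canonical]
        n_iso = int(seq_rng.integers(spec.isoforms_per_protein[0],
                                     spec.isoforms_per_protein[1] + 1))
        for k in range(n_iso):
            group.append(SequenceRecord(
                accession=f"{parent}-{k + 2}",
                sequence=_make_isoform(seq_rng, canonical.sequence, spec),
                is_canonical=False, parent_accession=parent, taxonomy_id=taxid,
            ))
        records.extend(group)
        groups.append(group)

    truth = GroundTruth(archive_id=f"synthetic-{spec.seed}-{spec.n_proteins}")
    xrefs: list[ManualXref] = []
    n_chimera = int(round(spec.chimera_fraction * spec.n_proteins))
    for i, group in enumerate(groups):
        entry_id = f"{1000 + i}"
        chain_id = "A"
        chimeric = i < n_chimera
        author_offset = int(chain_rng.integers(0, 50))
        if chimeric:
            j = int(chain_rng.integers(spec.n_proteins - 1))
            if j >= i:
                j += 1
            other = groups[j][0]
            mine = group[0]
            half_a = mine.sequence[: len(mine.sequence) // 2]
            half_b = other.sequence[: len(other.sequence) // 2]
            construct = half_a + half_b
            loops = _plant_loops(chain_rng, len(construct), spec)
            chain = _build_chain(entry_id, chain_id, construct, loops, author_offset)
            xrefs.append(ManualXref(entry_id, chain_id, mine.accession,
                                    1, len(half_a)))
            xrefs.append(ManualXref(entry_id, chain_id, other.accession,
                                    len(half_a) + 1, len(construct)))
            source = ""
            xref_accs = (mine.accession, other.accession)
        else:
            src = group[int(chain_rng.integers(len(group)))]
            frac = chain_rng.uniform(*spec.chain_span_fraction)
            span = max(30, int(round(frac * len(src.sequence))))
            start = int(chain_rng.integers(0, len(src.sequence) - span + 1))
            construct = src.sequence[start:start + span]
            loops = _plant_loops(chain_rng, len(construct), spec)
            chain = _build_chain(entry_id, chain_id, construct, loops, author_offset)
            xrefs.append(ManualXref(entry_id, chain_id, group[0].accession,
                                    None, None))
            source = src.accession
            xref_accs = (group[0].accession,)
        write_pdb_min([chain], out / "structures" / f"{entry_id}.pdb")
        truth.chains[(entry_id, chain_id)] = ChainTruth(
            entry_id=entry_id, chain_id=chain_id, source_accession=source,
            chimeric=chimeric,
            observed_segments=tuple(observed_segments(chain)),
            xref_accessions=xref_accs,
        )

    write_fasta(records, out / "sequences.fasta")
    write_metadata(records, out / "sequences_meta.tsv")
    write_manual_xrefs(xrefs, out / "xrefs.tsv")
    write_ground_truth(truth, out / "ground_truth.tsv")
    return truth


# ---------------------------------------------------------------------------
# cluster-divergence collections


def generate_cluster_collection(
    seed: int = 0,
    n_seeds: int = 40,
    members_per_seed: int = 4,
    length_range: tuple[int, int] = (150, 250),
    divergence_range: tuple[float, float] = (0.85, 1.0),
    n_fragments: int = 0,
    fragment_cover_range: tuple[float, float] = (0.6, 1.0),
    fragment_identity: float = 0.95,
    taxonomy_pool: int = 7,
) -> tuple[SequenceCollection, GroundTruth]:
    """Sequence set with planted member-to-seed identities for clustering.

    Each of ``n_seeds`` random parents gets ``members_per_seed`` same-length
    variants whose identity to the parent is drawn uniformly from
    ``divergence_range`` and planted *exactly* (a fixed count of substituted
    positions), plus optionally ``n_fragments`` contiguous fragments at
    ``fragment_identity`` covering a uniform fraction of their parent.
    Identities below the clustering threshold are intended: such members
    must found their own clusters.
    """
    lo, hi = divergence_range
    if not (0.0 < lo <= hi <= 1.0):
        raise InvalidInputError("divergence_range must satisfy 0 < lo <= hi <= 1")
    if lo < 1.0 and length_range[0] * (1.0 - lo) < 1.0:
        raise InvalidInputError(
            f"target identity {lo} indistinguishable from 1.0 at length "
            f"{length_range[0]}"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    coll = SequenceCollection()
    truth = GroundTruth(archive_id=f"clusters-{seed}-{n_seeds}")
    parents: list[SequenceRecord] = []
    for i in range(n_seeds):
        acc = f"S{i:04d}"
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        rec = SequenceRecord(
            accession=acc, sequence=_random_seq(rng, length),
            taxonomy_id=9000 + int(rng.integers(taxonomy_pool)),
        )
        coll.add(rec)
        parents.append(rec)
        for j in range(members_per_seed):
            target = rng.uniform(lo, hi)
            n_sub = int(round((1.0 - target) * length))
            seq = rec.sequence
            if n_sub:
                pos = rng.choice(length, size=n_sub, replace=False)
                seq = _substitute(rng, seq, pos)
            macc = f"{acc}M{j}"
            coll.add(SequenceRecord(
                accession=macc, sequence=seq,
                taxonomy_id=9000 + int(rng.integers(taxonomy_pool)),
            ))
            truth.cluster_members[macc] = (acc, (length - n_sub) / length)
    for k in range(n_fragments):
        parent = parents[int(rng.integers(len(parents)))]
        cover = rng.uniform(*fragment_cover_range)
        flen = max(20, int(round(cover * parent.length)))
        start = int(rng.integers(0, parent.length - flen + 1))
        seq = parent.sequence[start:start + flen]
        n_sub = int(round((1.0 - fragment_identity) * flen))
        if n_sub:
            pos = rng.choice(flen, size=n_sub, replace=False)
            seq = _substitute(rng, seq, pos)
        facc = f"F{k:04d}"
        coll.add(SequenceRecord(
            accession=facc, sequence=seq,
            taxonomy_id=9000 + int(rng.integers(taxonomy_pool)),
        ))
        truth.cluster_members[facc] = (parent.accession, (flen - n_sub) / flen)
    return coll, truth


def generate_truncation_archive(
    out_dir: Union[str, Path],
    seed: int = 0,
    coverages: tuple[float, ...] = tuple(c / 100 for c in range(50, 100, 5)),
    length: int = 200,
) -> GroundTruth:
    """Archive whose chains are exact N-terminal truncations of their
    canonical sequences at the given coverage fractions (one protein per
    coverage, fully observed chains)."""
    out = Path(out_dir)
    (out / "structures").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    records, xrefs = [], []
    truth = GroundTruth(archive_id=f"truncation-{seed}")
    for i, cov in enumerate(coverages):
        acc = f"T{i:05d}"
        rec = SequenceRecord(accession=acc, sequence=_random_seq(rng, length),
                             taxonomy_id=9000)
        records.append(rec)
        entry_id = f"{2000 + i}"
        span = int(round(cov * length))
        chain = _build_chain(entry_id, "A", rec.sequence[:span], [], 0)
        write_pdb_min([chain], out / "structures" / f"{entry_id}.pdb")
        xrefs.append(ManualXref(entry_id, "A", acc, None, None))
        truth.chains[(entry_id, "A")] = ChainTruth(
            entry_id=entry_id, chain_id="A", source_accession=acc,
            chimeric=False, observed_segments=((1, span),),
            xref_accessions=(acc,),
        )
    write_fasta(records, out / "sequences.fasta")
    write_metadata(records, out / "sequences_meta.tsv")
    write_manual_xrefs(xrefs, out / "xrefs.tsv")
    write_ground_truth(truth, out / "ground_truth.tsv")
    return truth


# ---------------------------------------------------------------------------
# ground truth I/O and verification

TRUTH_COLUMNS = ("entry", "chain", "source_accession", "chimeric",
                 "observed_segments", "xref_accessions")


def write_ground_truth(truth: GroundTruth, path: Union[str, Path]) -> None:
    lines = [f"# archive_id={truth.archive_id}", "\t".join(TRUTH_COLUMNS)]
    for (entry, chain), t in sorted(truth.chains.items()):
        segs = ";".join(f"{s}-{e}" for s, e in t.observed_segments)
        lines.append("\t".join([
            entry, chain, t.source_accession, str(int(t.chimeric)),
            segs, ";".join(t.xref_accessions),
        ]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_ground_truth(path: Union[str, Path]) -> GroundTruth:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if len(lines) < 2 or not lines[0].startswith("# archive_id="):
        raise InvalidInputError(f"{path}: not a ground-truth table")
    truth = GroundTruth(archive_id=lines[0].split("=", 1)[1])
    for line in lines[2:]:
        if not line.strip():
            continue
        entry, chain, source, chim, segs, xaccs = line.split("\t")
        segments = tuple(
            tuple(int(v) for v in part.split("-"))
            for part in segs.split(";") if part
        )
        truth.chains[(entry, chain)] = ChainTruth(
            entry_id=entry, chain_id=chain, source_accession=source,
            chimeric=chim == "1", observed_segments=segments,
            xref_accessions=tuple(a for a in xaccs.split(";") if a),
        )
    return truth


@dataclass
class VerificationReport:
    """Per-chain verification outcome plus summary recovery rates."""

    per_chain: dict[tuple[str, str], dict]
    recovery_rate: float  # best == planted source, over non-degenerate chains
    observed_segment_rate: float
    chimera_not_expanded_rate: float
    n_degenerate: int


def verify_against_truth(results, truth: GroundTruth) -> VerificationReport:
    """Compare pipeline output against planted truth.

    ``results`` is a :class:`~siftsforge.pipeline.MappingRun`.  A chain is
    *degenerate* when two or more candidates tie at the top identity — the
    planted source is then not recoverable in principle and the chain is
    excluded from the recovery rate (the tie rule sends such chains to the
    canonical accession).
    """
    keys = {(r.chain.entry_id, r.chain.chain_id) for r in results.results}
    if keys != set(truth.chains):
        raise InvalidInputError(
            "pipeline output and ground truth describe different archives: "
            f"{sorted(keys ^ set(truth.chains))[:5]}..."
        )
    per_chain: dict[tuple[str, str], dict] = {}
    n_recovered = n_eligible = n_deg = 0
    n_seg_ok = 0
    n_chim = n_chim_ok = 0
    for res in results.results:
        key = (res.chain.entry_id, res.chain.chain_id)
        t = truth.chains[key]
        segs = tuple(observed_segments(res.chain))
        seg_ok = segs == t.observed_segments
        n_seg_ok += seg_ok
        top = max(c.identity for c in res.candidates)
        degenerate = sum(1 for c in res.candidates if c.identity == top) > 1
        entry = {"observed_segments_ok": seg_ok, "degenerate": degenerate}
        if t.chimeric:
            n_chim += 1
            cand_accs = {c.accession for c in res.candidates}
            not_expanded = cand_accs <= set(t.xref_accessions)
            n_chim_ok += not_expanded
            entry["chimera_not_expanded"] = not_expanded
        else:
            recovered = res.best.accession == t.source_accession
            entry["best_matches_source"] = recovered
            if degenerate:
                n_deg += 1
            else:
                n_eligible += 1
                n_recovered += recovered
        per_chain[key] = entry
    return VerificationReport(
        per_chain=per_chain,
        recovery_rate=n_recovered / n_eligible if n_eligible else 1.0,
        observed_segment_rate=n_seg_ok / len(per_chain) if per_chain else 1.0,
        chimera_not_expanded_rate=n_chim_ok / n_chim if n_chim else 1.0,
        n_degenerate=n_deg,
    )
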