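"""Cross-reference routing and per-domain structure coverage.

Resources differ in which sequence they annotate, so each cross-reference is
attached on a fixed *basis*:

* ``canonical`` — Pfam, IntEnz, Homologene: these resources do not model
  isoforms, so their annotations ride on the canonical accession regardless
  of which isoform won the mapping;
* ``isoform`` — Ensembl: transcript-level, so it follows the winning
  isoform;
* ``query`` — GOA, InterPro and provisional HMM-based Pfam assignments are
  computed for the chain's own sequence; SCOP, CATH, PubMed and Taxonomy are
  entry/chain-keyed pass-through fields and travel the same way.

Profile scanning itself is out of scope: domain hits arrive as precomputed
tables and only the routing and coverage arithmetic happen here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Union

from .errors import InvalidInputError, ParseError
from .mapping import MappingCandidate, ResidueMapping, observed_only

logger = logging.getLogger("siftsforge")

#: resource -> basis its annotations are attached on
ROUTING_TABLE = {
    "Pfam": "canonical",
    "IntEnz": "canonical",
    "Homologene": "canonical",
    "Ensembl": "isoform",
    "GOA": "query",
    "InterPro": "query",
    "HMM-Pfam": "query",
    "SCOP": "query",
    "CATH": "query",
    "PubMed": "query",
    "Taxonomy": "query",
}


@dataclass(frozen=True, slots=True)
class GenomicPosition:
    """Ensembl-style genomic location of a transcript."""

    assembly: str
    chromosome: str
    start: int
    end: int
    strand: int


@dataclass(frozen=True, slots=True)
class CrossRef:
    """A cross-reference to an external resource.

    ``carrier`` is the accession or chain key the reference was supplied
    for; ``basis`` is set by routing.  ``extra`` holds resource-specific
    payload (e.g. the Ensembl gene id next to a transcript identifier).
    """

    resource: str
    identifier: str
    carrier: str = ""
    basis: Optional[str] = None
    extra: str = ""
    genomic: Optional[GenomicPosition] = None


def chain_key(entry_id: str, chain_id: str) -> str:
    return f"{entry_id}_{chain_id}"


def route_crossrefs(
    xrefs: list[CrossRef],
    best: MappingCandidate,
    canonical_accession: str,
    chain: str,
) -> list[CrossRef]:
    """Attach cross-references on the basis their resource dictates.

    ``xrefs`` is the pooled input (canonical-record, winning-record and
    chain-keyed references together).  Each is either attached with its
    basis set, or dropped with a log entry — unknown resources and
    references whose carrier does not match the expected source for their
    resource.  The result is sorted (resource, identifier, carrier) and so
    independent of input order.
    """
    expected_carrier = {
        "canonical": canonical_accession,
        "isoform": best.accession,
        "query": chain,
    }
    routed = []
    for x in xrefs:
        basis = ROUTING_TABLE.get(x.resource)
        if basis is None:
            logger.warning("dropping cross-reference to unknown resource %r (%s)",
                           x.resource, x.identifier)
            continue
        if x.carrier and x.carrier != expected_carrier[basis]:
            logger.info(
                "dropping %s xref %s: carried by %r, expected %r for basis %s",
                x.resource, x.identifier, x.carrier, expected_carrier[basis], basis,
            )
            continue
        routed.append(replace(x, basis=basis))
    routed.sort(key=lambda x: (x.resource, x.identifier, x.carrier))
    return routed


@dataclass(frozen=True, slots=True)
class DomainHit:
    """A domain-family hit on a carrying sequence (1-based inclusive span)."""

    family_id: str
    carrier: str
    start: int
    end: int
    score: float = 0.0
    structure_coverage: Optional[float] = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise InvalidInputError(
                f"domain hit {self.family_id}: invalid span ({self.start}, {self.end})"
            )


def domain_structure_coverage(
    hit: DomainHit,
    mapping: ResidueMapping,
    observed_only_flag: bool = False,
    sequence_length: Optional[int] = None,
) -> float:
    """Fraction of a domain's span present in the (optionally
    observed-restricted) residue mapping.

    Monotone non-increasing when ``observed_only_flag`` switches on.
    """
    if sequence_length is not None and hit.end > sequence_length:
        raise InvalidInputError(
            f"domain hit {hit.family_id} span ({hit.start}, {hit.end}) outside "
            f"sequence of length {sequence_length}"
        )
    m = observed_only(mapping) if observed_only_flag else mapping
    mapped = {upos for _, upos in m.pairs}
    span = hit.end - hit.start + 1
    return sum(1 for p in range(hit.start, hit.end + 1) if p in mapped) / span


# ---------------------------------------------------------------------------
# TSV ingestion

DOMAIN_COLUMNS = ("carrier_id", "family_id", "start", "end", "score")
XREF_TABLE_COLUMNS = ("accession_or_chain", "resource", "identifier", "extra")


def read_domain_hits(path: Union[str, Path]) -> list[DomainHit]:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or tuple(lines[0].split("\t")) != DOMAIN_COLUMNS:
        raise ParseError(f"{path}: expected header {DOMAIN_COLUMNS}")
    out = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise ParseError(f"{path}:{ln}: expected 5 tab-separated fields")
        carrier, family, start, end, score = fields
        out.append(DomainHit(family_id=family, carrier=carrier,
                             start=int(start), end=int(end), score=float(score)))
    return out


def read_xref_table(path: Union[str, Path]) -> list[CrossRef]:
    """Read supplied cross-references.

    The ``extra`` column holds `key=value` pairs separated by `;`.  Ensembl
    rows may carry `gene=...;assembly=...;chromosome=...;start=...;end=...;
    strand=...` from which the genomic position is built.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or tuple(lines[0].split("\t")) != XREF_TABLE_COLUMNS:
        raise ParseError(f"{path}: expected header {XREF_TABLE_COLUMNS}")
    out = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise ParseError(f"{path}:{ln}: expected 4 tab-separated fields")
        carrier, resource, identifier, extra = fields
        kv = dict(
            item.split("=", 1) for item in extra.split(";") if "=" in item
        )
        genomic = None
        if {"assembly", "chromosome", "start", "end", "strand"} <= kv.keys():
            genomic = GenomicPosition(
                assembly=kv["assembly"], chromosome=kv["chromosome"],
                start=int(kv["start"]), end=int(kv["end"]), strand=int(kv["strand"]),
            )
        out.append(CrossRef(
            resource=resource, identifier=identifier, carrier=carrier,
            extra=kv.get("gene", ""), genomic=genomic,
        ))
    return out
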