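"""Per-entry XML and summary CSV emission (and re-ingestion).

The XML dialect is deliberately small but lossless for the information
classes the pipeline produces: per-residue author numbering, observed
flags, mapped sequence positions, and routed cross-references including
Ensembl genomic positions.  ``docs/formats.md`` is the authoritative
description of both the XML dialect and the CSV column sets.

Four summary CSV dialects exist:

* ``pdb_chain_uniprot`` — one row per mapping segment;
* ``uniprot_segments_observed`` — the same, restricted to observed residues
  (a segment with an internal unobserved loop therefore splits);
* ``pdb_chain_hmmer`` — domain hits with their structure coverage;
* ``pdb_chain_ensembl`` — Ensembl transcript references with genomic
  positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

from lxml import etree

from .annotations import CrossRef, GenomicPosition
from .errors import InvalidInputError, ParseError

SCHEMA_VERSION = "1.0"

CSV_DIALECTS = (
    "pdb_chain_uniprot",
    "uniprot_segments_observed",
    "pdb_chain_hmmer",
    "pdb_chain_ensembl",
)


@dataclass(frozen=True, slots=True)
class ResidueDoc:
    """One construct residue in an entry document."""

    seqres_index: int
    author_number: int
    insertion_code: str
    observed: bool
    amino_acid: str
    accession: Optional[str] = None
    uniprot_position: Optional[int] = None
    xrefs: tuple[CrossRef, ...] = ()


@dataclass(frozen=True, slots=True)
class ChainDoc:
    chain_id: str
    construct_sequence: str
    residues: tuple[ResidueDoc, ...]
    xrefs: tuple[CrossRef, ...] = ()


@dataclass(frozen=True, slots=True)
class EntryDocument:
    entry_id: str
    chains: tuple[ChainDoc, ...]
    xrefs: tuple[CrossRef, ...] = ()


def build_entry_document(chain_payloads, entry_id: str,
                         entry_xrefs: Iterable[CrossRef] = ()) -> EntryDocument:
    """Assemble an :class:`EntryDocument`.

    ``chain_payloads`` is an iterable of ``(chain, mapping, chain_xrefs,
    residue_xrefs)`` where ``chain`` is a :class:`~siftsforge.structure.ChainModel`,
    ``mapping`` a :class:`~siftsforge.mapping.ResidueMapping` or ``None`` and
    ``residue_xrefs`` maps seqres index -> tuple of :class:`CrossRef`.
    """
    chains = []
    for chain, mapping, chain_xrefs, residue_xrefs in chain_payloads:
        mapped = {}
        if mapping is not None:
            mapped = {ref.seqres_index: (mapping.accession, upos)
                      for ref, upos in mapping.pairs}
        residues = tuple(
            ResidueDoc(
                seqres_index=r.seqres_index,
                author_number=r.author_number,
                insertion_code=r.insertion_code,
                observed=r.observed,
                amino_acid=chain.construct_sequence[r.seqres_index - 1],
                accession=mapped.get(r.seqres_index, (None, None))[0],
                uniprot_position=mapped.get(r.seqres_index, (None, None))[1],
                xrefs=tuple(residue_xrefs.get(r.seqres_index, ())),
            )
            for r in chain.residues
        )
        chains.append(ChainDoc(
            chain_id=chain.chain_id,
            construct_sequence=chain.construct_sequence,
            residues=residues,
            xrefs=tuple(chain_xrefs),
        ))
    return EntryDocument(entry_id=entry_id, chains=tuple(chains),
                         xrefs=tuple(entry_xrefs))


# ---------------------------------------------------------------------------
# XML


def _xref_element(x: CrossRef) -> etree._Element:
    el = etree.Element("crossref")
    el.set("resource", x.resource)
    el.set("identifier", x.identifier)
    if x.carrier:
        el.set("carrier", x.carrier)
    if x.basis:
        el.set("basis", x.basis)
    if x.extra:
        el.set("extra", x.extra)
    if x.genomic is not None:
        g = etree.SubElement(el, "genomic_position")
        g.set("assembly", x.genomic.assembly)
        g.set("chromosome", x.genomic.chromosome)
        g.set("start", str(x.genomic.start))
        g.set("end", str(x.genomic.end))
        g.set("strand", str(x.genomic.strand))
    return el


def _xref_from_element(el: etree._Element) -> CrossRef:
    genomic = None
    g = el.find("genomic_position")
    if g is not None:
        genomic = GenomicPosition(
            assembly=g.get("assembly"), chromosome=g.get("chromosome"),
            start=int(g.get("start")), end=int(g.get("end")),
            strand=int(g.get("strand")),
        )
    return CrossRef(
        resource=el.get("resource"), identifier=el.get("identifier"),
        carrier=el.get("carrier") or "", basis=el.get("basis"),
        extra=el.get("extra") or "", genomic=genomic,
    )


def write_entry_xml(doc: EntryDocument, path: Union[str, Path]) -> None:
    """Serialize an entry document as schema-versioned XML.

    Element order is stable (entry xrefs, then chains in document order,
    residues by seqres index), so output is byte-reproducible.
    """
    root = etree.Element("sifts_entry")
    root.set("schema_version", SCHEMA_VERSION)
    root.set("entry_id", doc.entry_id)
    xr = etree.SubElement(root, "crossrefs")
    for x in doc.xrefs:
        xr.append(_xref_element(x))
    for chain in doc.chains:
        ch = etree.SubElement(root, "chain")
        ch.set("id", chain.chain_id)
        ch.set("construct_sequence", chain.construct_sequence)
        cxr = etree.SubElement(ch, "crossrefs")
        for x in chain.xrefs:
            cxr.append(_xref_element(x))
        for r in chain.residues:
            re_ = etree.SubElement(ch, "residue")
            re_.set("seqres_index", str(r.seqres_index))
            re_.set("author_number", str(r.author_number))
            re_.set("insertion_code", r.insertion_code)
            re_.set("observed", "true" if r.observed else "false")
            re_.set("amino_acid", r.amino_acid)
            if r.accession is not None:
                u = etree.SubElement(re_, "uniprot")
                u.set("accession", r.accession)
                u.set("position", str(r.uniprot_position))
            for x in r.xrefs:
                re_.append(_xref_element(x))
    tree = etree.ElementTree(root)
    tree.write(str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8")


def read_entry_xml(path: Union[str, Path]) -> EntryDocument:
    """Parse a file produced by :func:`write_entry_xml` (lossless inverse)."""
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    root = tree.getroot()
    if root.tag != "sifts_entry":
        raise ParseError(f"{path}: root element is <{root.tag}>, expected <sifts_entry>")
    if root.get("schema_version") != SCHEMA_VERSION:
        raise ParseError(
            f"{path}: schema_version {root.get('schema_version')!r} unsupported"
        )
    entry_id = root.get("entry_id")
    if entry_id is None:
        raise ParseError(f"{path}: <sifts_entry> lacks entry_id")
    entry_xr_el = root.find("crossrefs")
    entry_xrefs = tuple(
        _xref_from_element(el) for el in (entry_xr_el if entry_xr_el is not None else ())
    )
    chains = []
    for ch in root.findall("chain"):
        seq = ch.get("construct_sequence")
        if ch.get("id") is None or seq is None:
            raise ParseError(f"{path}: <chain> lacks id or construct_sequence")
        cxr_el = ch.find("crossrefs")
        cxrefs = tuple(
            _xref_from_element(el) for el in (cxr_el if cxr_el is not None else ())
        )
        residues = []
        for re_ in ch.findall("residue"):
            u = re_.find("uniprot")
            residues.append(ResidueDoc(
                seqres_index=int(re_.get("seqres_index")),
                author_number=int(re_.get("author_number")),
                insertion_code=re_.get("insertion_code") or "",
                observed=re_.get("observed") == "true",
                amino_acid=re_.get("amino_acid"),
                accession=None if u is None else u.get("accession"),
                uniprot_position=None if u is None else int(u.get("position")),
                xrefs=tuple(_xref_from_element(el) for el in re_.findall("crossref")),
            ))
        chains.append(ChainDoc(
            chain_id=ch.get("id"),
            construct_sequence=seq,
            residues=tuple(residues),
            xrefs=cxrefs,
        ))
    return EntryDocument(entry_id=entry_id, chains=tuple(chains), xrefs=entry_xrefs)


# ---------------------------------------------------------------------------
# summary CSVs


def _author_label(number: int, icode: str) -> str:
    return f"{number}{icode}"


def chain_mapping_segments(chain: ChainDoc, observed_restricted: bool):
    """Mapping segments of a chain document.

    Yields ``(accession, res_beg, res_end, pdb_beg, pdb_end, sp_beg, sp_end)``
    for maximal runs of mapped residues consecutive in both coordinates.
    With ``observed_restricted`` unobserved residues break runs.
    """
    run: list[ResidueDoc] = []

    def flush():
        if run:
            a, b = run[0], run[-1]
            yield (
                a.accession,
                a.seqres_index, b.seqres_index,
                _author_label(a.author_number, a.insertion_code),
                _author_label(b.author_number, b.insertion_code),
                a.uniprot_position, b.uniprot_position,
            )

    for r in chain.residues:
        eligible = r.accession is not None and (r.observed or not observed_restricted)
        if not eligible:
            yield from flush()
            run = []
            continue
        if run and (
            r.accession != run[-1].accession
            or r.seqres_index != run[-1].seqres_index + 1
            or r.uniprot_position != run[-1].uniprot_position + 1
        ):
            yield from flush()
            run = []
        run.append(r)
    yield from flush()


_CSV_HEADERS = {
    "pdb_chain_uniprot":
        "PDB,CHAIN,SP_PRIMARY,RES_BEG,RES_END,PDB_BEG,PDB_END,SP_BEG,SP_END",
    "uniprot_segments_observed":
        "PDB,CHAIN,SP_PRIMARY,RES_BEG,RES_END,PDB_BEG,PDB_END,SP_BEG,SP_END",
    "pdb_chain_hmmer":
        "PDB,CHAIN,PFAM_ID,SEQ_BEG,SEQ_END,COVERAGE",
    "pdb_chain_ensembl":
        "PDB,CHAIN,GENE_ID,TRANSCRIPT_ID,ASSEMBLY,CHROMOSOME,GENOMIC_BEG,GENOMIC_END,STRAND",
}


def write_summary_csv(
    entries: Iterable[EntryDocument],
    which: str,
    path: Union[str, Path],
    generation_date: str = "1970-01-01",
    domain_rows: Iterable[tuple] = (),
) -> None:
    """Write one summary CSV dialect.

    ``domain_rows`` feeds the ``pdb_chain_hmmer`` dialect as
    ``(entry_id, chain_id, family_id, start, end, coverage)`` tuples;
    the other dialects derive everything from the entry documents.
    """
    if which not in CSV_DIALECTS:
        raise InvalidInputError(
            f"unknown summary dialect {which!r}; expected one of {CSV_DIALECTS}"
        )
    lines = [f"# {generation_date}", _CSV_HEADERS[which]]
    if which in ("pdb_chain_uniprot", "uniprot_segments_observed"):
        observed_restricted = which == "uniprot_segments_observed"
        for doc in entries:
            for chain in doc.chains:
                for seg in chain_mapping_segments(chain, observed_restricted):
                    acc, rb, re_, pb, pe, sb, se = seg
                    lines.append(
                        f"{doc.entry_id},{chain.chain_id},{acc},{rb},{re_},"
                        f"{pb},{pe},{sb},{se}"
                    )
    elif which == "pdb_chain_hmmer":
        for entry_id, chain_id, family, start, end, coverage in domain_rows:
            lines.append(
                f"{entry_id},{chain_id},{family},{start},{end},{coverage:.3f}"
            )
    else:  # pdb_chain_ensembl
        for doc in entries:
            for chain in doc.chains:
                for x in chain.xrefs:
                    if x.resource != "Ensembl":
                        continue
                    g = x.genomic
                    pos = (
                        f"{g.assembly},{g.chromosome},{g.start},{g.end},{g.strand}"
                        if g is not None else ",,,,"
                    )
                    lines.append(
                        f"{doc.entry_id},{chain.chain_id},{x.extra},{x.identifier},{pos}"
                    )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
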