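"""End-to-end orchestration: archive in, XML + summary CSVs out.

Thin glue over the per-stage modules; everything here is deterministic
given the config (seed, date pin) and input files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from .annotations import (
    CrossRef,
    DomainHit,
    chain_key,
    domain_structure_coverage,
    route_crossrefs,
)
from .config import SiftsConfig
from .errors import InvalidInputError
from .mapping import (
    ManualXref,
    MappingCandidate,
    ResidueMapping,
    map_chain,
    read_manual_xrefs,
)
from .seq import SequenceCollection, read_collection
from .sifts_io import (
    CSV_DIALECTS,
    EntryDocument,
    build_entry_document,
    write_entry_xml,
    write_summary_csv,
)
from .structure import ChainModel, read_structure_chains
from .uniref import (
    Cluster,
    ExpansionResult,
    clusters_by_member,
    expand_for_chain,
)

logger = logging.getLogger("siftsforge")


@dataclass
class ChainResult:
    chain: ChainModel
    best: MappingCandidate
    mapping: ResidueMapping
    candidates: list[MappingCandidate]
    canonical_accession: Optional[str]
    canonical_coverage: Optional[float]


@dataclass
class MappingRun:
    results: list[ChainResult]
    collection: SequenceCollection
    config: SiftsConfig
    xrefs: list[ManualXref] = field(default_factory=list)


def run_mapping(
    structures_dir: Union[str, Path],
    fasta_path: Union[str, Path],
    meta_path: Union[str, Path],
    xrefs_path: Union[str, Path],
    config: SiftsConfig | None = None,
    dialect: str = "pdb-min",
) -> MappingRun:
    """Map every chain of every structure file in ``structures_dir``.

    The canonical (primary) accession of a chain is the parent of its first
    curated cross-reference; chimeric chains have no single primary
    accession, so their canonical coverage is left unset and they never
    enter the cluster-expansion route.
    """
    config = config or SiftsConfig()
    collection = read_collection(fasta_path, meta_path)
    xrefs = read_manual_xrefs(xrefs_path)
    suffix = "*.cif" if dialect == "mmcif-min" else "*.pdb"
    paths = sorted(Path(structures_dir).glob(suffix))
    if not paths:
        raise InvalidInputError(f"no {suffix} files in {structures_dir}")
    results = []
    for path in paths:
        for chain in read_structure_chains(path, dialect):
            best, mapping, candidates = map_chain(
                chain, xrefs, collection, config.alignment
            )
            mine = [x for x in xrefs
                    if (x.entry_id, x.chain_id) == (chain.entry_id, chain.chain_id)]
            parents = {collection.get(x.accession).parent_accession for x in mine}
            if len(parents) == 1:
                canonical = parents.pop()
                coverage = next(
                    (c.coverage for c in candidates
                     if c.accession == canonical and c.coverage is not None),
                    None,
                )
            else:  # chimera: no single primary accession
                canonical, coverage = None, None
            results.append(ChainResult(
                chain=chain, best=best, mapping=mapping, candidates=candidates,
                canonical_accession=canonical, canonical_coverage=coverage,
            ))
    logger.info("mapped %d chains from %d structure files", len(results), len(paths))
    return MappingRun(results=results, collection=collection, config=config,
                      xrefs=xrefs)


def run_expansion(
    run: MappingRun,
    clusters: list[Cluster],
) -> list[ExpansionResult]:
    """Cluster-expansion route over all mapped chains (gated on coverage)."""
    index = clusters_by_member(clusters)
    out: list[ExpansionResult] = []
    for res in run.results:
        if res.canonical_accession is None or res.canonical_coverage is None:
            continue
        out.extend(expand_for_chain(
            res.chain, res.canonical_accession, res.canonical_coverage,
            index, run.collection, run.config.alignment,
            cap=run.config.cluster_size_cap, seed=run.config.seed,
        ))
    return out


def _domain_rows_for_chain(
    res: ChainResult,
    hits: list[DomainHit],
    collection: SequenceCollection,
) -> list[tuple]:
    """Structure-coverage rows for domain hits relevant to one chain.

    Hits carried by the mapped accession are measured through the residue
    mapping (observed residues only); hits carried by the chain itself
    (provisional HMM assignments) are measured as the observed fraction of
    their seqres span.
    """
    key = chain_key(res.chain.entry_id, res.chain.chain_id)
    rows = []
    for hit in hits:
        if hit.carrier == res.best.accession:
            cov = domain_structure_coverage(
                hit, res.mapping, observed_only_flag=True,
                sequence_length=collection.get(hit.carrier).length,
            )
        elif hit.carrier == key:
            if hit.end > len(res.chain.construct_sequence):
                raise InvalidInputError(
                    f"domain hit {hit.family_id} outside chain {key}"
                )
            obs = {r.seqres_index for r in res.chain.residues if r.observed}
            span = range(hit.start, hit.end + 1)
            cov = sum(1 for p in span if p in obs) / len(span)
        else:
            continue
        rows.append((res.chain.entry_id, res.chain.chain_id,
                     hit.family_id, hit.start, hit.end, cov))
    return rows


def emit_outputs(
    run: MappingRun,
    out_dir: Union[str, Path],
    supplied_xrefs: list[CrossRef] | None = None,
    domain_hits: list[DomainHit] | None = None,
) -> list[EntryDocument]:
    """Write per-entry XML plus all four summary CSVs; returns the documents."""
    out = Path(out_dir)
    (out / "xml").mkdir(parents=True, exist_ok=True)
    supplied_xrefs = supplied_xrefs or []
    domain_hits = domain_hits or []

    by_entry: dict[str, list[ChainResult]] = {}
    for res in run.results:
        by_entry.setdefault(res.chain.entry_id, []).append(res)

    docs = []
    all_domain_rows = []
    for entry_id in sorted(by_entry):
        payloads = []
        for res in by_entry[entry_id]:
            key = chain_key(entry_id, res.chain.chain_id)
            canonical = res.canonical_accession or res.best.accession
            pool = [x for x in supplied_xrefs
                    if x.carrier in (canonical, res.best.accession, key)]
            routed = route_crossrefs(pool, res.best, canonical, key)
            residue_xrefs: dict[int, tuple[CrossRef, ...]] = {}
            for hit in domain_hits:
                if hit.carrier != key:
                    continue
                xref = CrossRef(resource="HMM-Pfam", identifier=hit.family_id,
                                carrier=key, basis="query")
                for idx in range(hit.start, hit.end + 1):
                    residue_xrefs[idx] = residue_xrefs.get(idx, ()) + (xref,)
            payloads.append((res.chain, res.mapping, routed, residue_xrefs))
            all_domain_rows.extend(
                _domain_rows_for_chain(res, domain_hits, run.collection)
            )
        doc = build_entry_document(payloads, entry_id)
        write_entry_xml(doc, out / "xml" / f"{entry_id}.xml")
        docs.append(doc)

    date = run.config.generation_date()
    for which in CSV_DIALECTS:
        write_summary_csv(docs, which, out / f"{which}.csv",
                          generation_date=date, domain_rows=all_domain_rows)
    logger.info("emitted %d XML entries and %d summary CSVs under %s",
                len(docs), len(CSV_DIALECTS), out)
    return docs
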