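# File formats

This document is authoritative for every format `sifts-forge` reads or
writes. All text files are UTF-8; TSV files are tab-delimited with a header
row; CSV files are comma-delimited with one leading comment line carrying
the generation date (`# YYYY-MM-DD`, pinnable via `date_pin` in the config
for byte-stable output).

## Sequence collection

* `sequences.fasta` — standard FASTA, record id = accession.
* `sequences_meta.tsv` — columns
  `accession  parent_accession  is_canonical  taxonomy_id`;
  `is_canonical` is `1`/`0`; canonical records have
  `parent_accession == accession`. Every FASTA record needs a metadata row
  and vice versa; each parent group must contain exactly one canonical.

## Curated cross-references

`xrefs.tsv` — columns `entry  chain  accession  start  end`.
`start`/`end` are 1-based inclusive seqres indices restricting the
reference to a chain segment; both blank means whole chain.

## Cluster table

`clusters.tsv` — columns
`cluster_id  seed_accession  member_accession  taxonomy_id`, one row per
member (seed included). Cluster ids are `UR90_<seed accession>`.

## Domain hits and supplied annotations

* Domain hits: `carrier_id  family_id  start  end  score`; `carrier_id` is
  either a sequence accession (positions on that sequence) or a chain key
  `<entry>_<chain>` (positions in seqres coordinates).
* Cross-reference table: `accession_or_chain  resource  identifier  extra`;
  `extra` holds `key=value` pairs separated by `;`. Ensembl rows may carry
  `gene=...;assembly=...;chromosome=...;start=...;end=...;strand=...`.

## Structure dialects

* `pdb-min` — fixed-column PDB `HEADER`, `SEQRES`, `ATOM`, `TER`, `END`
  records; one CA atom per observed residue suffices. Chain ids are single
  characters; author numbering may carry insertion codes.
* `mmcif-min` — only `_entity_poly_seq` (entity_id, num, mon_id) and
  `_atom_site` (label_atom_id, label_comp_id, auth_asym_id,
  label_entity_id, label_seq_id, auth_seq_id, pdbx_PDB_ins_code).

## Per-entry XML

Root `<sifts_entry schema_version="1.0" entry_id="...">` containing one
`<crossrefs>` block (entry-level) and one `<chain id construct_sequence>`
per chain. Each chain holds a `<crossrefs>` block (routed references) and
one `<residue>` per construct position, in seqres order:

```xml
<residue seqres_index="5" author_number="17" insertion_code=""
         observed="true" amino_acid="K">
  <uniprot accession="P00001-2" position="33"/>
  <crossref resource="HMM-Pfam" identifier="PF00042" basis="query" .../>
</residue>
```

`<crossref>` elements carry `resource`, `identifier`, and optionally
`carrier`, `basis`, `extra`, plus a `<genomic_position assembly chromosome
start end strand>` child for Ensembl transcripts. Serialisation order is
fixed (entry xrefs, chains in document order, residues by seqres index,
xrefs sorted by resource/identifier/carrier), so write→read→write is
byte-stable and read(write(doc)) == doc field-for-field.

## Summary CSVs

* `pdb_chain_uniprot.csv` —
  `PDB,CHAIN,SP_PRIMARY,RES_BEG,RES_END,PDB_BEG,PDB_END,SP_BEG,SP_END`;
  one row per mapping segment (maximal run advancing by one in both seqres
  and sequence coordinates, single accession). `PDB_BEG`/`PDB_END` are
  author numbers with the insertion code appended (`52A`).
* `uniprot_segments_observed.csv` — same columns, segments restricted to
  observed residues (an internal unobserved loop splits a row in two).
* `pdb_chain_hmmer.csv` — `PDB,CHAIN,PFAM_ID,SEQ_BEG,SEQ_END,COVERAGE`;
  coverage is the observed-restricted structure coverage, 3 decimals.
* `pdb_chain_ensembl.csv` —
  `PDB,CHAIN,GENE_ID,TRANSCRIPT_ID,ASSEMBLY,CHROMOSOME,GENOMIC_BEG,GENOMIC_END,STRAND`.

## Ground truth (synthetic archives)

`ground_truth.tsv` — first line `# archive_id=<id>`, then columns
`entry  chain  source_accession  chimeric  observed_segments
xref_accessions`; segments as `start-end` joined by `;`, chimeras have an
empty `source_accession`.

## Configuration

A single YAML mapping; all keys optional. `alignment` is a nested mapping
(`match_score`, `mismatch_score`, `gap_open`, `gap_extend`, `mode`); the
rest are `cluster_identity` (0.90), `cluster_overlap` (0.80),
`overlap_denominator` (`seed` | `shorter`), `coverage_gate` (0.70),
`cluster_size_cap` (5000), `seed` (0) and `date_pin` (null → today).
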