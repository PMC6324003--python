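# sifts-forge

Residue-level cross-referencing between protein structure chains and protein
sequence records, as a self-contained pipeline: isoform-aware best-mapping
selection, UniRef90-style sequence clustering and cluster expansion,
annotation routing, and emission of per-entry XML plus summary CSV tables.

## The problem

A structure chain deposited in a PDB-style archive carries two sequences: the
full construct (SEQRES role, including residues that were in the crystallised
sample but never modelled) and the modelled residues with author numbering.
Sequence databases carry, per protein, a *canonical* sequence plus alternative
splice isoforms, grouped under one parent accession. Transferring annotations
between the two worlds needs residue-level mappings — and a decision about
*which* sequence record a chain actually represents, because roughly one in
ten structures of human proteins matches a non-canonical isoform better than
the canonical sequence.

`sifts-forge` implements that decision procedure and everything around it:

1. **Isoform mapping.** Starting from the curated chain↔accession
   cross-reference, the candidate set is expanded to the full isoform group
   (canonical + isoforms) — unless the chain is a chimeric construct, in which
   case the set stays exactly the curated accessions. Every candidate is
   aligned to the chain with an affine-gap semiglobal alignment (Gotoh
   dynamic programming, free end gaps: constructs are routinely truncations
   and carry tags). The **best mapping** is the candidate with the highest
   sequence identity (identical aligned pairs / aligned pairs); exact ties
   prefer the canonical accession. The winning alignment becomes a
   residue-level mapping partitioned into segments contiguous in both
   coordinate systems, with an observed-residues-only view.

2. **Cluster expansion.** Sequences longer than 10 residues are greedily
   clustered so that every member has ≥ 90 % identity and ≥ 80 % overlap to
   its cluster's *seed* (the longest member). When a chain covers more than
   70 % of its canonical accession, every accession in the canonical's
   cluster(s) is pulled in and scored against the chain — clusters above
   5000 members are first thinned to one randomly chosen accession per
   taxonomy identifier (seeded, reproducible).

3. **Annotation routing.** Cross-references attach on the basis their
   resource dictates: Pfam/IntEnz/Homologene on the canonical accession
   (those resources ignore isoforms), Ensembl on the winning isoform,
   GOA/InterPro/provisional HMM-based Pfam assignments on the chain's own
   sequence. Per-domain structure coverage is computed through the residue
   mapping.

4. **Emission.** Per-entry XML (lossless round-trip) and four summary CSVs:
   `pdb_chain_uniprot` (one row per mapping segment),
   `uniprot_segments_observed` (observed residues only — an unobserved loop
   splits a segment), `pdb_chain_hmmer` (domain hits + structure coverage)
   and `pdb_chain_ensembl` (transcripts + genomic positions). Formats are
   documented in `docs/formats.md`.

A seeded synthetic-archive generator (`siftsforge.fixtures`) produces toy
archives — isoform groups, chains cut from a known isoform with planted
unobserved loops, chimeras, cluster members at exact planted identities —
with machine-readable ground truth, so the whole pipeline is testable
offline.

## Worked example

```sh
sifts-forge fixtures --seed 42 --spec <(echo "n_proteins: 8") --out arch
sifts-forge map --structures arch/structures --sequences arch/sequences.fasta \
    --meta arch/sequences_meta.tsv --xrefs arch/xrefs.tsv --out out
sifts-forge cluster --sequences arch/sequences.fasta \
    --meta arch/sequences_meta.tsv --out clusters.tsv
sifts-forge expand --clusters clusters.tsv --structures arch/structures \
    --sequences arch/sequences.fasta --meta arch/sequences_meta.tsv \
    --xrefs arch/xrefs.tsv --seed 42 --out expansion.tsv
```

prints

```
wrote archive with 8 chains to arch
mapped 8 chains; output under out
14 clusters over 23 sequences -> clusters.tsv
7 expansion results -> expansion.tsv
```

and `head -5 out/pdb_chain_uniprot.csv` shows one row per mapping segment —
entry, chain, the accession that won the identity contest, the segment in
seqres / author / sequence coordinates:

```
# 2026-09-30
PDB,CHAIN,SP_PRIMARY,RES_BEG,RES_END,PDB_BEG,PDB_END,SP_BEG,SP_END
1000,A,P00004,122,240,125,243,1,119
1001,A,P00001-3,1,85,3,87,29,113
1002,A,P00002,1,189,22,210,11,199
```

Chain `1001/A` was generated from isoform 3 of protein `P00001`, and the
pipeline recovered exactly that (`SP_PRIMARY = P00001-3`): an
isoform-specific substitution inside the chain span makes the isoform win
the identity comparison against the canonical sequence. `expansion.tsv`
lists every accession reachable through the clusters for chains whose
canonical coverage exceeds 70 %, with its identity to the chain:

```
entry	chain	accession	cluster_id	identity
1002	A	P00002	UR90_P00002	1.0000
1002	A	P00002-2	UR90_P00002	0.9364
1003	A	P00003	UR90_P00003	1.0000
```

The same operations are available as a library (`siftsforge.map_chain`,
`siftsforge.greedy_cluster`, `siftsforge.run_mapping`, ...); see
`docs/methods.md` for the model, parameter defaults and numerical choices.

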