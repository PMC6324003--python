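# Methods

This note records the models, parameter choices and numerical conventions
behind `sifts-forge`, including the points where the underlying procedure is
described in the literature only loosely and a concrete choice had to be
made here.

## Pairwise alignment

All identity and coverage statistics derive from one alignment engine: an
affine-gap Gotoh dynamic program over the 20 standard amino-acid letters
plus X/U/B/Z. A gap of length L costs `gap_open + L·gap_extend`.

Defaults: `match = +2`, `mismatch = −1`, `gap_open = −10`,
`gap_extend = −0.5`, mode `semiglobal`. The production systems this mirrors
do not publish their alignment parameters, so these are this package's own
choice: a gap-opening penalty an order of magnitude above the mismatch
penalty keeps alignments of same-protein variants gapless except at genuine
splice deletions, which is the regime the statistics are meant for.

* **Mode.** `semiglobal` leaves leading/trailing gap runs in *either*
  sequence unpenalised (overlap alignment). Structure constructs are
  routinely truncations of the database sequence (unaligned target ends)
  and carry expression tags the database sequence lacks (unaligned query
  ends); both must be free. `global` mode (ends penalised) is available via
  configuration.
* **Identity** = identical aligned pairs / aligned (non-gap) pairs; 0 when
  no pairs. This denominator is insensitive to tag/linker overhangs. A
  consequence worth knowing: a pure deletion variant can tie a full-length
  sequence at identity 1.0, because deleted positions are gap columns, not
  mismatches — ties are then resolved by the canonical preference (below).
* **Coverage** of a target sequence = distinct aligned target positions /
  full target length.
* **Ambiguity letters** (X, B, Z, U) align like ordinary residues but never
  count as identical, so identity is conservative on chains with unknown
  residues.
* **Determinism.** The traceback tie-break is fixed: match/mismatch is
  preferred over either gap move, and a gap in the query over a gap in the
  target; in semiglobal mode the end cell is chosen by a fixed scan (full
  corner, then longest alignments first). Repeated calls return
  byte-identical pair lists. The matrix fill is numba-jitted; the traceback
  is plain Python.

The engine is verified two ways in the test suite: against exhaustive
enumeration of all alignment paths (small sequences), and against an
independently configured `Bio.Align.PairwiseAligner` at realistic lengths.

## Isoform mapping

Candidate expansion follows the curated chain↔accession references: the
whole isoform group of each referenced accession, except for chimeric
constructs, where the set stays exactly the curated accessions.

* **Chimera criterion** (not precisely defined in the literature): a chain
  is chimeric iff its curated references name ≥ 2 distinct *parent*
  accessions on non-identical chain segments.
* **Selection**: highest identity wins; an exact tie prefers the canonical
  accession; a tie among non-canonical isoforms falls back to lexicographic
  accession order, purely for determinism. Candidates with zero aligned
  pairs are dropped before selection (an empty alignment is not a mapping).
* **Coverage** is computed for canonical candidates only; isoform
  candidates carry identity alone.
* **Residue mapping**: each aligned column becomes a (residue, sequence
  position) pair; segments are maximal runs advancing by one in *both*
  coordinates, so a splice deletion or insertion always starts a new
  segment. The observed-only view drops unmodelled residues and
  re-segments; it is idempotent.

## Clustering and expansion

Clustering is incremental greedy over length-sorted input (ties broken by
accession): each sequence joins the first existing cluster whose seed it
matches at ≥ 90 % identity and ≥ 80 % overlap, else founds a new cluster.
The length sort makes the result invariant to input order, and guarantees
the seed is the longest member. Identity to the seed is computed by the
exact dynamic program — no k-mer prefilter or banding — because desk-scale
collections are small enough that exactness costs little and the printed
thresholds then apply with no heuristic slack.

* **Overlap denominator.** "80 % overlap with the longest sequence" is read
  literally: aligned columns / seed length, so a short high-identity
  fragment fails membership. The alternative convention (aligned columns /
  shorter sequence length, under which any full-length fragment passes) is
  available as `overlap_denominator: shorter` in the configuration.
* **Threshold comparisons** follow the wording they come from: ≥ for the
  90/80 membership thresholds ("at least"), strictly > for the 70 %
  coverage gate and the 5000-member cap ("greater than", "more than").
  Sequences must be strictly longer than 10 residues to be clustered.
* **Capped expansion.** Clusters of ≤ 5000 members contribute all members;
  larger clusters contribute exactly one member per distinct taxonomy
  identifier, chosen uniformly by a seeded generator (taxa processed in
  sorted order, so a fixed seed reproduces the selection byte for byte).
* A primary accession may belong to several clusters; the expansion is the
  union of their contributions.

## Annotation routing

Each cross-reference resource has a fixed basis: canonical
(Pfam, IntEnz, Homologene — these resources do not model isoforms), isoform
(Ensembl, transcript-level), or query (GOA, InterPro, provisional HMM-based
Pfam assignments — computed for the chain's own sequence). SCOP, CATH,
PubMed and Taxonomy references are pass-through fields routed with the
query basis. Routing is total: every input reference is either attached
with its basis set or dropped with a log entry (unknown resource, or
supplied on a carrier that is not the expected source for its basis).

Domain hits arrive as precomputed tables; profile scanning itself is out of
scope. Structure coverage of a hit carried by a sequence accession is the
fraction of its span present in the residue mapping; whether the mapping is
first restricted to observed residues is a flag (the summary CSV uses the
observed-restricted value, the stricter of the two). Hits carried by the
chain itself are measured as the observed fraction of their seqres span.

## Structure ingestion

Two dialects: fixed-column PDB (`SEQRES` + `ATOM`) and an mmCIF subset
(`_entity_poly_seq` + `_atom_site`), both parsed through gemmi. A residue
is *observed* iff it has a CA atom — the operational criterion chosen here
for "residues whose atomic coordinates were not modelled". Author numbering
is carried verbatim (any integer, optional insertion code) and never used
arithmetically, with one exception: residues absent from the coordinate
records have no author number in the file, so they get one extrapolated by
seqres offset from the nearest observed residue. For the PDB dialect,
seqres indices of modelled residues are assigned by anchoring the first
residue at the smallest construct position consistent with the residue
letters and following author-number deltas thereafter (insertion-coded
residues advance by one); this is exact whenever author numbering mirrors
the construct, and raises a consistency error when coordinate residue names
cannot be reconciled with the construct sequence. Modified residues map to
their parent residue through a small fixed table (MSE→M, SEC→U, ...);
unknown names become X. Alt-locations: first CA wins. Non-polypeptide
chains are skipped with a log notice.

## Synthetic archives

The fixture generator emulates the pipeline's inputs with planted truth:

* canonical sequences uniform over the 20 letters, 150–250 residues;
* 1–3 isoforms per protein, each by 1–2 internal "exon-skip" deletions of
  10–30 residues plus point substitutions at rate 0.005;
* chains cut verbatim from a uniformly chosen record of the group, spanning
  60–100 % of it, with 0–2 planted unobserved loops of 2–8 residues and a
  constant author-numbering offset;
* 10 % of chains are chimeras (concatenated halves of two proteins, curated
  with two segment references);
* cluster collections plant members at *exact* target identities (a fixed
  count of substituted positions) and optional fragments at 95 % identity
  covering 60–100 % of their parent;
* one global seed fans out to per-component substreams
  (`numpy.random.SeedSequence`), so identical specs give byte-identical
  archives.

What the generator does not emulate — and what passing tests therefore do
not show about real archives: realistic evolutionary substitution patterns,
splice-site biology, sequencing/construct errors (chains are exact cuts),
non-monotone author numbering, multi-chain entries, and archive-scale
redundancy. In particular, a chain cut from an isoform whose edits all fall
outside the chain span is *in principle* indistinguishable from the
canonical (identity ties at 1.0, and the tie rule returns the canonical);
verification classifies such chains as degenerate and reports recovery over
the non-degenerate remainder, where it is 100 %.

## Problem sizes and verification

The shipped checks run at desk scale, chosen so each stage still exercises
every rule: clustering runs use 200–220 sequences of 150–250 residues at
mixed divergence 85–100 % with fragments spanning 60–100 % of their parent;
the coverage gate is probed with exact truncations at 50–95 % in 5 % steps
(the smallest coverage that expands is 75 %, the largest that does not is
70 %); the expansion cap with clusters of 5000 and 5001 members over 7
taxa; recovery with a 50-protein archive. Accepted cluster members are
re-verified against the 90/80 thresholds with an independent aligner, never
with the clustering's own identity values.

## Known limitations

* The alignment scoring is match/mismatch only; no substitution matrix is
  shipped (the parameters are configurable, a matrix hook is not).
* Greedy clustering is order-canonical but still greedy: a sequence joins
  the *first* matching cluster, not the best one.
* `pdb-min` seqres-index assignment requires author numbering consistent
  with the construct (offset + gaps); deliberately scrambled numbering is
  rejected rather than realigned.
* The XML dialect is this package's own documented schema
  (`docs/formats.md`), not an external XSD.
* One polypeptide chain per synthetic entry; the readers handle multi-chain
  files, but the generator does not produce them.
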