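# Methods

## Model and definitions

A miRNA gene is represented by its precursor (hairpin) interval, with zero
or more mature products linked to it; the precursor is the unit screened
for containment. "Intragenic" means the precursor interval is fully
contained in a host gene's span — the union of its transcript spans — on
the same chromosome and strand. Containment is closed-interval: a
precursor coterminous with a gene boundary counts as contained. This
definition is deliberate: sense orientation is what permits transcription
from a shared promoter, and transcript-level placement labels presuppose
that the whole hairpin sits inside the gene. Antisense overlaps (any
overlap on the opposite strand) and partial sense overlaps are tallied and
reported but never enter the catalog or its denominators, since an
antisense miRNA has an independent transcription unit and a partially
overlapping one has no well-defined placement.

### Coordinates

External files are 1-based inclusive (GFF/GTF/VCF convention). Internally
every interval is 0-based half-open; the conversion happens exactly once
at the I/O boundary (`mirhost.io`), which removes off-by-one hazards from
all interval arithmetic. Chromosome names are harmonized by stripping a
leading `chr` (case-insensitive) before exact matching, because miRNA and
gene annotations frequently disagree on the prefix; a user alias table can
extend this.

### Placement classification

For each transcript of a containing host, the precursor is classified with
the following precedence:

1. fully covered by the transcript's 5′-UTR blocks → `5′-UTR`;
2. fully covered by the 3′-UTR blocks → `3′-UTR`;
3. fully inside the *k*-th intron → `intron k`;
4. fully inside the *k*-th exon → `exon k`;
5. inside the transcript span but none of the above → `junction`.

UTR takes precedence over an exon ordinal because a UTR-resident miRNA is
biologically a UTR case (untranslated, potentially sharing the mRNA's
regulatory context), not "exon 1". Ordinals are numbered in transcription
direction on both strands, so "intron 1" is always the first intron of the
transcript as transcribed; on the minus strand the leftmost genomic gap of
an E-exon transcript is intron E−1.

Placements from all transcripts of one host aggregate into a canonical
label: kind groups in the fixed order 5′-UTR, exon, intron, 3′-UTR,
junction; ordinal kinds carry ascending deduplicated ordinals without
range compression (`exon 7; intron 4, 5, 6, 14, 15`); groups joined by
`"; "`. The pair's category is the single kind when all placements agree,
`mixed` when two or more kinds occur or any placement is a junction (a
junction is evidence of transcript-dependent placement and is flagged for
review), and `gene_body` when the precursor is inside the gene span but
outside every transcript span — a case the annotation permits and the
catalog must not drop.

A miRNA contained in several hosts contributes one catalog row per host.
In summary statistics it is counted once, with the union of its placement
kinds across hosts deciding its category, so category counts and
host-biotype-class counts each partition the intragenic set.

### Percentages

All printed fractions are truncated (rounded toward zero) to one decimal,
not rounded half-up: 849/1,600 prints as 53.0%, 418/855 as 48.8%, 121/849
as 14.2%. Truncation means a percentage is only reported once fully
attained, which is how screening catalogs conventionally print coverage
figures; `gwiss.printed_percentage` implements it with decimal arithmetic
to avoid float artifacts.

### Cross-species matching

Name matching is tiered. Tier 1 lowercases, strips the species prefix
(`hsa-`, `mmu-`, `gga-`, …) and a trailing `-<integer>` paralog counter —
but only when the remainder still looks like a stem, so `mir-21` keeps its
21. Tier 2 additionally strips a single trailing letter preceded by a
digit (`mir-103a` → `mir-103`), reproducing pairings like
`mir-101-2` ↔ `mir-101b` where one species' annotation lacks the letter.
The let-7 family is exempt from letter stripping because its letters
(`let-7a` … `let-7g`) denote distinct family members, not annotation
drift. Explicit overrides (a `canonical_stem → member_name` table) handle
renamed orthologues that no string rule can infer.

Since tier-1 equality implies tier-2 equality, the match graph is built on
the coarsest relation (tier-2 key or shared override group), with edges
additionally requiring host-gene orthology and distinct species. Conserved
pairs are the maximal cliques of this graph (via `networkx`); each records
the lowest tier sufficient for all its member pairs ("1" < "2" <
"override"). Keying pairs by (stem, orthologous host group) means two
cluster members in one host (e.g. two distinct stems in the same gene) are
two pairs, while the same stem in two unlinked hosts never merges.
One2one and one2many orthology links are accepted alike, with the link
type recorded; filtering is left to the user. Tier-2 stripping can in
principle merge true paralogs when both letter variants exist in one
species; the reported `match_tier` makes such matches auditable.

### Seed variants

The seed is positions `first..last` (default 2–8, configurable to 2–7)
from the mature 5′ end. On the plus strand the mature 5′ end is the lower
genomic coordinate; on the minus strand the higher. A variant hits when
any reference base overlaps the projected seed interval — so an indel
whose footprint touches the seed counts, and a multi-allelic record counts
once (the screen counts polymorphic miRNA genes, not alleles). The hit
offset is the seed position of the 5′-most overlapping base. A precursor
is polymorphic when any of its mature arms has a hit; per-species rates
use distinct intragenic precursors as the denominator.

## Synthetic data

The generator emulates the structures the screens must distinguish:
multi-transcript genes with exon/UTR structure on both strands, planted
miRNAs in every placement class (intron *k*, exon *k*, both UTRs,
mixed-across-transcripts via a cassette exon, clusters of 2–3 in one host,
miRNAs inside two overlapping hosts, gene-body cases between transcript
spans), antisense/intergenic/partial-overlap decoys, ncRNA-biotype hosts,
and — in trio mode — three species with orthologous hosts, planted
conserved triples (a configurable fraction requiring tier-2 matching or
overrides), and distractors that share stems without orthology or
orthology without stems.

Plants are made **by construction**: intervals are chosen inside known
introns/exons/UTRs with safety margins, rather than sampled and filtered,
so the manifest label is ground truth by design. Before anything is
written, an independent per-base verifier re-derives each planted label by
walking the precursor base by base against each transcript; a mismatch
aborts generation. Recovery tests then compare the screen's output to the
manifest, keeping the two routes (interval arithmetic vs per-base
labelling) independent.

Default study conditions: 215 planted intragenic miRNAs across all eight
classes, 100 decoys, 20 background genes, a 70/20/5/5
protein-coding/lincRNA/snoRNA/other biotype mix, 30 planted seed variants,
3 chromosomes; trio mode plants 27 conserved triples (the three-way
count the screens are sized for) among 40 distractors, with 25% of
triples requiring overrides and 25% tier-2 matching. Exons are 140–300 bp,
introns 300–1,500 bp, UTRs 150–250 bp, precursors 70–90 bp with two 22-nt
mature arms — small enough that a full species builds in well under a
second while still exercising per-chromosome summaries and every code
path. All randomness flows through one seeded `random.Random`; identical
(config, seed) yields byte-identical files.

What the generator does **not** emulate: sequence content (no FASTA),
realistic chromosome lengths or gene densities, annotation noise
(truncated transcripts, inconsistent biotypes), or population-genetic
structure in variants. Passing the recovery tests therefore demonstrates
correctness of the screening logic on well-formed annotations, not
robustness to the curation artifacts real miRBase/Ensembl releases
contain — those require the release-pinned inputs themselves.

## Numerical and degenerate-input choices

- Empty annotation files parse to empty lists; an empty catalog reports
  its intragenic fraction as absent (`None`/`null`), not 0.
- A transcript with zero exons, overlapping exons, or abutting exons
  (which would create a zero-length intron and break ordinal numbering)
  is rejected at construction, naming the transcript.
- Orphan matures (whose `Derives_from` names no precursor) are collected
  into a warning list and logged, never silently dropped; a mature on the
  wrong strand or outside its precursor is an error naming the mature.
- Output files are written atomically (temp file + rename), so a failing
  run leaves no partial outputs.
- Catalog rows are sorted by (chrom, start, precursor, gene); all
  serializations are deterministic.

## Packaged reference tables

`fixtures/table1_conserved_pairs.tsv` (27 cross-species conserved
miRNA/host pairs) and `fixtures/table2_epigenetic.tsv` (43 epigenetically
silenced intragenic miRNAs; 47 rows, as four miRNAs have a secondary host
line) are transcribed with ordinal ranges expanded to explicit lists and
location strings in the canonical label grammar. Parenthetical markers
(synonyms, orthologue flags) are preserved in the name fields and stripped
by `crossref.strip_annotation` for counting. Positional tallies over the
table count distinct miRNA genes, matching the 43-gene denominator.

## Known limitations

- The catalog carries source gene symbols verbatim; no HGNC/MGI
  re-unification is attempted, so symbol-level comparisons across
  annotation sources need the orthology/override tables.
- Cluster detection is host-sharing only; proximity clustering (e.g.
  within 50 kb, irrespective of a shared host) is out of scope.
- Tier-2 name matching trades precision for recall and relies on
  `match_tier` auditing rather than sequence evidence.
- Genome-scale counts depend entirely on the annotation releases supplied;
  the package pins nothing and downloads nothing.
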