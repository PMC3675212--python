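# mirhost

Screens genome annotations for **intragenic microRNAs** — miRNA genes whose
precursor (hairpin) lies inside the boundaries of another gene on the same
strand — and builds a catalog of miRNA/host gene pairs. Roughly half of
vertebrate miRNA genes are intragenic; because a sense-oriented resident
miRNA can share its host's promoter and primary transcript, intragenic
pairs are candidates for co-expression and co-regulation, and host-gene
knockouts or polymorphisms can have collateral effects on the miRNAs they
harbour. `mirhost` is for genomicists who want those pairs, their placement
within host transcripts, their cross-species conservation, and their
seed-region variants, from standard annotation files.

## What it computes

**Genome-wide screen (per species).** Every precursor *m* is assigned to
every gene *g* with the same chromosome and strand whose span fully
contains it (closed-interval containment). For each transcript *t* of *g*
the precursor is classified as

- `intron k` / `exon k` — fully inside the *k*-th intron/exon, numbered in
  transcription direction (intron 1 is the first intron 5′→3′, on either
  strand);
- `5′-UTR` / `3′-UTR` — fully inside the transcript's UTR blocks (UTR wins
  over an exon ordinal);
- `junction` — inside the transcript span but straddling a boundary.

Per-transcript placements aggregate into one canonical label per pair
(e.g. `exon 7; intron 4, 5, 6, 14, 15`) and a category: `intron`, `exon`,
`five_utr`, `three_utr`, `mixed` (different placements in different
transcripts), or `gene_body` (inside the gene span but outside every
transcript span). Antisense and partial sense overlaps are tallied but
excluded. The catalog also reports clusters (hosts with ≥ 2 resident
miRNAs), miRNAs contained in two overlapping hosts, host-biotype classes
(protein-coding / ncRNA / both, with lincRNA and snoRNA subclasses), and
the intragenic fraction (printed truncated to one decimal, so 849/1,600 →
53.0%).

**Species-wide screen.** miRNA names are matched across species by tiered
normalization — tier 1 strips the species prefix and trailing paralog
counter (`hsa-mir-103a-1` → `mir-103a`), tier 2 additionally strips a
single letter variant (`mir-103a` → `mir-103`; the let-7 family is exempt),
and explicit overrides handle renamed orthologues (chicken `mir-204-2` ↔
mammalian `mir-211`). A conserved pair is a maximal set of species whose
matching miRNAs sit in pairwise-orthologous hosts; results include
per-subset (Venn) counts.

**Seed-variant screen.** The seed — nucleotides 2–7 or 2–8 from the mature
miRNA's 5′ end, the region critical for target recognition — is projected
to genomic coordinates (strand-aware) and intersected with variants; a
precursor is polymorphic when any mature arm has a seed hit.

**Synthetic data.** `mirhost.simulate` generates multi-species toy
annotation sets with a machine-readable truth manifest: planted miRNAs in
every placement class, antisense/intergenic/partial decoys, clusters,
dual hosts, ncRNA hosts, conserved triples with orthology and override
tables, and planted seed variants — so the whole pipeline is testable
without downloads.

## Worked example

```bash
mirhost simulate species --seed 11 --outdir demo
mirhost gwiss --mirna-gff demo/synthA.mirna.gff3 --genes demo/synthA.genes.gtf \
    --species synthA --out demo/catalog.tsv --summary demo/summary.json
```

prints

```
miRNA genes screened:      315
intragenic miRNA genes:    215 (68.2%)
host genes:                219
clusters (>=2 per host):   9
multi-host miRNA genes:    15
antisense overlaps (excl): 40
partial overlaps (excl):   20
location categories:
  exon         30
  five_utr     25
  gene_body    15
  intron       95
  mixed        25
  three_utr    25
host biotype classes:
  both                 8
  ncRNA_only           44
  protein_coding_only  163
```

Of 315 simulated miRNA genes, 215 are sense-contained in a host (68.2%,
truncated to one decimal); the 40 antisense and 20 partial overlaps are
counted but excluded from the catalog; 8 miRNAs sit in both a
protein-coding and an ncRNA host. The catalog itself is a TSV with one row
per miRNA/host pair:

```
species  precursor_id    mirna_name   chrom start end  strand gene_id       ... location_label category cluster_id
synthA   synthA:MI00101  syn-mir-101  1     7058  7147 +      synthA:G00001 ... intron 6       intron
```

The other subcommands follow the same shape: `mirhost swiss` takes two or
more catalogs plus an ortholog table (and optional name-override table) and
writes conserved pairs with Venn-cell counts; `mirhost seeds` overlaps a
VCF with projected seed regions; `mirhost crossref` resolves a name list
against a catalog and tallies positional predicates such as
`"5utr|intron:1|exon:1"`.

Two transcribed reference tables ship with the package
(`mirhost.crossref.load_table1()` / `load_table2()`): the 27 miRNA/host
pairs with conserved co-location in human, mouse and chicken, and the 43
epigenetically silenced intragenic miRNAs with their hosts.

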