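"""Shared fixtures and independent test oracles.

The oracles here (per-base placement labelling, all-pairs containment scan,
coordinate reflection) are deliberately written against the naive
definition of each operation, independent of the package's interval
arithmetic, so agreement is meaningful.
"""

from __future__ import annotations

import random

import pytest

from mirhost.model import (
    Biotype,
    GeneModel,
    GenomicInterval,
    MatureMiRNA,
    MiRNAGene,
    Strand,
    TranscriptModel,
    Variant,
)
from mirhost.simulate import GeneratorConfig, generate_species


# ---------------------------------------------------------------------------
# Small hand-built models
# ---------------------------------------------------------------------------

def make_transcript(chrom="1", strand="+", exons=((100, 200), (300, 400), (500, 600)),
                    utr5=(), utr3=(), tid="T1", gene_id="G1") -> TranscriptModel:
    s = Strand(strand)
    return TranscriptModel(
        transcript_id=tid, parent_gene_id=gene_id,
        exons=[GenomicInterval(chrom, a, b, s) for a, b in exons],
        five_utr=[GenomicInterval(chrom, a, b, s) for a, b in utr5],
        three_utr=[GenomicInterval(chrom, a, b, s) for a, b in utr3],
    )


def make_gene(gene_id="G1", symbol=None, biotype=Biotype.PROTEIN_CODING,
              transcripts=None, **tx_kwargs) -> GeneModel:
    if transcripts is None:
        transcripts = [make_transcript(gene_id=gene_id, **tx_kwargs)]
    return GeneModel(gene_id=gene_id, symbol=symbol or gene_id,
                     biotype=biotype, transcripts=transcripts)


def make_mirna(pid="MI001", name="syn-mir-1", chrom="1", start=310, end=390,
               strand="+", with_matures=False) -> MiRNAGene:
    s = Strand(strand)
    iv = GenomicInterval(chrom, start, end, s)
    matures = []
    if with_matures:
        left = GenomicInterval(chrom, iv.start + 5, iv.start + 27, s)
        matures = [MatureMiRNA(f"{pid}_m", f"{name}-m", left, pid)]
    return MiRNAGene(precursor_id=pid, name=name, interval=iv, matures=matures)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def perbase_placement(iv: GenomicInterval, t: TranscriptModel):
    """Per-base placement oracle: label each base, then combine.

    Returns None (outside span) or (kind, ordinal-or-None), mirroring the
    classification contract but computed by explicit position membership.
    """
    if not (t.span.start <= iv.start and iv.end <= t.span.end):
        return None
    bases = list(range(iv.start, iv.end))
    in5 = [any(u.start <= p < u.end for u in t.five_utr) for p in bases]
    in3 = [any(u.start <= p < u.end for u in t.three_utr) for p in bases]
    if t.five_utr and all(in5):
        return ("five_utr", None)
    if t.three_utr and all(in3):
        return ("three_utr", None)
    intron_ids = set()
    for p in bases:
        hit = None
        for k, i in enumerate(t.introns_tx_order(), start=1):
            if i.start <= p < i.end:
                hit = k
        intron_ids.add(hit)
    if len(intron_ids) == 1 and None not in intron_ids:
        return ("intron", intron_ids.pop())
    exon_ids = set()
    for p in bases:
        hit = None
        for k, e in enumerate(t.exons_tx_order(), start=1):
            if e.start <= p < e.end:
                hit = k
        exon_ids.add(hit)
    if len(exon_ids) == 1 and None not in exon_ids:
        return ("exon", exon_ids.pop())
    return ("junction", None)


def brute_force_pairs(mirnas, genes):
    """All-pairs scan: sense-contained pairs plus antisense/partial tallies."""
    pairs = set()
    antisense = partial = 0
    for m in mirnas:
        for g in genes:
            iv, sp = m.interval, g.span
            if iv.chrom != sp.chrom:
                continue
            if not (iv.start < sp.end and sp.start < iv.end):
                continue
            if iv.strand is not sp.strand:
                antisense += 1
            elif sp.start <= iv.start and iv.end <= sp.end:
                pairs.add((m.precursor_id, g.gene_id))
            else:
                partial += 1
    return pairs, antisense, partial


# ---------------------------------------------------------------------------
# Coordinate reflection (strand-symmetry checks)
# ---------------------------------------------------------------------------

REFLECT_PIVOT = 50_000_000


def reflect_interval(iv: GenomicInterval, pivot=REFLECT_PIVOT) -> GenomicInterval:
    return GenomicInterval(iv.chrom, pivot - iv.end, pivot - iv.start,
                           iv.strand.flipped())


def reflect_transcript(t: TranscriptModel, pivot=REFLECT_PIVOT) -> TranscriptModel:
    return TranscriptModel(
        transcript_id=t.transcript_id, parent_gene_id=t.parent_gene_id,
        exons=[reflect_interval(e, pivot) for e in t.exons],
        five_utr=[reflect_interval(u, pivot) for u in t.five_utr],
        three_utr=[reflect_interval(u, pivot) for u in t.three_utr],
    )


def reflect_gene(g: GeneModel, pivot=REFLECT_PIVOT) -> GeneModel:
    return GeneModel(gene_id=g.gene_id, symbol=g.symbol, biotype=g.biotype,
                     transcripts=[reflect_transcript(t, pivot) for t in g.transcripts])


def reflect_mirna(m: MiRNAGene, pivot=REFLECT_PIVOT) -> MiRNAGene:
    return MiRNAGene(
        precursor_id=m.precursor_id, name=m.name,
        interval=reflect_interval(m.interval, pivot),
        matures=[MatureMiRNA(x.mature_id, x.name, reflect_interval(x.interval, pivot),
                             x.derives_from) for x in m.matures],
    )


def reflect_variant(v: Variant, pivot=REFLECT_PIVOT) -> Variant:
    start0, end0 = v.ref_span0
    new_start0 = pivot - end0
    return Variant(v.variant_id, v.chrom, new_start0 + 1, v.ref_allele[::-1],
                   v.alt_alleles)


# ---------------------------------------------------------------------------
# Generator fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """A scaled-down generator configuration for fast unit tests."""
    return GeneratorConfig(
        planted={"intron": 5, "exon": 3, "five_utr": 3, "three_utr": 3,
                 "mixed": 3, "cluster": 4, "dual_host": 2, "gene_body": 2},
        decoys={"antisense": 3, "intergenic": 3, "partial_overlap": 2},
        background_genes=3,
        seed_variant_count=6,
        conserved_triples=5,
        conserved_distractors=6,
    )


@pytest.fixture(scope="session")
def default_bundle():
    """One full-size synthetic species shared across the session."""
    return generate_species(GeneratorConfig(), seed=42)


def random_instance(rng: random.Random, n_mirnas=10, n_genes=8):
    """A random single-exon gene set and miRNA set for oracle comparisons."""
    chroms = ["1", "2"]
    genes = []
    for i in range(n_genes):
        chrom = rng.choice(chroms)
        start = rng.randrange(0, 50_000)
        length = rng.randrange(200, 5_000)
        strand = rng.choice("+-")
        genes.append(make_gene(
            gene_id=f"G{i}", transcripts=[make_transcript(
                chrom=chrom, strand=strand, exons=((start, start + length),),
                tid=f"G{i}.t1", gene_id=f"G{i}")]))
    mirnas = []
    for i in range(n_mirnas):
        chrom = rng.choice(chroms)
        start = rng.randrange(0, 55_000)
        length = rng.randrange(60, 120)
        strand = rng.choice("+-")
        mirnas.append(make_mirna(pid=f"MI{i}", name=f"syn-mir-{i}", chrom=chrom,
                                 start=start, end=start + length, strand=strand))
    return mirnas, genes
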