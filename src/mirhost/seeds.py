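"""Seed-region projection and variant overlap (miR-seed-SNP screen).

The seed — nucleotides 2-7 or 2-8 from the mature miRNA's 5' end — drives
target recognition, so variants falling inside it are flagged.  The seed is
projected from mature-relative positions onto genomic coordinates
(strand-aware: on the minus strand the mature 5' end is the higher genomic
coordinate), then intersected with variant positions.  Multi-allelic
records count once; an indel counts as a hit when any reference base
overlaps the seed.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Sequence

from .gwiss import printed_percentage
from .model import (
    Catalog,
    GenomicInterval,
    MatureMiRNA,
    MiRNAGene,
    SeedDefinition,
    SeedVariantHit,
    Strand,
    Variant,
)

__all__ = [
    "project_seed",
    "find_seed_variants",
    "seed_polymorphism_summary",
]


def project_seed(mature: MatureMiRNA, seed: SeedDefinition) -> GenomicInterval:
    """Genomic interval of the seed positions of one mature miRNA.

    Plus strand: bases ``first..last`` counted from the interval start;
    minus strand: counted down from the interval end (the 5' end of the
    transcript).  Errors if the mature is shorter than ``seed.last``.
    """
    iv = mature.interval
    if len(iv) < seed.last:
        raise ValueError(
            f"mature {mature.mature_id} ({len(iv)} nt) shorter than seed end {seed.last}"
        )
    if iv.strand is Strand.PLUS:
        start = iv.start + (seed.first - 1)
        end = iv.start + seed.last
    else:
        start = iv.end - seed.last
        end = iv.end - (seed.first - 1)
    return GenomicInterval(iv.chrom, start, end, iv.strand)


def find_seed_variants(
    matures: Sequence[MatureMiRNA],
    variants: Sequence[Variant],
    seed: SeedDefinition = SeedDefinition(),
) -> list[SeedVariantHit]:
    """All (mature, variant) overlaps within projected seed regions.

    The hit offset is the seed position (1 = seed base closest to the
    mature 5' end) of the 5'-most overlapping reference base.
    """
    by_chrom: dict[str, list[Variant]] = defaultdict(list)
    for v in variants:
        by_chrom[v.chrom].append(v)
    hits: list[SeedVariantHit] = []
    for mature in matures:
        seed_iv = project_seed(mature, seed)
        for v in by_chrom.get(seed_iv.chrom, ()):
            v_start, v_end = v.ref_span0
            ov_start = max(seed_iv.start, v_start)
            ov_end = min(seed_iv.end, v_end)
            if ov_start >= ov_end:
                continue
            if seed_iv.strand is Strand.PLUS:
                offset = ov_start - seed_iv.start + 1
            else:
                offset = seed_iv.end - ov_end + 1
            hits.append(SeedVariantHit(
                mature_id=mature.mature_id,
                precursor_id=mature.derives_from,
                variant_id=v.variant_id,
                offset=offset,
                seed_interval=seed_iv,
            ))
    hits.sort(key=lambda h: (h.seed_interval.chrom, h.seed_interval.start,
                             h.mature_id, h.variant_id))
    return hits


def all_matures(mirnas: Sequence[MiRNAGene]) -> list[MatureMiRNA]:
    return [m for gene in mirnas for m in gene.matures]


def seed_polymorphism_summary(
    catalog: Catalog, hits: Sequence[SeedVariantHit]
) -> dict[str, float | int | None]:
    """Per-species seed-polymorphism rate among intragenic miRNAs.

    A precursor counts as polymorphic when any of its matures has a seed
    hit; the denominator is the catalog's distinct intragenic precursors.
    """
    intragenic = catalog.intragenic_precursors
    polymorphic = {h.precursor_id for h in hits} & intragenic
    denom = len(intragenic)
    pct = None if denom == 0 else printed_percentage(len(polymorphic), denom)
    return {
        "species": catalog.species,
        "intragenic_mirnas": denom,
        "polymorphic_intragenic_mirnas": len(polymorphic),
        "percent_polymorphic": pct,
    }
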