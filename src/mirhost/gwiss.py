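"""Genome-wide screen for sense-oriented miRNA / host gene pairs.

The screen walks every miRNA precursor against an interval index of gene
spans.  A pair becomes a catalog assignment when the precursor interval is
fully contained in the gene span on the same chromosome and strand;
antisense overlaps and partial sense overlaps are tallied but excluded.
Within each assignment the precursor is classified against every transcript
of the host (intron *k* / exon *k* / 5'-UTR / 3'-UTR / junction, ordinals in
transcription direction), and the per-transcript placements are aggregated
into one canonical location label and category per pair.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .model import (
    Catalog,
    CatalogEntry,
    Category,
    GeneModel,
    GenomicInterval,
    HostAssignment,
    MiRNAGene,
    OverlapTallies,
    Placement,
    PlacementKind,
    SummaryStats,
    TranscriptModel,
)

__all__ = [
    "classify_in_transcript",
    "aggregate_assignment",
    "assign_hosts",
    "build_catalog",
    "detect_clusters",
    "partition_biotypes",
    "summarize_catalog",
    "parse_location_label",
    "printed_percentage",
    "round_half_up",
    "GENE_BODY_LABEL",
]

GENE_BODY_LABEL = "gene-body"

_KIND_LABEL = {
    PlacementKind.FIVE_UTR: "5′-UTR",
    PlacementKind.EXON: "exon",
    PlacementKind.INTRON: "intron",
    PlacementKind.THREE_UTR: "3′-UTR",
    PlacementKind.JUNCTION: "junction",
}
# fixed group order of the canonical label grammar
_KIND_ORDER = [
    PlacementKind.FIVE_UTR,
    PlacementKind.EXON,
    PlacementKind.INTRON,
    PlacementKind.THREE_UTR,
    PlacementKind.JUNCTION,
]
_LABEL_KIND = {v: k for k, v in _KIND_LABEL.items()}

_ORDINAL_KINDS = (PlacementKind.INTRON, PlacementKind.EXON)


def round_half_up(value: float | Decimal, decimals: int = 1) -> float:
    """Round half up (so 0.05 -> 0.1)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(str(value)).quantize(q, rounding=ROUND_HALF_UP))


def printed_percentage(numerator: int, denominator: int) -> float:
    """Percentage truncated to one decimal (849/1600 -> 53.0, not 53.1).

    Catalog fractions are reported the way screening studies print them:
    the second decimal is dropped, never rounded up, so a fraction only
    reaches x.y% once it is fully attained.  Exact ratios are unaffected.
    """
    pct = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_DOWN))


def _covered_by(blocks: Sequence[GenomicInterval], iv: GenomicInterval) -> bool:
    pos = iv.start
    for b in sorted(blocks, key=lambda b: b.start):
        if b.start > pos:
            break
        pos = max(pos, b.end)
        if pos >= iv.end:
            return True
    return pos >= iv.end


def classify_in_transcript(
    interval: GenomicInterval, transcript: TranscriptModel
) -> Placement | None:
    """Place ``interval`` within one transcript, or None if outside its span.

    Precedence: full containment in the 5'-UTR (then 3'-UTR) union wins over
    an exon ordinal, so UTR-resident miRNAs are labelled as UTR rather than
    "exon 1"; an interval inside the span that straddles an exon-intron
    boundary is a junction.
    """
    if interval.chrom != transcript.chrom or interval.strand is not transcript.strand:
        raise ValueError("interval and transcript must share chromosome and strand")
    if not transcript.span.contains(interval):
        return None
    tid = transcript.transcript_id
    if transcript.five_utr and _covered_by(transcript.five_utr, interval):
        return Placement(tid, PlacementKind.FIVE_UTR)
    if transcript.three_utr and _covered_by(transcript.three_utr, interval):
        return Placement(tid, PlacementKind.THREE_UTR)
    for k, intron in enumerate(transcript.introns_tx_order(), start=1):
        if intron.contains(interval):
            return Placement(tid, PlacementKind.INTRON, k)
    for k, exon in enumerate(transcript.exons_tx_order(), start=1):
        if exon.contains(interval):
            return Placement(tid, PlacementKind.EXON, k)
    return Placement(tid, PlacementKind.JUNCTION)


def aggregate_assignment(
    placements: Sequence[Placement],
) -> tuple[str, Category]:
    """Collapse per-transcript placements into one label and category.

    Label grammar: kind groups in the fixed order 5'-UTR, exon, intron,
    3'-UTR, junction; ordinal kinds list ascending deduplicated ordinals
    (no range compression); groups joined by "; ".  An empty placement list
    means the miRNA sits in the gene span outside every transcript span.
    """
    if not placements:
        return GENE_BODY_LABEL, Category.GENE_BODY
    by_kind: dict[PlacementKind, set[int]] = defaultdict(set)
    for p in placements:
        if p.kind in _ORDINAL_KINDS:
            by_kind[p.kind].add(p.ordinal)
        else:
            by_kind.setdefault(p.kind, set())
    groups = []
    for kind in _KIND_ORDER:
        if kind not in by_kind:
            continue
        if kind in _ORDINAL_KINDS:
            ords = ", ".join(str(o) for o in sorted(by_kind[kind]))
            groups.append(f"{_KIND_LABEL[kind]} {ords}")
        else:
            groups.append(_KIND_LABEL[kind])
    label = "; ".join(groups)
    kinds = set(by_kind)
    if PlacementKind.JUNCTION in kinds or len(kinds) > 1:
        category = Category.MIXED
    else:
        category = Category((next(iter(kinds))).value)
    return label, category


def parse_location_label(label: str) -> dict[PlacementKind, frozenset[int]]:
    """Parse a canonical location label back into kind -> ordinal sets.

    Non-ordinal kinds map to an empty set; ``gene-body`` parses to an empty
    dict.  Raises ValueError on anything outside the grammar.
    """
    label = label.strip()
    if not label:
        raise ValueError("empty location label")
    if label == GENE_BODY_LABEL:
        return {}
    out: dict[PlacementKind, frozenset[int]] = {}
    for group in label.split("; "):
        group = group.strip()
        if group in _LABEL_KIND:
            out[_LABEL_KIND[group]] = frozenset()
            continue
        head, _, rest = group.partition(" ")
        if head not in ("exon", "intron") or not rest:
            raise ValueError(f"unparseable location label group: {group!r}")
        try:
            ordinals = frozenset(int(tok) for tok in rest.split(", "))
        except ValueError as exc:
            raise ValueError(f"unparseable ordinals in group {group!r}") from exc
        if not ordinals or min(ordinals) < 1:
            raise ValueError(f"invalid ordinals in group {group!r}")
        out[_LABEL_KIND[head]] = ordinals
    return out


def merge_labels(labels: Iterable[str]) -> str:
    """Union several canonical labels into one canonical label."""
    merged: dict[PlacementKind, set[int]] = {}
    for label in labels:
        for kind, ords in parse_location_label(label).items():
            merged.setdefault(kind, set()).update(ords)
    if not merged:
        return GENE_BODY_LABEL
    groups = []
    for kind in _KIND_ORDER:
        if kind not in merged:
            continue
        if kind in _ORDINAL_KINDS:
            groups.append(f"{_KIND_LABEL[kind]} " + ", ".join(
                str(o) for o in sorted(merged[kind])))
        else:
            groups.append(_KIND_LABEL[kind])
    return "; ".join(groups)


def category_of_kinds(kinds: set[PlacementKind]) -> Category:
    if not kinds:
        return Category.GENE_BODY
    if PlacementKind.JUNCTION in kinds or len(kinds) > 1:
        return Category.MIXED
    return Category(next(iter(kinds)).value)


# ---------------------------------------------------------------------------
# Host assignment
# ---------------------------------------------------------------------------

def assign_hosts(
    mirnas: Sequence[MiRNAGene],
    genes: Sequence[GeneModel],
    policy: str = "full_sense",
) -> tuple[list[HostAssignment], OverlapTallies]:
    """Assign each miRNA precursor to every host gene that fully contains it
    on the same strand.  Returns (assignments, excluded-overlap tallies).

    A miRNA contained in two overlapping genes yields two assignments.
    Containment is closed-interval: a precursor coterminous with the gene
    boundary counts as contained.
    """
    if policy != "full_sense":
        raise ValueError(f"unknown containment policy: {policy}")
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for g in genes:
        trees[g.span.chrom].addi(g.span.start, g.span.end, g)
    assignments: list[HostAssignment] = []
    tallies = OverlapTallies()
    for m in sorted(mirnas, key=lambda m: (m.interval.chrom, m.interval.start,
                                           m.precursor_id)):
        iv = m.interval
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        hits = sorted(tree.overlap(iv.start, iv.end), key=lambda h: h.data.gene_id)
        for hit in hits:
            gene: GeneModel = hit.data
            if gene.span.strand is not iv.strand:
                tallies.antisense += 1
                continue
            if not gene.span.contains(iv):
                tallies.partial_sense += 1
                continue
            placements = []
            for t in gene.transcripts:
                p = classify_in_transcript(iv, t)
                if p is not None:
                    placements.append(p)
            label, category = aggregate_assignment(placements)
            assignments.append(HostAssignment(
                precursor_id=m.precursor_id,
                gene_id=gene.gene_id,
                orientation="sense",
                containment="full",
                placements=placements,
                location_label=label,
                category=category,
            ))
    return assignments, tallies


def build_catalog(
    species: str,
    mirnas: Sequence[MiRNAGene],
    genes: Sequence[GeneModel],
    assignments: Sequence[HostAssignment],
    source: str = "",
) -> Catalog:
    """Flatten assignments into the serializable per-species catalog.

    ``cluster_id`` marks hosts with >= 2 resident miRNAs (``cluster:<gene>``).
    """
    mirna_by_id = {m.precursor_id: m for m in mirnas}
    gene_by_id = {g.gene_id: g for g in genes}
    residents: dict[str, set[str]] = defaultdict(set)
    for a in assignments:
        residents[a.gene_id].add(a.precursor_id)
    entries = []
    for a in assignments:
        m = mirna_by_id[a.precursor_id]
        g = gene_by_id[a.gene_id]
        cluster_id = f"cluster:{a.gene_id}" if len(residents[a.gene_id]) >= 2 else ""
        entries.append(CatalogEntry(
            species=species,
            precursor_id=a.precursor_id,
            mirna_name=m.name,
            chrom=m.interval.chrom,
            start=m.interval.start1,
            end=m.interval.end1,
            strand=m.interval.strand.value,
            gene_id=a.gene_id,
            gene_symbol=g.symbol,
            gene_biotype=g.biotype.value,
            containment=a.containment,
            location_label=a.location_label,
            category=a.category.value,
            cluster_id=cluster_id,
        ))
    return Catalog(species=species, source=source,
                   total_mirnas=len(mirnas), entries=entries)


# ---------------------------------------------------------------------------
# Clusters, biotype partition, summary
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    gene_id: str
    members: list[str]  # precursor ids sorted by genomic start

    @property
    def size(self) -> int:
        return len(self.members)


def detect_clusters(entries: Sequence[CatalogEntry]) -> tuple[list[Cluster], dict[int, int]]:
    """Group resident miRNAs per host; a cluster is a host with >= 2.

    Returns clusters (members sorted by start) and a size histogram.
    """
    per_gene: dict[str, list[tuple[int, str]]] = defaultdict(list)
    for e in entries:
        per_gene[e.gene_id].append((e.start, e.precursor_id))
    clusters = []
    for gene_id in sorted(per_gene):
        members = sorted(set(per_gene[gene_id]))
        if len(members) >= 2:
            clusters.append(Cluster(gene_id=gene_id, members=[p for _, p in members]))
    histogram = dict(Counter(c.size for c in clusters))
    return clusters, histogram


def partition_biotypes(entries: Sequence[CatalogEntry]) -> dict[str, int]:
    """Count each distinct intragenic miRNA once into
    {protein_coding_only, ncRNA_only, both} by the biotypes of its hosts."""
    hosts: dict[str, set[str]] = defaultdict(set)
    for e in entries:
        hosts[e.precursor_id].add(e.gene_biotype)
    counts = {"protein_coding_only": 0, "ncRNA_only": 0, "both": 0}
    for pid, biotypes in hosts.items():
        has_pc = "protein_coding" in biotypes
        has_nc = any(b != "protein_coding" for b in biotypes)
        if has_pc and has_nc:
            counts["both"] += 1
        elif has_pc:
            counts["protein_coding_only"] += 1
        else:
            counts["ncRNA_only"] += 1
    return counts


def summarize_catalog(
    catalog: Catalog, tallies: OverlapTallies | None = None
) -> SummaryStats:
    """Compute the catalog's summary statistics.

    A miRNA contained in several hosts contributes once, with the union of
    its placement kinds across hosts deciding its category.  The intragenic
    fraction is a percentage rounded half-up to one decimal; it is absent
    when the miRNA denominator is zero.
    """
    entries = catalog.entries
    per_mirna_labels: dict[str, list[str]] = defaultdict(list)
    per_mirna_chrom: dict[str, str] = {}
    for e in entries:
        per_mirna_labels[e.precursor_id].append(e.location_label)
        per_mirna_chrom[e.precursor_id] = e.chrom
    category_counts = {c.value: 0 for c in Category}
    for pid, labels in per_mirna_labels.items():
        kinds: set[PlacementKind] = set()
        for label in labels:
            kinds.update(parse_location_label(label))
        category_counts[category_of_kinds(kinds).value] += 1
    intragenic = len(per_mirna_labels)
    total = catalog.total_mirnas
    fraction = None if total == 0 else printed_percentage(intragenic, total)
    ncrna_sub: dict[str, int] = defaultdict(int)
    per_mirna_biotypes: dict[str, set[str]] = defaultdict(set)
    for e in entries:
        per_mirna_biotypes[e.precursor_id].add(e.gene_biotype)
    for biotypes in per_mirna_biotypes.values():
        for b in sorted(biotypes):
            if b != "protein_coding":
                ncrna_sub[b] += 1
    clusters, histogram = detect_clusters(entries)
    per_chrom = Counter(per_mirna_chrom.values())
    multi_host = sum(
        1 for pid in per_mirna_labels
        if len({e.gene_id for e in entries if e.precursor_id == pid}) >= 2
    )
    return SummaryStats(
        total_mirnas=total,
        intragenic_count=intragenic,
        intragenic_fraction=fraction,
        category_counts=category_counts,
        biotype_class_counts=partition_biotypes(entries),
        ncrna_host_subclass_counts=dict(ncrna_sub),
        host_gene_count=len({e.gene_id for e in entries}),
        cluster_count=len(clusters),
        cluster_size_histogram=histogram,
        multi_host_mirna_count=multi_host,
        per_chromosome_counts=dict(per_chrom),
        antisense_count=tallies.antisense if tallies else 0,
        partial_sense_count=tallies.partial_sense if tallies else 0,
    )
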