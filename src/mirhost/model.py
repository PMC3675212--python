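"""Domain types for the intragenic miRNA screen.

Coordinate convention
---------------------
All external files (GFF3/GTF/VCF/TSV) use 1-based inclusive coordinates, as
those formats prescribe.  Every object in this module stores 0-based
half-open coordinates; conversion happens once, at the I/O boundary
(:mod:`mirhost.io`).  ``GenomicInterval.start1`` / ``end1`` expose the
external convention for display and serialization.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "Strand",
    "Biotype",
    "GenomicInterval",
    "TranscriptModel",
    "GeneModel",
    "MatureMiRNA",
    "MiRNAGene",
    "Variant",
    "OrthologyMap",
    "Placement",
    "HostAssignment",
    "OverlapTallies",
    "SummaryStats",
    "CatalogEntry",
    "Catalog",
    "SeedDefinition",
    "SeedVariantHit",
    "MiRNAStem",
    "ConservedPair",
    "CrossRefRow",
    "ModelError",
    "harmonize_chrom",
]

NCRNA_BIOTYPES = frozenset({"lincRNA", "snoRNA", "miRNA", "other_ncRNA"})


class ModelError(ValueError):
    """Raised when a domain invariant is violated at construction time."""


class Strand(str, enum.Enum):
    PLUS = "+"
    MINUS = "-"

    def flipped(self) -> "Strand":
        return Strand.MINUS if self is Strand.PLUS else Strand.PLUS


class Biotype(str, enum.Enum):
    """Host-gene biotype classes tracked by the catalog."""

    PROTEIN_CODING = "protein_coding"
    LINCRNA = "lincRNA"
    SNORNA = "snoRNA"
    MIRNA = "miRNA"
    OTHER_NCRNA = "other_ncRNA"

    @property
    def is_ncrna(self) -> bool:
        return self is not Biotype.PROTEIN_CODING

    @classmethod
    def from_source(cls, raw: str) -> "Biotype":
        """Map a source-annotation biotype string into the enumeration.

        Unknown biotypes collapse to ``other_ncRNA``; the caller is expected
        to log that collapse.
        """
        canon = {
            "protein_coding": cls.PROTEIN_CODING,
            "lincrna": cls.LINCRNA,
            "snorna": cls.SNORNA,
            "mirna": cls.MIRNA,
            "other_ncrna": cls.OTHER_NCRNA,
        }
        return canon.get(raw.strip().lower(), cls.OTHER_NCRNA)


def harmonize_chrom(name: str, aliases: Mapping[str, str] | None = None) -> str:
    """Normalize a chromosome name: strip a leading ``chr`` (any case), then
    apply the optional user alias table.  Exact string matching afterwards."""
    name = name.strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    if aliases:
        name = aliases.get(name, name)
    if not name:
        raise ModelError("empty chromosome name after harmonization")
    return name


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open internally."""

    chrom: str
    start: int
    end: int
    strand: Strand

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ModelError("interval chromosome must be non-empty")
        if self.start < 0:
            raise ModelError(f"interval start {self.start} < 0")
        if self.start >= self.end:
            raise ModelError(
                f"empty/inverted interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if not isinstance(self.strand, Strand):
            object.__setattr__(self, "strand", Strand(self.strand))

    # -- external (1-based inclusive) views --------------------------------
    @property
    def start1(self) -> int:
        return self.start + 1

    @property
    def end1(self) -> int:
        return self.end

    @classmethod
    def from_gff(cls, chrom: str, start1: int, end1: int, strand: str) -> "GenomicInterval":
        return cls(chrom, start1 - 1, end1, Strand(strand))

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        """Positional containment (chromosome required; strand ignored)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def same_strand(self, other: "GenomicInterval") -> bool:
        return self.strand is other.strand


def _union_covers(blocks: list[GenomicInterval], iv: GenomicInterval) -> bool:
    """True if ``iv`` is fully covered by the union of ``blocks``."""
    pos = iv.start
    for b in sorted(blocks, key=lambda b: b.start):
        if b.chrom != iv.chrom:
            continue
        if b.start > pos:
            break
        pos = max(pos, b.end)
        if pos >= iv.end:
            return True
    return pos >= iv.end


@dataclass
class TranscriptModel:
    """One transcript: ordered exons plus optional UTR blocks.

    Introns are derived at construction as the gaps between genomically
    adjacent exons; for a transcript with E exons there are exactly E-1.
    """

    transcript_id: str
    parent_gene_id: str
    exons: list[GenomicInterval]
    five_utr: list[GenomicInterval] = field(default_factory=list)
    three_utr: list[GenomicInterval] = field(default_factory=list)
    introns: list[GenomicInterval] = field(init=False)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ModelError(f"transcript {self.transcript_id} has zero exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ModelError(
                f"transcript {self.transcript_id} mixes chromosomes/strands"
            )
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ModelError(
                    f"overlapping exons in transcript {self.transcript_id}"
                )
        self.introns = [
            GenomicInterval(a.chrom, a.end, b.start, a.strand)
            for a, b in zip(self.exons, self.exons[1:])
            if a.end < b.start
        ]
        if len(self.introns) != len(self.exons) - 1:
            # adjacent exons abutting with no gap would break intron numbering
            raise ModelError(
                f"transcript {self.transcript_id} has abutting exons (zero-length intron)"
            )
        for utr in (*self.five_utr, *self.three_utr):
            if not _union_covers(self.exons, utr):
                raise ModelError(
                    f"UTR block outside exons in transcript {self.transcript_id}"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> Strand:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    def exons_tx_order(self) -> list[GenomicInterval]:
        """Exons in transcription order (exon 1 first)."""
        return self.exons if self.strand is Strand.PLUS else self.exons[::-1]

    def introns_tx_order(self) -> list[GenomicInterval]:
        return self.introns if self.strand is Strand.PLUS else self.introns[::-1]


@dataclass
class GeneModel:
    gene_id: str
    symbol: str
    biotype: Biotype
    transcripts: list[TranscriptModel]
    span: GenomicInterval = field(init=False)

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ModelError(f"gene {self.gene_id} has no transcripts")
        chroms = {t.chrom for t in self.transcripts}
        strands = {t.strand for t in self.transcripts}
        if len(chroms) != 1 or len(strands) != 1:
            raise ModelError(f"gene {self.gene_id} mixes chromosomes/strands")
        start = min(t.span.start for t in self.transcripts)
        end = max(t.span.end for t in self.transcripts)
        self.span = GenomicInterval(chroms.pop(), start, end, strands.pop())


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature product annotated inside a precursor; carries the seed."""

    mature_id: str
    name: str
    interval: GenomicInterval
    derives_from: str

    def __post_init__(self) -> None:
        if len(self.interval) < 15:
            raise ModelError(f"mature {self.mature_id} shorter than 15 nt")


@dataclass
class MiRNAGene:
    """A miRNA precursor (hairpin) with its linked mature products."""

    precursor_id: str
    name: str
    interval: GenomicInterval
    matures: list[MatureMiRNA] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.name:
            raise ModelError("miRNA gene name must be non-empty")
        for m in self.matures:
            if m.interval.strand is not self.interval.strand:
                raise ModelError(
                    f"mature {m.mature_id} strand differs from precursor {self.precursor_id}"
                )
            if not self.interval.contains(m.interval):
                raise ModelError(
                    f"mature {m.mature_id} not contained in precursor {self.precursor_id}"
                )


@dataclass(frozen=True)
class Variant:
    variant_id: str
    chrom: str
    pos: int  # 1-based, as in VCF
    ref_allele: str
    alt_alleles: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ModelError(f"variant {self.variant_id} position < 1")
        if not self.ref_allele:
            raise ModelError(f"variant {self.variant_id} has empty REF")

    @property
    def ref_span0(self) -> tuple[int, int]:
        """0-based half-open genomic span of the reference allele."""
        return self.pos - 1, self.pos - 1 + len(self.ref_allele)


@dataclass
class OrthologyMap:
    """Cross-species gene links plus explicit miRNA-name overrides."""

    # frozenset({(species_a, gene_id_a), (species_b, gene_id_b)}) -> link type
    gene_links: dict[frozenset, str] = field(default_factory=dict)
    # canonical stem -> set of member miRNA names (lowercased)
    mirna_overrides: dict[str, set[str]] = field(default_factory=dict)

    def add_link(self, species_a: str, gene_a: str, species_b: str, gene_b: str,
                 link_type: str = "one2one") -> None:
        if species_a == species_b:
            raise ModelError("orthology link must span two distinct species")
        key = frozenset({(species_a, gene_a), (species_b, gene_b)})
        if len(key) < 2:
            raise ModelError("self-link in orthology map")
        existing = self.gene_links.get(key)
        if existing is not None and existing != link_type:
            raise ModelError(
                f"conflicting link types for {sorted(key)}: {existing} vs {link_type}"
            )
        self.gene_links[key] = link_type

    def linked(self, species_a: str, gene_a: str, species_b: str, gene_b: str) -> bool:
        return frozenset({(species_a, gene_a), (species_b, gene_b)}) in self.gene_links

    def link_type(self, species_a: str, gene_a: str, species_b: str, gene_b: str) -> str | None:
        return self.gene_links.get(frozenset({(species_a, gene_a), (species_b, gene_b)}))


# ---------------------------------------------------------------------------
# Screen results
# ---------------------------------------------------------------------------

class PlacementKind(str, enum.Enum):
    INTRON = "intron"
    EXON = "exon"
    FIVE_UTR = "five_utr"
    THREE_UTR = "three_utr"
    JUNCTION = "junction"


@dataclass(frozen=True)
class Placement:
    """Where a miRNA sits within one transcript of its host."""

    transcript_id: str
    kind: PlacementKind
    ordinal: int | None = None  # transcription-direction numbering

    def __post_init__(self) -> None:
        needs_ordinal = self.kind in (PlacementKind.INTRON, PlacementKind.EXON)
        if needs_ordinal and (self.ordinal is None or self.ordinal < 1):
            raise ModelError(f"{self.kind.value} placement requires a positive ordinal")
        if not needs_ordinal and self.ordinal is not None:
            raise ModelError(f"{self.kind.value} placement must not carry an ordinal")


class Category(str, enum.Enum):
    INTRON = "intron"
    EXON = "exon"
    FIVE_UTR = "five_utr"
    THREE_UTR = "three_utr"
    MIXED = "mixed"
    GENE_BODY = "gene_body"


@dataclass
class HostAssignment:
    """One sense-oriented miRNA-in-gene containment."""

    precursor_id: str
    gene_id: str
    orientation: str  # always "sense" for catalog assignments
    containment: str  # "full"
    placements: list[Placement]
    location_label: str
    category: Category


@dataclass
class OverlapTallies:
    """Overlaps excluded from the catalog but counted for reporting."""

    antisense: int = 0
    partial_sense: int = 0


@dataclass
class SummaryStats:
    total_mirnas: int
    intragenic_count: int
    intragenic_fraction: float | None  # percentage, one decimal; None if undefined
    category_counts: dict[str, int]
    biotype_class_counts: dict[str, int]  # protein_coding_only / ncRNA_only / both
    ncrna_host_subclass_counts: dict[str, int]
    host_gene_count: int
    cluster_count: int
    cluster_size_histogram: dict[int, int]
    multi_host_mirna_count: int
    per_chromosome_counts: dict[str, int]
    antisense_count: int = 0
    partial_sense_count: int = 0


@dataclass(frozen=True)
class CatalogEntry:
    """One flattened catalog row: a miRNA resident in one host gene."""

    species: str
    precursor_id: str
    mirna_name: str
    chrom: str
    start: int  # 1-based inclusive, as serialized
    end: int
    strand: str
    gene_id: str
    gene_symbol: str
    gene_biotype: str
    containment: str
    location_label: str
    category: str
    cluster_id: str  # empty when host has a single resident miRNA


@dataclass
class Catalog:
    """The per-species catalog of intragenic miRNAs."""

    species: str
    source: str
    total_mirnas: int
    entries: list[CatalogEntry]

    def __post_init__(self) -> None:
        self.entries = sorted(
            self.entries, key=lambda e: (e.chrom, e.start, e.precursor_id, e.gene_id)
        )
        distinct = len({e.precursor_id for e in self.entries})
        if self.total_mirnas < distinct:
            raise ModelError(
                f"total_mirnas {self.total_mirnas} < {distinct} distinct intragenic miRNAs"
            )

    @property
    def intragenic_precursors(self) -> set[str]:
        return {e.precursor_id for e in self.entries}


# ---------------------------------------------------------------------------
# Seed-variant screen
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeedDefinition:
    """Seed positions counted 1-based from the mature 5' end (default 2-8)."""

    first: int = 2
    last: int = 8

    def __post_init__(self) -> None:
        if not (1 <= self.first < self.last <= 10):
            raise ModelError(f"invalid seed definition {self.first}-{self.last}")

    @property
    def length(self) -> int:
        return self.last - self.first + 1


@dataclass(frozen=True)
class SeedVariantHit:
    mature_id: str
    precursor_id: str
    variant_id: str
    offset: int  # 1 = first seed base (5' side)
    seed_interval: GenomicInterval

    def __post_init__(self) -> None:
        if not (1 <= self.offset <= len(self.seed_interval)):
            raise ModelError(f"seed hit offset {self.offset} outside the seed")


# ---------------------------------------------------------------------------
# Cross-species conservation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MiRNAStem:
    """Tiered normalization of a miRNA gene name.

    tier1 strips the species prefix and a trailing ``-<int>`` paralog
    counter; tier2 additionally strips a single trailing letter variant
    (``mir-103a`` -> ``mir-103``), except for the let-7 family whose letters
    distinguish genuine family members.
    """

    raw_name: str
    tier1_stem: str
    tier2_stem: str | None

    @property
    def tier2_key(self) -> str:
        """Coarse matching key: tier2 when defined, else tier1."""
        return self.tier2_stem if self.tier2_stem is not None else self.tier1_stem


@dataclass(frozen=True)
class ConservedEntry:
    species: str
    precursor_name: str
    gene_id: str
    gene_symbol: str
    location_label: str


@dataclass
class ConservedPair:
    """A miRNA stem co-located in orthologous hosts across >= 2 species."""

    stem: str
    match_tier: str  # "1", "2", or "override"
    entries: list[ConservedEntry]

    @property
    def species_set(self) -> frozenset[str]:
        return frozenset(e.species for e in self.entries)

    def __post_init__(self) -> None:
        if len(self.species_set) < 2:
            raise ModelError("conserved pair needs >= 2 species")


# ---------------------------------------------------------------------------
# List cross-referencing
# ---------------------------------------------------------------------------

@dataclass
class CrossRefRow:
    query: str
    matched_precursors: list[str]
    matched_genes: list[str]
    location_labels: list[str]
    categories: list[str]
    host_biotypes: list[str]

    @property
    def matched(self) -> bool:
        return bool(self.matched_precursors) or bool(self.matched_genes)
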