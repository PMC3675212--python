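"""Synthetic multi-species annotation generator with a truth manifest.

Every pipeline stage is testable without downloads: the generator builds
toy gene models and plants miRNA precursors in every placement class
(intron k, exon k, 5'-UTR, 3'-UTR, mixed-across-transcripts, clusters,
dual overlapping hosts, gene-body), plus antisense / intergenic /
partial-overlap decoys, seed-region variants, and — in trio mode — three
species with orthologous hosts and planted conserved co-location groups.

Plants are made by construction (intervals chosen inside known introns,
exons or UTRs), then re-checked by an independent per-base labeller before
anything is written, so manifest labels are ground truth rather than the
output of the screening code under test.  Identical (config, seed) yields
byte-identical files.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from pathlib import Path

from . import io as mio
from .model import (
    Biotype,
    GeneModel,
    GenomicInterval,
    MatureMiRNA,
    MiRNAGene,
    OrthologyMap,
    Strand,
    TranscriptModel,
    Variant,
)

__all__ = [
    "GeneratorConfig",
    "TruthManifest",
    "TruthRecord",
    "PlantedHost",
    "SpeciesBundle",
    "TrioBundle",
    "generate_species",
    "generate_trio",
    "write_manifest",
    "read_manifest",
]

MATURE_LEN = 22
_PLACEMENT_CLASSES = ("intron", "exon", "five_utr", "three_utr", "mixed",
                      "cluster", "dual_host", "gene_body")
_DECOY_CLASSES = ("antisense", "intergenic", "partial_overlap")


class GeneratorError(ValueError):
    """Raised for infeasible generator configurations, before any output."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic species (or a trio).

    Planted counts are per placement class; ``cluster`` counts miRNAs (hosts
    hold 2-3 members each) and ``dual_host`` miRNAs each get two hosts.
    Lengths are in base pairs.
    """

    species: str = "synthA"
    name_prefix: str = "syn"
    n_chromosomes: int = 3
    exons_per_transcript: tuple[int, int] = (3, 8)
    exon_length: tuple[int, int] = (140, 300)
    intron_length: tuple[int, int] = (300, 1500)
    utr_length: tuple[int, int] = (150, 250)
    intergenic_spacing: tuple[int, int] = (2000, 8000)
    precursor_length: tuple[int, int] = (70, 90)
    planted: dict[str, int] = field(default_factory=lambda: {
        "intron": 60, "exon": 30, "five_utr": 25, "three_utr": 25,
        "mixed": 25, "cluster": 20, "dual_host": 15, "gene_body": 15,
    })
    decoys: dict[str, int] = field(default_factory=lambda: {
        "antisense": 40, "intergenic": 40, "partial_overlap": 20,
    })
    biotype_mix: dict[str, float] = field(default_factory=lambda: {
        "protein_coding": 0.70, "lincRNA": 0.20, "snoRNA": 0.05,
        "other_ncRNA": 0.05,
    })
    background_genes: int = 20
    intergenic_mirnas: int = 0  # extra plain intergenic miRNAs beyond decoys
    seed_variant_count: int = 30
    seed_first: int = 2
    seed_last: int = 8
    # trio mode
    conserved_triples: int = 27
    conserved_distractors: int = 40
    override_fraction: float = 0.25
    tier2_fraction: float = 0.25

    def validate(self) -> None:
        for name, count in {**self.planted, **self.decoys}.items():
            if count < 0:
                raise GeneratorError(f"negative count for {name}")
        if unknown := set(self.planted) - set(_PLACEMENT_CLASSES):
            raise GeneratorError(f"unknown placement classes: {sorted(unknown)}")
        if unknown := set(self.decoys) - set(_DECOY_CLASSES):
            raise GeneratorError(f"unknown decoy classes: {sorted(unknown)}")
        if abs(sum(self.biotype_mix.values()) - 1.0) > 1e-9:
            raise GeneratorError("biotype proportions must sum to 1")
        if self.planted.get("cluster", 0) == 1:
            raise GeneratorError("a cluster needs >= 2 resident miRNAs")
        if not (1 <= self.seed_first < self.seed_last <= 10):
            raise GeneratorError("invalid seed definition")
        if self.precursor_length[0] < 2 * MATURE_LEN + 4:
            raise GeneratorError("precursor too short for two mature arms")
        if self.utr_length[0] < self.precursor_length[1] + 10:
            raise GeneratorError("UTR length range cannot contain a precursor")
        if self.intron_length[0] < self.precursor_length[1] + 20:
            raise GeneratorError("intron length range cannot contain a precursor")
        if self.exons_per_transcript[0] < 3:
            raise GeneratorError("placement classes require >= 3 exons per transcript")
        if self.conserved_triples < 0 or self.conserved_distractors < 0:
            raise GeneratorError("negative trio counts")


# ---------------------------------------------------------------------------
# Truth manifest
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedHost:
    gene_id: str
    location_label: str
    category: str


@dataclass
class TruthRecord:
    precursor_id: str
    name: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    klass: str  # placement class or decoy class
    hosts: list[PlantedHost] = field(default_factory=list)
    cluster_id: str = ""
    conservation_group: str = ""
    override_required: bool = False


@dataclass(frozen=True)
class PlantedSeedVariant:
    variant_id: str
    mature_id: str
    precursor_id: str
    offset: int  # 1 = first seed base


@dataclass
class TruthManifest:
    species: str
    records: list[TruthRecord] = field(default_factory=list)
    seed_variants: list[PlantedSeedVariant] = field(default_factory=list)

    @property
    def planted(self) -> list[TruthRecord]:
        return [r for r in self.records if r.klass in _PLACEMENT_CLASSES]

    @property
    def decoys(self) -> list[TruthRecord]:
        return [r for r in self.records if r.klass in _DECOY_CLASSES]

    def expected_entries(self) -> set[tuple[str, str, str, str]]:
        """The (precursor, gene, label, category) tuples the screen must find."""
        return {
            (r.precursor_id, h.gene_id, h.location_label, h.category)
            for r in self.planted for h in r.hosts
        }


MANIFEST_COLUMNS = [
    "record_type", "id", "name", "chrom", "start", "end", "strand", "class",
    "hosts", "cluster_id", "conservation_group", "override_required", "extra",
]


def write_manifest(manifest: TruthManifest, path: str | Path) -> None:
    lines = [f"# species={manifest.species}", "\t".join(MANIFEST_COLUMNS)]
    for r in manifest.records:
        hosts = "|".join(f"{h.gene_id}~{h.location_label}~{h.category}" for h in r.hosts)
        lines.append("\t".join([
            "mirna", r.precursor_id, r.name, r.chrom, str(r.start), str(r.end),
            r.strand, r.klass, hosts, r.cluster_id, r.conservation_group,
            "1" if r.override_required else "0", "",
        ]))
    for sv in manifest.seed_variants:
        lines.append("\t".join([
            "seed_variant", sv.variant_id, "", "", "", "", "", "", "", "", "", "",
            f"{sv.mature_id}~{sv.precursor_id}~{sv.offset}",
        ]))
    mio.atomic_write(path, "\n".join(lines) + "\n")


def read_manifest(path: str | Path) -> TruthManifest:
    species = ""
    records: list[TruthRecord] = []
    seed_variants: list[PlantedSeedVariant] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "species=" in line:
                    species = line.split("species=", 1)[1].strip()
                continue
            fields = line.split("\t")
            if fields[0] == "record_type":
                continue
            if fields[0] == "mirna":
                hosts = []
                if fields[8]:
                    for part in fields[8].split("|"):
                        gid, label, category = part.split("~")
                        hosts.append(PlantedHost(gid, label, category))
                records.append(TruthRecord(
                    precursor_id=fields[1], name=fields[2], chrom=fields[3],
                    start=int(fields[4]), end=int(fields[5]), strand=fields[6],
                    klass=fields[7], hosts=hosts, cluster_id=fields[9],
                    conservation_group=fields[10],
                    override_required=fields[11] == "1",
                ))
            elif fields[0] == "seed_variant":
                mature_id, pid, offset = fields[12].split("~")
                seed_variants.append(PlantedSeedVariant(
                    variant_id=fields[1], mature_id=mature_id,
                    precursor_id=pid, offset=int(offset)))
    return TruthManifest(species=species, records=records, seed_variants=seed_variants)


# ---------------------------------------------------------------------------
# Independent per-base verifier
# ---------------------------------------------------------------------------

def _perbase_placement(iv: GenomicInterval, t: TranscriptModel) -> tuple[str, int | None] | None:
    """Label an interval against one transcript by walking it base by base.

    Deliberately naive (position-by-position membership) so it cannot share
    a defect with the interval arithmetic used by the screen.
    """
    if not (t.span.start <= iv.start and iv.end <= t.span.end):
        return None

    def exon_at(pos: int) -> int | None:
        for k, e in enumerate(t.exons_tx_order(), start=1):
            if e.start <= pos < e.end:
                return k
        return None

    def intron_at(pos: int) -> int | None:
        for k, i in enumerate(t.introns_tx_order(), start=1):
            if i.start <= pos < i.end:
                return k
        return None

    def in_blocks(pos: int, blocks) -> bool:
        return any(b.start <= pos < b.end for b in blocks)

    positions = range(iv.start, iv.end)
    if t.five_utr and all(in_blocks(p, t.five_utr) for p in positions):
        return ("five_utr", None)
    if t.three_utr and all(in_blocks(p, t.three_utr) for p in positions):
        return ("three_utr", None)
    intron_ids = {intron_at(p) for p in positions}
    if None not in intron_ids and len(intron_ids) == 1:
        return ("intron", intron_ids.pop())
    exon_ids = {exon_at(p) for p in positions}
    if None not in exon_ids and len(exon_ids) == 1:
        return ("exon", exon_ids.pop())
    return ("junction", None)


_LABEL_NAMES = {"five_utr": "5′-UTR", "three_utr": "3′-UTR", "exon": "exon",
                "intron": "intron", "junction": "junction"}
_ORDER = ["five_utr", "exon", "intron", "three_utr", "junction"]


def _perbase_label(iv: GenomicInterval, gene: GeneModel) -> tuple[str, str]:
    """(location label, category) from the per-base verifier, gene level."""
    kinds: dict[str, set[int]] = {}
    for t in gene.transcripts:
        p = _perbase_placement(iv, t)
        if p is None:
            continue
        kind, ordinal = p
        kinds.setdefault(kind, set())
        if ordinal is not None:
            kinds[kind].add(ordinal)
    if not kinds:
        return "gene-body", "gene_body"
    groups = []
    for kind in _ORDER:
        if kind not in kinds:
            continue
        if kind in ("exon", "intron"):
            groups.append(f"{_LABEL_NAMES[kind]} "
                          + ", ".join(str(o) for o in sorted(kinds[kind])))
        else:
            groups.append(_LABEL_NAMES[kind])
    label = "; ".join(groups)
    if "junction" in kinds or len(kinds) > 1:
        category = "mixed"
    else:
        category = next(iter(kinds))
    return label, category


# ---------------------------------------------------------------------------
# Species builder
# ---------------------------------------------------------------------------

def _intron_tx_ordinal(n_exons: int, genomic_gap: int, strand: Strand) -> int:
    """Transcription-order ordinal of the ``genomic_gap``-th gap (1 = leftmost)."""
    return genomic_gap if strand is Strand.PLUS else n_exons - genomic_gap


def _exon_tx_ordinal(n_exons: int, genomic_index: int, strand: Strand) -> int:
    return genomic_index if strand is Strand.PLUS else n_exons - genomic_index + 1


class _SpeciesBuilder:
    def __init__(self, config: GeneratorConfig, rng: random.Random):
        config.validate()
        self.cfg = config
        self.rng = rng
        self.genes: list[GeneModel] = []
        self.mirnas: list[MiRNAGene] = []
        self.variants: list[Variant] = []
        self.manifest = TruthManifest(species=config.species)
        self.chroms = [f"{i + 1}" for i in range(config.n_chromosomes)]
        self.cursors = {c: 1000 for c in self.chroms}
        self._chrom_idx = 0
        self._gene_n = 0
        self._mirna_n = 100

    # -- allocation helpers -------------------------------------------------
    def _next_block(self) -> str:
        chrom = self.chroms[self._chrom_idx % len(self.chroms)]
        self._chrom_idx += 1
        return chrom

    def _advance(self, chrom: str, end: int) -> None:
        self.cursors[chrom] = end + self.rng.randint(*self.cfg.intergenic_spacing)

    def _gene_id(self) -> str:
        self._gene_n += 1
        return f"{self.cfg.species}:G{self._gene_n:05d}"

    def _mirna_ids(self, stem_name: str | None = None) -> tuple[str, str]:
        self._mirna_n += 1
        pid = f"{self.cfg.species}:MI{self._mirna_n:05d}"
        name = stem_name or f"{self.cfg.name_prefix}-mir-{self._mirna_n}"
        return pid, name

    def _strand(self) -> Strand:
        return Strand.PLUS if self.rng.random() < 0.5 else Strand.MINUS

    def _biotype(self, coding_required: bool = False) -> Biotype:
        if coding_required:
            return Biotype.PROTEIN_CODING
        r = self.rng.random()
        acc = 0.0
        for name, p in self.cfg.biotype_mix.items():
            acc += p
            if r < acc:
                return Biotype(name)
        return Biotype.PROTEIN_CODING

    # -- feature construction ----------------------------------------------
    def _exon_coords(self, chrom: str, n_exons: int,
                     exon_lens: list[int] | None = None,
                     intron_lens: list[int] | None = None) -> list[tuple[int, int]]:
        start = self.cursors[chrom]
        exon_lens = exon_lens or [self.rng.randint(*self.cfg.exon_length)
                                  for _ in range(n_exons)]
        intron_lens = intron_lens or [self.rng.randint(*self.cfg.intron_length)
                                      for _ in range(n_exons - 1)]
        coords = []
        pos = start
        for i, el in enumerate(exon_lens):
            coords.append((pos, pos + el))
            pos += el
            if i < len(intron_lens):
                pos += intron_lens[i]
        return coords

    def _make_gene(self, chrom: str, strand: Strand, coords: list[tuple[int, int]],
                   biotype: Biotype, utr5_len: int = 0, utr3_len: int = 0,
                   extra_transcripts: list[list[tuple[int, int]]] | None = None,
                   ) -> GeneModel:
        gid = self._gene_id()

        def tx(tx_coords: list[tuple[int, int]], idx: int,
               with_utrs: bool) -> TranscriptModel:
            exons = [GenomicInterval(chrom, s, e, strand) for s, e in tx_coords]
            utr5: list[GenomicInterval] = []
            utr3: list[GenomicInterval] = []
            if with_utrs and biotype is Biotype.PROTEIN_CODING:
                first = exons[0] if strand is Strand.PLUS else exons[-1]
                last = exons[-1] if strand is Strand.PLUS else exons[0]
                if utr5_len:
                    if strand is Strand.PLUS:
                        utr5 = [GenomicInterval(chrom, first.start,
                                                first.start + utr5_len, strand)]
                    else:
                        utr5 = [GenomicInterval(chrom, first.end - utr5_len,
                                                first.end, strand)]
                if utr3_len:
                    if strand is Strand.PLUS:
                        utr3 = [GenomicInterval(chrom, last.end - utr3_len,
                                                last.end, strand)]
                    else:
                        utr3 = [GenomicInterval(chrom, last.start,
                                                last.start + utr3_len, strand)]
            return TranscriptModel(transcript_id=f"{gid}.t{idx}", parent_gene_id=gid,
                                   exons=exons, five_utr=utr5, three_utr=utr3)

        transcripts = [tx(coords, 1, True)]
        for i, extra in enumerate(extra_transcripts or [], start=2):
            transcripts.append(tx(extra, i, True))
        gene = GeneModel(gene_id=gid, symbol=f"SYM{gid.rsplit('G', 1)[-1]}",
                         biotype=biotype, transcripts=transcripts)
        self.genes.append(gene)
        return gene

    def _make_mirna(self, chrom: str, start: int, length: int, strand: Strand,
                    name: str | None = None) -> MiRNAGene:
        pid, nm = self._mirna_ids(name)
        iv = GenomicInterval(chrom, start, start + length, strand)
        arm_left = GenomicInterval(chrom, iv.start + 11, iv.start + 11 + MATURE_LEN, strand)
        arm_right = GenomicInterval(chrom, iv.end - 11 - MATURE_LEN, iv.end - 11, strand)
        five_arm, three_arm = ((arm_left, arm_right) if strand is Strand.PLUS
                               else (arm_right, arm_left))
        matures = [
            MatureMiRNA(f"{pid}_5p", f"{nm}-5p", five_arm, pid),
            MatureMiRNA(f"{pid}_3p", f"{nm}-3p", three_arm, pid),
        ]
        mirna = MiRNAGene(precursor_id=pid, name=nm, interval=iv, matures=matures)
        self.mirnas.append(mirna)
        return mirna

    def _plen(self) -> int:
        return self.rng.randint(*self.cfg.precursor_length)

    def _record(self, mirna: MiRNAGene, klass: str, hosts: list[PlantedHost],
                **kw) -> TruthRecord:
        rec = TruthRecord(
            precursor_id=mirna.precursor_id, name=mirna.name,
            chrom=mirna.interval.chrom, start=mirna.interval.start1,
            end=mirna.interval.end1, strand=mirna.interval.strand.value,
            klass=klass, hosts=hosts, **kw)
        self.manifest.records.append(rec)
        return rec

    # -- placement-class plants --------------------------------------------
    def plant_intron(self, name: str | None = None, biotype: Biotype | None = None,
                     conservation_group: str = "", override_required: bool = False,
                     ) -> TruthRecord:
        chrom = self._next_block()
        strand = self._strand()
        n_exons = self.rng.randint(*self.cfg.exons_per_transcript)
        coords = self._exon_coords(chrom, n_exons)
        gene = self._make_gene(chrom, strand, coords,
                               biotype or self._biotype(),
                               utr5_len=0, utr3_len=0)
        gap = self.rng.randint(1, n_exons - 1)  # genomic gap index
        gap_start, gap_end = coords[gap - 1][1], coords[gap][0]
        plen = self._plen()
        mstart = self.rng.randint(gap_start + 5, gap_end - plen - 5)
        mirna = self._make_mirna(chrom, mstart, plen, strand, name)
        ordinal = _intron_tx_ordinal(n_exons, gap, strand)
        self._advance(chrom, gene.span.end)
        return self._record(
            mirna, "intron",
            [PlantedHost(gene.gene_id, f"intron {ordinal}", "intron")],
            conservation_group=conservation_group,
            override_required=override_required)

    def plant_exon(self) -> TruthRecord:
        chrom = self._next_block()
        strand = self._strand()
        n_exons = self.rng.randint(*self.cfg.exons_per_transcript)
        idx = self.rng.randint(2, n_exons - 1)  # middle exon, genomic index
        plen = self._plen()
        exon_lens = [self.rng.randint(*self.cfg.exon_length) for _ in range(n_exons)]
        exon_lens[idx - 1] = max(exon_lens[idx - 1], plen + 20)
        coords = self._exon_coords(chrom, n_exons, exon_lens=exon_lens)
        gene = self._make_gene(chrom, strand, coords, self._biotype())
        es, ee = coords[idx - 1]
        mstart = self.rng.randint(es + 5, ee - plen - 5)
        mirna = self._make_mirna(chrom, mstart, plen, strand)
        ordinal = _exon_tx_ordinal(n_exons, idx, strand)
        self._advance(chrom, gene.span.end)
        return self._record(
            mirna, "exon",
            [PlantedHost(gene.gene_id, f"exon {ordinal}", "exon")])

    def _plant_utr(self, which: str) -> TruthRecord:
        chrom = self._next_block()
        strand = self._strand()
        n_exons = self.rng.randint(*self.cfg.exons_per_transcript)
        plen = self._plen()
        utr_len = self.rng.randint(max(self.cfg.utr_length[0], plen + 10),
                                   self.cfg.utr_length[1])
        exon_lens = [self.rng.randint(*self.cfg.exon_length) for _ in range(n_exons)]
        # the UTR sits in the transcription-first (5') or -last (3') exon
        if which == "five_utr":
            host_exon = 0 if strand is Strand.PLUS else n_exons - 1
        else:
            host_exon = n_exons - 1 if strand is Strand.PLUS else 0
        exon_lens[host_exon] = max(exon_lens[host_exon], utr_len + 20)
        coords = self._exon_coords(chrom, n_exons, exon_lens=exon_lens)
        gene = self._make_gene(
            chrom, strand, coords, Biotype.PROTEIN_CODING,
            utr5_len=utr_len if which == "five_utr" else 0,
            utr3_len=utr_len if which == "three_utr" else 0)
        t = gene.transcripts[0]
        utr_blocks = t.five_utr if which == "five_utr" else t.three_utr
        block = utr_blocks[0]
        mstart = self.rng.randint(block.start + 2, block.end - plen - 2)
        mirna = self._make_mirna(chrom, mstart, plen, strand)
        label = "5′-UTR" if which == "five_utr" else "3′-UTR"
        self._advance(chrom, gene.span.end)
        return self._record(mirna, which,
                            [PlantedHost(gene.gene_id, label, which)])

    def plant_five_utr(self) -> TruthRecord:
        return self._plant_utr("five_utr")

    def plant_three_utr(self) -> TruthRecord:
        return self._plant_utr("three_utr")

    def plant_mixed(self) -> TruthRecord:
        """Intron of transcript 1, cassette exon of transcript 2."""
        chrom = self._next_block()
        strand = self._strand()
        n_exons = self.rng.randint(*self.cfg.exons_per_transcript)
        intron_lens = [self.rng.randint(*self.cfg.intron_length)
                       for _ in range(n_exons - 1)]
        gap = self.rng.randint(1, n_exons - 1)
        plen = self._plen()
        intron_lens[gap - 1] = max(intron_lens[gap - 1], plen + 260)
        coords = self._exon_coords(chrom, n_exons, intron_lens=intron_lens)
        gap_start, gap_end = coords[gap - 1][1], coords[gap][0]
        mstart = self.rng.randint(gap_start + 110, gap_end - plen - 110)
        cassette = (mstart - 30, mstart + plen + 30)
        alt_coords = sorted(coords + [cassette])
        gene = self._make_gene(chrom, strand, coords, self._biotype(),
                               extra_transcripts=[alt_coords])
        mirna = self._make_mirna(chrom, mstart, plen, strand)
        intron_ord = _intron_tx_ordinal(n_exons, gap, strand)
        exon_ord = _exon_tx_ordinal(n_exons + 1, gap + 1, strand)
        label = f"exon {exon_ord}; intron {intron_ord}"
        self._advance(chrom, gene.span.end)
        return self._record(mirna, "mixed",
                            [PlantedHost(gene.gene_id, label, "mixed")])

    def plant_cluster(self, n_members: int) -> list[TruthRecord]:
        chrom = self._next_block()
        strand = self._strand()
        n_exons = max(self.rng.randint(*self.cfg.exons_per_transcript),
                      n_members + 1)
        coords = self._exon_coords(chrom, n_exons)
        gene = self._make_gene(chrom, strand, coords, self._biotype())
        gaps = sorted(self.rng.sample(range(1, n_exons), n_members))
        records = []
        for gap in gaps:
            gap_start, gap_end = coords[gap - 1][1], coords[gap][0]
            plen = self._plen()
            mstart = self.rng.randint(gap_start + 5, gap_end - plen - 5)
            mirna = self._make_mirna(chrom, mstart, plen, strand)
            ordinal = _intron_tx_ordinal(n_exons, gap, strand)
            records.append(self._record(
                mirna, "cluster",
                [PlantedHost(gene.gene_id, f"intron {ordinal}", "intron")],
                cluster_id=f"cluster:{gene.gene_id}"))
        self._advance(chrom, gene.span.end)
        return records

    def plant_dual_host(self, second_host_ncrna: bool) -> TruthRecord:
        """One miRNA inside two overlapping same-strand genes."""
        chrom = self._next_block()
        strand = self._strand()
        s = self.cursors[chrom]
        plen = self._plen()
        coords_a = [(s, s + 300), (s + 1300, s + 1600), (s + 2600, s + 2900)]
        coords_b = [(s + 1650, s + 1750), (s + 2000, s + 2100), (s + 3200, s + 3500)]
        mstart = 1800 + s
        gene_a = self._make_gene(chrom, strand, coords_a, Biotype.PROTEIN_CODING)
        gene_b = self._make_gene(
            chrom, strand, coords_b,
            Biotype.LINCRNA if second_host_ncrna else Biotype.PROTEIN_CODING)
        mirna = self._make_mirna(chrom, mstart, plen, strand)
        ord_a = _intron_tx_ordinal(3, 2, strand)
        ord_b = _intron_tx_ordinal(3, 1, strand)
        self._advance(chrom, s + 3500)
        return self._record(mirna, "dual_host", [
            PlantedHost(gene_a.gene_id, f"intron {ord_a}", "intron"),
            PlantedHost(gene_b.gene_id, f"intron {ord_b}", "intron"),
        ])

    def plant_gene_body(self) -> TruthRecord:
        """Inside the gene span but outside every transcript span."""
        chrom = self._next_block()
        strand = self._strand()
        s = self.cursors[chrom]
        coords_1 = [(s, s + 200), (s + 500, s + 700)]
        coords_2 = [(s + 1500, s + 1700), (s + 2000, s + 2200)]
        plen = self._plen()
        mstart = s + 1000
        gene = self._make_gene(chrom, strand, coords_1, self._biotype(),
                               extra_transcripts=[coords_2])
        mirna = self._make_mirna(chrom, mstart, plen, strand)
        self._advance(chrom, s + 2200)
        return self._record(mirna, "gene_body",
                            [PlantedHost(gene.gene_id, "gene-body", "gene_body")])

    # -- decoys -------------------------------------------------------------
    def plant_antisense(self) -> TruthRecord:
        chrom = self._next_block()
        strand = self._strand()
        n_exons = self.rng.randint(*self.cfg.exons_per_transcript)
        coords = self._exon_coords(chrom, n_exons)
        gene = self._make_gene(chrom, strand, coords, self._biotype())
        gap = self.rng.randint(1, n_exons - 1)
        gap_start, gap_end = coords[gap - 1][1], coords[gap][0]
        plen = self._plen()
        mstart = self.rng.randint(gap_start + 5, gap_end - plen - 5)
        mirna = self._make_mirna(chrom, mstart, plen, strand.flipped())
        self._advance(chrom, gene.span.end)
        return self._record(mirna, "antisense", [])

    def plant_intergenic(self) -> TruthRecord:
        chrom = self._next_block()
        plen = self._plen()
        mstart = self.cursors[chrom] + self.rng.randint(100, 600)
        mirna = self._make_mirna(chrom, mstart, plen, self._strand())
        self._advance(chrom, mstart + plen)
        return self._record(mirna, "intergenic", [])

    def plant_partial_overlap(self) -> TruthRecord:
        chrom = self._next_block()
        strand = self._strand()
        n_exons = self.rng.randint(*self.cfg.exons_per_transcript)
        coords = self._exon_coords(chrom, n_exons)
        gene = self._make_gene(chrom, strand, coords, self._biotype())
        plen = self._plen()
        mstart = gene.span.start - plen // 2
        mirna = self._make_mirna(chrom, mstart, plen, strand)
        self._advance(chrom, gene.span.end)
        return self._record(mirna, "partial_overlap", [])

    def plant_background_gene(self) -> None:
        chrom = self._next_block()
        n_exons = self.rng.randint(*self.cfg.exons_per_transcript)
        coords = self._exon_coords(chrom, n_exons)
        gene = self._make_gene(chrom, self._strand(), coords, self._biotype())
        self._advance(chrom, gene.span.end)

    # -- seed variants ------------------------------------------------------
    def plant_seed_variants(self) -> None:
        cfg = self.cfg
        planted_ids = {r.precursor_id for r in self.manifest.planted}
        candidates = [m for g in self.mirnas if g.precursor_id in planted_ids
                      for m in g.matures]
        if cfg.seed_variant_count > len(candidates):
            raise GeneratorError(
                f"{cfg.seed_variant_count} seed variants requested but only "
                f"{len(candidates)} mature arms planted")
        chosen = self.rng.sample(candidates, cfg.seed_variant_count)
        seed_len = cfg.seed_last - cfg.seed_first + 1
        for i, mature in enumerate(sorted(chosen, key=lambda m: m.mature_id)):
            offset = self.rng.randint(1, seed_len)
            iv = mature.interval
            # direct position arithmetic, independent of the screen's projection
            if iv.strand is Strand.PLUS:
                pos1 = iv.start1 + (cfg.seed_first - 1) + (offset - 1)
            else:
                pos1 = iv.end1 - (cfg.seed_first - 1) - (offset - 1)
            vid = f"rs_syn_{i:04d}"
            self.variants.append(Variant(vid, iv.chrom, pos1, "A", ("G",)))
            self.manifest.seed_variants.append(PlantedSeedVariant(
                variant_id=vid, mature_id=mature.mature_id,
                precursor_id=mature.derives_from, offset=offset))
        # near-miss decoys: the base just 3' of the seed (mature position
        # seed_last + 1) and one upstream of the mature
        for j, mature in enumerate(sorted(chosen, key=lambda m: m.mature_id)[:10]):
            iv = mature.interval
            if iv.strand is Strand.PLUS:
                pos1 = iv.start1 + cfg.seed_last
            else:
                pos1 = iv.end1 - cfg.seed_last
            self.variants.append(Variant(f"rs_decoy_{j:04d}", iv.chrom, pos1, "C", ("T",)))

    # -- assembly -----------------------------------------------------------
    def build(self) -> None:
        cfg = self.cfg
        for _ in range(cfg.planted.get("intron", 0)):
            self.plant_intron()
        for _ in range(cfg.planted.get("exon", 0)):
            self.plant_exon()
        for _ in range(cfg.planted.get("five_utr", 0)):
            self.plant_five_utr()
        for _ in range(cfg.planted.get("three_utr", 0)):
            self.plant_three_utr()
        for _ in range(cfg.planted.get("mixed", 0)):
            self.plant_mixed()
        remaining = cfg.planted.get("cluster", 0)
        while remaining > 0:
            size = 2 if remaining < 3 or self.rng.random() < 0.6 else 3
            size = min(size, remaining)
            if size < 2:
                size = 2  # unreachable given validate(); defensive
            self.plant_cluster(size)
            remaining -= size
        for i in range(cfg.planted.get("dual_host", 0)):
            self.plant_dual_host(second_host_ncrna=(i % 2 == 0))
        for _ in range(cfg.planted.get("gene_body", 0)):
            self.plant_gene_body()
        for _ in range(cfg.decoys.get("antisense", 0)):
            self.plant_antisense()
        for _ in range(cfg.decoys.get("intergenic", 0) + cfg.intergenic_mirnas):
            self.plant_intergenic()
        for _ in range(cfg.decoys.get("partial_overlap", 0)):
            self.plant_partial_overlap()
        for _ in range(cfg.background_genes):
            self.plant_background_gene()
        if cfg.seed_variant_count:
            self.plant_seed_variants()
        self.verify()

    def verify(self) -> None:
        """Per-base self-check of every planted record before writing."""
        gene_by_id = {g.gene_id: g for g in self.genes}
        mirna_by_id = {m.precursor_id: m for m in self.mirnas}
        for rec in self.manifest.planted:
            iv = mirna_by_id[rec.precursor_id].interval
            for host in rec.hosts:
                gene = gene_by_id[host.gene_id]
                if gene.span.strand is not iv.strand or not gene.span.contains(iv):
                    raise GeneratorError(
                        f"plant {rec.precursor_id} not sense-contained in {host.gene_id}")
                label, category = _perbase_label(iv, gene)
                if (label, category) != (host.location_label, host.category):
                    raise GeneratorError(
                        f"plant {rec.precursor_id} in {host.gene_id}: intended "
                        f"{host.location_label!r}/{host.category} but per-base "
                        f"verification says {label!r}/{category}")
        spans = [g.span for g in self.genes]
        for rec in self.manifest.decoys:
            iv = mirna_by_id[rec.precursor_id].interval
            overlapping = [s for s in spans if s.overlaps(iv)]
            if rec.klass == "intergenic" and overlapping:
                raise GeneratorError(f"intergenic decoy {rec.precursor_id} overlaps a gene")
            if rec.klass == "antisense" and not any(
                    s.contains(iv) and s.strand is not iv.strand for s in overlapping):
                raise GeneratorError(f"antisense decoy {rec.precursor_id} malformed")
            if rec.klass == "partial_overlap" and not any(
                    s.overlaps(iv) and not s.contains(iv) and s.strand is iv.strand
                    for s in overlapping):
                raise GeneratorError(f"partial decoy {rec.precursor_id} malformed")
            if any(s.contains(iv) and s.strand is iv.strand for s in overlapping):
                raise GeneratorError(f"decoy {rec.precursor_id} is sense-contained")


# ---------------------------------------------------------------------------
# Public entry points
# ---------------------------------------------------------------------------

@dataclass
class SpeciesBundle:
    species: str
    mirnas: list[MiRNAGene]
    genes: list[GeneModel]
    variants: list[Variant]
    manifest: TruthManifest
    paths: dict[str, Path] = field(default_factory=dict)


def generate_species(
    config: GeneratorConfig,
    seed: int,
    outdir: str | Path | None = None,
) -> SpeciesBundle:
    """Build one synthetic species; write its GFF3/GTF/VCF/manifest when
    ``outdir`` is given.  Identical (config, seed) gives identical output."""
    builder = _SpeciesBuilder(config, random.Random(seed))
    builder.build()
    bundle = SpeciesBundle(
        species=config.species, mirnas=builder.mirnas, genes=builder.genes,
        variants=builder.variants, manifest=builder.manifest)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tag = config.species
        paths = {
            "mirna_gff3": outdir / f"{tag}.mirna.gff3",
            "genes_gtf": outdir / f"{tag}.genes.gtf",
            "vcf": outdir / f"{tag}.variants.vcf",
            "manifest": outdir / f"{tag}.manifest.tsv",
        }
        mio.write_mirna_gff3(bundle.mirnas, paths["mirna_gff3"])
        mio.write_genes_gtf(bundle.genes, paths["genes_gtf"])
        mio.write_vcf(bundle.variants, paths["vcf"],
                      contigs=[f"{i + 1}" for i in range(config.n_chromosomes)])
        write_manifest(bundle.manifest, paths["manifest"])
        bundle.paths = paths
    return bundle


@dataclass
class TrioBundle:
    bundles: list[SpeciesBundle]
    orthology: OrthologyMap
    overrides: dict[str, set[str]]
    paths: dict[str, Path] = field(default_factory=dict)

    def conserved_groups(self, with_overrides: bool = True) -> set[str]:
        """Conservation-group ids expected to be recovered as full triples."""
        out = set()
        for b in self.bundles:
            for r in b.manifest.planted:
                if r.conservation_group and (with_overrides or not r.override_required):
                    out.add(r.conservation_group)
        return out


_TRIO_SPECIES = (("human", "hsa"), ("mouse", "mmu"), ("chicken", "gga"))


def generate_trio(
    config: GeneratorConfig,
    seed: int,
    outdir: str | Path | None = None,
) -> TrioBundle:
    """Three species with planted conserved co-location groups.

    Conserved groups share a miRNA stem across all three species and sit in
    hosts linked pairwise in the emitted ortholog table; a configurable
    fraction use a tier-2 letter variant in human, and another fraction use
    a chicken name that only the emitted override table unifies.
    Distractors share stems without host orthology, or orthologous hosts
    without matching stems, and must never be recovered as conserved.
    """
    config.validate()
    rng = random.Random(seed)
    orthology = OrthologyMap()
    overrides: dict[str, set[str]] = {}
    builders = {}
    for sp, prefix in _TRIO_SPECIES:
        sub_seed = rng.randrange(2**31)
        builders[sp] = _SpeciesBuilder(
            replace(config, species=sp, name_prefix=prefix,
                    planted={}, decoys={"antisense": 2, "intergenic": 3,
                                        "partial_overlap": 2},
                    background_genes=5, seed_variant_count=0),
            random.Random(sub_seed))

    P = config.conserved_triples
    n_override = round(P * config.override_fraction)
    n_tier2 = round(P * config.tier2_fraction)
    for i in range(P):
        n = 100 + i
        group = f"cg-mir-{n}"
        needs_override = i < n_override
        is_tier2 = n_override <= i < n_override + n_tier2
        if needs_override:
            names = {"human": f"hsa-mir-{n}", "mouse": f"mmu-mir-{n}",
                     "chicken": f"gga-mir-{n + 4000}"}
            overrides.setdefault(f"mir-{n}", set()).add(f"gga-mir-{n + 4000}")
        elif is_tier2:
            names = {"human": f"hsa-mir-{n}a-1", "mouse": f"mmu-mir-{n}-1",
                     "chicken": f"gga-mir-{n}"}
        else:
            names = {"human": f"hsa-mir-{n}", "mouse": f"mmu-mir-{n}",
                     "chicken": f"gga-mir-{n}"}
        gene_ids = {}
        for sp, _ in _TRIO_SPECIES:
            rec = builders[sp].plant_intron(
                name=names[sp], biotype=Biotype.PROTEIN_CODING,
                conservation_group=group, override_required=needs_override)
            gene_ids[sp] = rec.hosts[0].gene_id
        species_names = [sp for sp, _ in _TRIO_SPECIES]
        for a in range(len(species_names)):
            for b in range(a + 1, len(species_names)):
                orthology.add_link(species_names[a], gene_ids[species_names[a]],
                                   species_names[b], gene_ids[species_names[b]])

    Q = config.conserved_distractors
    for j in range(Q):
        n = 500 + j
        if j % 2 == 0:
            # shared stem, hosts NOT orthologous
            builders["human"].plant_intron(name=f"hsa-mir-{n}")
            builders["mouse"].plant_intron(name=f"mmu-mir-{n}")
        else:
            # orthologous hosts, stems that never match
            rec_h = builders["human"].plant_intron(name=f"hsa-mir-{n}")
            rec_m = builders["mouse"].plant_intron(name=f"mmu-mir-{n + 2000}")
            orthology.add_link("human", rec_h.hosts[0].gene_id,
                               "mouse", rec_m.hosts[0].gene_id)

    bundles = []
    for sp, _ in _TRIO_SPECIES:
        b = builders[sp]
        b.verify()
        bundles.append(SpeciesBundle(
            species=sp, mirnas=b.mirnas, genes=b.genes,
            variants=b.variants, manifest=b.manifest))
    trio = TrioBundle(bundles=bundles, orthology=orthology, overrides=overrides)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for b in bundles:
            paths = {
                f"{b.species}_mirna_gff3": outdir / f"{b.species}.mirna.gff3",
                f"{b.species}_genes_gtf": outdir / f"{b.species}.genes.gtf",
                f"{b.species}_manifest": outdir / f"{b.species}.manifest.tsv",
            }
            mio.write_mirna_gff3(b.mirnas, paths[f"{b.species}_mirna_gff3"])
            mio.write_genes_gtf(b.genes, paths[f"{b.species}_genes_gtf"])
            write_manifest(b.manifest, paths[f"{b.species}_manifest"])
            trio.paths.update(paths)
        trio.paths["orthologs"] = outdir / "orthologs.tsv"
        trio.paths["overrides"] = outdir / "overrides.tsv"
        mio.write_ortholog_table(orthology, trio.paths["orthologs"])
        mio.write_override_table(overrides, trio.paths["overrides"])
    return trio
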