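"""Readers and writers for the standard formats the screen touches.

Supported formats: miRNA gene annotation in miRBase-dialect GFF3
(``miRNA_primary_transcript`` records plus mature ``miRNA`` records linked
by ``Derives_from``), gene models in Ensembl-dialect GTF or GFF3, sites-only
VCF, tab-separated ortholog and override tables, and the tab-separated
catalog produced by the screen.

All coordinates are converted to the internal 0-based half-open convention
here and back to 1-based inclusive on write; nothing downstream touches
file coordinates directly.
"""

from __future__ import annotations

import logging
import os
import tempfile
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pysam
from gffutils.feature import feature_from_line

from .model import (
    Biotype,
    Catalog,
    CatalogEntry,
    GeneModel,
    GenomicInterval,
    MatureMiRNA,
    MiRNAGene,
    ModelError,
    OrthologyMap,
    TranscriptModel,
    Variant,
    harmonize_chrom,
)

logger = logging.getLogger(__name__)

CATALOG_COLUMNS = [
    "species", "precursor_id", "mirna_name", "chrom", "start", "end", "strand",
    "gene_id", "gene_symbol", "gene_biotype", "containment", "location_label",
    "category", "cluster_id",
]

ORTHOLOG_COLUMNS = ["species_a", "gene_id_a", "species_b", "gene_id_b", "link_type"]


class ParseError(ValueError):
    """A structural problem in an input file; message names file and line."""


def atomic_write(path: str | os.PathLike, text: str) -> None:
    """Write ``text`` to ``path`` via a temp file + rename (no partial files)."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# miRBase-dialect GFF3
# ---------------------------------------------------------------------------

def read_mirna_annotation(
    path: str | os.PathLike,
    dialect: str = "gff3",
    aliases: dict[str, str] | None = None,
    warnings: list[str] | None = None,
) -> list[MiRNAGene]:
    """Parse miRNA precursors and their mature products from a GFF3 file.

    Matures are attached to precursors via the ``Derives_from`` attribute.
    Precursors with no matures are retained.  A mature whose ``Derives_from``
    names no precursor is collected into ``warnings`` (if given) and logged,
    never silently dropped.  Output is sorted by (chrom, start, name).
    """
    if dialect != "gff3":
        raise ValueError(f"unsupported miRNA annotation dialect: {dialect}")
    precursors: dict[str, MiRNAGene] = {}
    pending_matures: list[tuple[int, MatureMiRNA]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
                attrs = feat.attributes
            except Exception as exc:
                raise ParseError(f"{path}: line {lineno}: malformed GFF3 record ({exc})") from exc
            if len(line.split("\t")) != 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 tab-separated columns")
            if feat.featuretype not in ("miRNA_primary_transcript", "miRNA"):
                continue
            try:
                chrom = harmonize_chrom(feat.seqid, aliases)
                iv = GenomicInterval.from_gff(chrom, feat.start, feat.end, feat.strand)
            except (ModelError, ValueError) as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            ident = (attrs.get("ID") or [""])[0]
            name = (attrs.get("Name") or [ident])[0]
            if not ident:
                raise ParseError(f"{path}: line {lineno}: record lacks an ID attribute")
            if feat.featuretype == "miRNA_primary_transcript":
                precursors[ident] = MiRNAGene(precursor_id=ident, name=name, interval=iv)
            else:
                derives = (attrs.get("Derives_from") or [""])[0]
                if not derives:
                    raise ParseError(
                        f"{path}: line {lineno}: mature {ident} lacks Derives_from"
                    )
                pending_matures.append(
                    (lineno, MatureMiRNA(mature_id=ident, name=name, interval=iv,
                                         derives_from=derives))
                )
    for lineno, mature in pending_matures:
        parent = precursors.get(mature.derives_from)
        if parent is None:
            msg = (f"mature {mature.mature_id} (line {lineno}) derives from unknown "
                   f"precursor {mature.derives_from}")
            logger.warning(msg)
            if warnings is not None:
                warnings.append(msg)
            continue
        try:
            parent.matures.append(mature)
            MiRNAGene(parent.precursor_id, parent.name, parent.interval, parent.matures)
        except ModelError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return sorted(precursors.values(), key=lambda m: (m.interval.chrom, m.interval.start, m.name))


def write_mirna_gff3(mirnas: Sequence[MiRNAGene], path: str | os.PathLike) -> None:
    lines = ["##gff-version 3"]
    for m in mirnas:
        iv = m.interval
        lines.append(
            f"{iv.chrom}\t.\tmiRNA_primary_transcript\t{iv.start1}\t{iv.end1}\t."
            f"\t{iv.strand.value}\t.\tID={m.precursor_id};Name={m.name}"
        )
        for mat in m.matures:
            mi = mat.interval
            lines.append(
                f"{mi.chrom}\t.\tmiRNA\t{mi.start1}\t{mi.end1}\t.\t{mi.strand.value}\t."
                f"\tID={mat.mature_id};Name={mat.name};Derives_from={mat.derives_from}"
            )
    atomic_write(path, "\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Ensembl-dialect gene models (GTF / GFF3)
# ---------------------------------------------------------------------------

_UTR5_TYPES = {"five_prime_utr", "five_prime_UTR"}
_UTR3_TYPES = {"three_prime_utr", "three_prime_UTR"}


def _attr1(feat, *names: str) -> str | None:
    for n in names:
        vals = feat.attributes.get(n)
        if vals:
            return vals[0]
    return None


def read_gene_annotation(
    path: str | os.PathLike,
    dialect: str = "gtf",
    aliases: dict[str, str] | None = None,
) -> list[GeneModel]:
    """Parse gene models (gene/transcript/exon/UTR records) via gffutils.

    Unknown biotypes collapse to ``other_ncRNA`` with a logged note.  A
    transcript with zero exons, or with overlapping exons, is an error
    naming the transcript.
    """
    if dialect not in ("gtf", "gff3"):
        raise ValueError(f"unsupported gene annotation dialect: {dialect}")
    # quick emptiness check: gffutils rejects files with no parseable records
    with open(path, encoding="utf-8") as fh:
        if not any(line.strip() and not line.startswith("#") for line in fh):
            return []
    db = gffutils.create_db(
        str(path), ":memory:",
        force=True, keep_order=True, merge_strategy="error",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        gene_id = _attr1(g, "gene_id", "ID") or g.id
        if gene_id.startswith("gene:"):
            gene_id = gene_id.split(":", 1)[1]
        symbol = _attr1(g, "gene_name", "Name") or gene_id
        raw_biotype = _attr1(g, "gene_biotype", "biotype") or "protein_coding"
        biotype = Biotype.from_source(raw_biotype)
        if raw_biotype.lower() not in (
            "protein_coding", "lincrna", "snorna", "mirna", "other_ncrna"
        ):
            logger.info("gene %s: biotype %r mapped to other_ncRNA", gene_id, raw_biotype)
        transcripts = []
        for t in db.children(g, level=1):
            if t.featuretype == "gene" or t.featuretype in _UTR5_TYPES | _UTR3_TYPES \
                    or t.featuretype == "exon":
                continue
            tid = _attr1(t, "transcript_id", "ID") or t.id
            if tid.startswith("transcript:"):
                tid = tid.split(":", 1)[1]
            exons, utr5, utr3 = [], [], []
            for c in db.children(t, level=1):
                try:
                    chrom = harmonize_chrom(c.seqid, aliases)
                    iv = GenomicInterval.from_gff(chrom, c.start, c.end, c.strand)
                except (ModelError, ValueError) as exc:
                    raise ParseError(f"{path}: transcript {tid}: {exc}") from exc
                if c.featuretype == "exon":
                    exons.append(iv)
                elif c.featuretype in _UTR5_TYPES:
                    utr5.append(iv)
                elif c.featuretype in _UTR3_TYPES:
                    utr3.append(iv)
            if not exons:
                raise ParseError(f"{path}: transcript {tid} has zero exons")
            try:
                transcripts.append(
                    TranscriptModel(transcript_id=tid, parent_gene_id=gene_id,
                                    exons=exons, five_utr=utr5, three_utr=utr3)
                )
            except ModelError as exc:
                raise ParseError(f"{path}: {exc}") from exc
        if not transcripts:
            raise ParseError(f"{path}: gene {gene_id} has no transcripts")
        try:
            genes.append(GeneModel(gene_id=gene_id, symbol=symbol,
                                   biotype=biotype, transcripts=transcripts))
        except ModelError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    genes.sort(key=lambda g: (g.span.chrom, g.span.start, g.gene_id))
    return genes


def _gtf_attrs(**kv: str) -> str:
    return " ".join(f'{k} "{v}";' for k, v in kv.items())


def write_genes_gtf(genes: Sequence[GeneModel], path: str | os.PathLike) -> None:
    lines = ["#!genome-version synthetic"]
    for g in genes:
        s = g.span
        lines.append(
            f"{s.chrom}\tmirhost\tgene\t{s.start1}\t{s.end1}\t.\t{s.strand.value}\t.\t"
            + _gtf_attrs(gene_id=g.gene_id, gene_name=g.symbol, gene_biotype=g.biotype.value)
        )
        for t in g.transcripts:
            ts = t.span
            common = dict(gene_id=g.gene_id, transcript_id=t.transcript_id)
            lines.append(
                f"{ts.chrom}\tmirhost\ttranscript\t{ts.start1}\t{ts.end1}\t.\t"
                f"{ts.strand.value}\t.\t" + _gtf_attrs(**common)
            )
            for kind, ivs in (("exon", t.exons), ("five_prime_utr", t.five_utr),
                              ("three_prime_utr", t.three_utr)):
                for iv in ivs:
                    lines.append(
                        f"{iv.chrom}\tmirhost\t{kind}\t{iv.start1}\t{iv.end1}\t.\t"
                        f"{iv.strand.value}\t.\t" + _gtf_attrs(**common)
                    )
    atomic_write(path, "\n".join(lines) + "\n")


def write_genes_gff3(genes: Sequence[GeneModel], path: str | os.PathLike) -> None:
    lines = ["##gff-version 3"]
    for g in genes:
        s = g.span
        lines.append(
            f"{s.chrom}\tmirhost\tgene\t{s.start1}\t{s.end1}\t.\t{s.strand.value}\t.\t"
            f"ID=gene:{g.gene_id};Name={g.symbol};biotype={g.biotype.value}"
        )
        for t in g.transcripts:
            ts = t.span
            lines.append(
                f"{ts.chrom}\tmirhost\ttranscript\t{ts.start1}\t{ts.end1}\t.\t"
                f"{ts.strand.value}\t.\tID=transcript:{t.transcript_id};Parent=gene:{g.gene_id}"
            )
            for kind, ivs in (("exon", t.exons), ("five_prime_UTR", t.five_utr),
                              ("three_prime_UTR", t.three_utr)):
                for iv in ivs:
                    lines.append(
                        f"{iv.chrom}\tmirhost\t{kind}\t{iv.start1}\t{iv.end1}\t.\t"
                        f"{iv.strand.value}\t.\tParent=transcript:{t.transcript_id}"
                    )
    atomic_write(path, "\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Variants (VCF)
# ---------------------------------------------------------------------------

def read_variant_table(
    path: str | os.PathLike, aliases: dict[str, str] | None = None
) -> list[Variant]:
    """Read a (sites-only sufficient) VCF into Variant records, 1-based."""
    variants: list[Variant] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            vid = rec.id or f"{rec.chrom}:{rec.pos}:{rec.ref}"
            variants.append(
                Variant(
                    variant_id=vid,
                    chrom=harmonize_chrom(rec.chrom, aliases),
                    pos=rec.pos,
                    ref_allele=rec.ref,
                    alt_alleles=tuple(rec.alts or ()),
                )
            )
    return variants


def write_vcf(variants: Sequence[Variant], path: str | os.PathLike,
              contigs: Iterable[str] | None = None) -> None:
    lines = ["##fileformat=VCFv4.2"]
    if contigs is None:
        contigs = sorted({v.chrom for v in variants})
    for c in contigs:
        lines.append(f"##contig=<ID={c}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.variant_id)):
        alt = ",".join(v.alt_alleles) if v.alt_alleles else "."
        lines.append(f"{v.chrom}\t{v.pos}\t{v.variant_id}\t{v.ref_allele}\t{alt}\t.\t.\t.")
    atomic_write(path, "\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Ortholog / override tables
# ---------------------------------------------------------------------------

def read_ortholog_table(path: str | os.PathLike) -> OrthologyMap:
    omap = OrthologyMap()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ORTHOLOG_COLUMNS:
            raise ParseError(
                f"{path}: expected header {ORTHOLOG_COLUMNS}, found {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 5:
                raise ParseError(f"{path}: line {lineno}: expected 5 columns")
            sa, ga, sb, gb, lt = fields
            if lt not in ("one2one", "one2many", "many2many"):
                raise ParseError(f"{path}: line {lineno}: unknown link type {lt!r}")
            try:
                omap.add_link(sa, ga, sb, gb, lt)
            except ModelError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return omap


def write_ortholog_table(omap: OrthologyMap, path: str | os.PathLike) -> None:
    lines = ["\t".join(ORTHOLOG_COLUMNS)]
    rows = []
    for key, lt in omap.gene_links.items():
        (sa, ga), (sb, gb) = sorted(key)
        rows.append((sa, ga, sb, gb, lt))
    for row in sorted(rows):
        lines.append("\t".join(row))
    atomic_write(path, "\n".join(lines) + "\n")


def read_override_table(path: str | os.PathLike) -> dict[str, set[str]]:
    """Read ``canonical_stem<TAB>member_name`` rows into an override map."""
    overrides: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 columns")
            canonical, member = fields
            overrides.setdefault(canonical.lower(), set()).add(member.lower())
    return overrides


def write_override_table(overrides: dict[str, set[str]], path: str | os.PathLike) -> None:
    lines = []
    for canonical in sorted(overrides):
        for member in sorted(overrides[canonical]):
            lines.append(f"{canonical}\t{member}")
    atomic_write(path, "\n".join(lines) + "\n" if lines else "")


# ---------------------------------------------------------------------------
# Catalog TSV
# ---------------------------------------------------------------------------

def write_catalog(catalog: Catalog, path: str | os.PathLike) -> None:
    lines = [
        f"# species={catalog.species}",
        f"# source={catalog.source}",
        f"# total_mirnas={catalog.total_mirnas}",
        "\t".join(CATALOG_COLUMNS),
    ]
    for e in catalog.entries:
        lines.append("\t".join([
            e.species, e.precursor_id, e.mirna_name, e.chrom, str(e.start), str(e.end),
            e.strand, e.gene_id, e.gene_symbol, e.gene_biotype, e.containment,
            e.location_label, e.category, e.cluster_id,
        ]))
    atomic_write(path, "\n".join(lines) + "\n")


def read_catalog(path: str | os.PathLike) -> Catalog:
    meta: dict[str, str] = {}
    entries: list[CatalogEntry] = []
    with open(path, encoding="utf-8") as fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ")
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
                continue
            fields = line.split("\t")
            if not header_seen:
                if fields != CATALOG_COLUMNS:
                    raise ParseError(f"{path}: line {lineno}: unexpected catalog header")
                header_seen = True
                continue
            if len(fields) != len(CATALOG_COLUMNS):
                raise ParseError(f"{path}: line {lineno}: wrong column count")
            (species, pid, name, chrom, start, end, strand, gid, symbol, biotype,
             containment, label, category, cluster_id) = fields
            entries.append(CatalogEntry(
                species=species, precursor_id=pid, mirna_name=name, chrom=chrom,
                start=int(start), end=int(end), strand=strand, gene_id=gid,
                gene_symbol=symbol, gene_biotype=biotype, containment=containment,
                location_label=label, category=category, cluster_id=cluster_id,
            ))
    return Catalog(
        species=meta.get("species", ""),
        source=meta.get("source", ""),
        total_mirnas=int(meta.get("total_mirnas", len({e.precursor_id for e in entries}))),
        entries=entries,
    )
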