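"""Cross-reference externally supplied miRNA or host-gene lists against a
catalog, and tally positional predicates over location labels.

Ships two transcribed reference tables as tab-separated fixtures: the
cross-species conserved co-location table (27 miRNA/host pairs in human,
mouse, and chicken) and the epigenetically-silenced-miRNA host table
(43 distinct miRNA genes; ordinal ranges expanded to explicit lists).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

from .gwiss import merge_labels, parse_location_label
from .model import Catalog, CatalogEntry, CrossRefRow, PlacementKind
from .swiss import normalize_mirna_name

__all__ = [
    "cross_reference",
    "tally_positions",
    "parse_predicate",
    "PredicateTerm",
    "load_table1",
    "load_table2",
    "table2_mirna_records",
    "strip_annotation",
]

_ANNOTATION_RE = re.compile(r"\s*\(.*\)\s*$")


def strip_annotation(name: str) -> str:
    """Drop a trailing parenthetical (synonym / orthologue marker)."""
    return _ANNOTATION_RE.sub("", name).strip()


# ---------------------------------------------------------------------------
# Catalog lookup
# ---------------------------------------------------------------------------

def cross_reference(
    names: Sequence[str], catalog: Catalog, mode: str = "mirna"
) -> list[CrossRefRow]:
    """Resolve each query name against the catalog; one row per query.

    ``mirna`` mode matches the exact name first (case-insensitive), falling
    back to the tier-1 stem so species prefixes and paralog counters do not
    block a lookup; ``host_gene`` mode matches gene symbol or id
    case-insensitively.  Unmatched queries are flagged, never dropped.
    """
    if mode not in ("mirna", "host_gene"):
        raise ValueError(f"unknown cross-reference mode: {mode}")
    if not names:
        raise ValueError("query name list must be non-empty")
    rows = []
    for query in names:
        q = query.strip().lower()
        matched: list[CatalogEntry] = []
        if mode == "mirna":
            matched = [e for e in catalog.entries if e.mirna_name.lower() == q]
            if not matched:
                stem = normalize_mirna_name(query).tier1_stem
                matched = [
                    e for e in catalog.entries
                    if normalize_mirna_name(e.mirna_name).tier1_stem == stem
                ]
        else:
            matched = [
                e for e in catalog.entries
                if e.gene_symbol.lower() == q or e.gene_id.lower() == q
            ]
        rows.append(CrossRefRow(
            query=query,
            matched_precursors=sorted({e.precursor_id for e in matched}),
            matched_genes=sorted({e.gene_id for e in matched}),
            location_labels=[e.location_label for e in matched],
            categories=sorted({e.category for e in matched}),
            host_biotypes=sorted({e.gene_biotype for e in matched}),
        ))
    return rows


# ---------------------------------------------------------------------------
# Positional predicates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PredicateTerm:
    kind: PlacementKind
    ordinal: int | None = None  # None = any ordinal / ordinal-free kind


_TERM_ALIASES = {
    "5utr": PlacementKind.FIVE_UTR,
    "5'-utr": PlacementKind.FIVE_UTR,
    "5′-utr": PlacementKind.FIVE_UTR,
    "3utr": PlacementKind.THREE_UTR,
    "3'-utr": PlacementKind.THREE_UTR,
    "3′-utr": PlacementKind.THREE_UTR,
    "intron": PlacementKind.INTRON,
    "exon": PlacementKind.EXON,
    "junction": PlacementKind.JUNCTION,
}


def parse_predicate(spec: str) -> list[PredicateTerm]:
    """Parse ``"5utr|intron:1|exon:1"`` into a disjunction of terms."""
    terms = []
    for tok in spec.split("|"):
        tok = tok.strip().lower()
        if not tok:
            continue
        name, _, ordinal = tok.partition(":")
        if name not in _TERM_ALIASES:
            raise ValueError(f"unknown predicate term: {tok!r}")
        terms.append(PredicateTerm(
            _TERM_ALIASES[name], int(ordinal) if ordinal else None))
    if not terms:
        raise ValueError(f"empty predicate: {spec!r}")
    return terms


def _label_satisfies(label: str, terms: Sequence[PredicateTerm]) -> bool:
    parsed = parse_location_label(label)
    for term in terms:
        if term.kind not in parsed:
            continue
        if term.ordinal is None or term.ordinal in parsed[term.kind]:
            return True
    return False


def tally_positions(rows: Sequence[CrossRefRow], terms: Sequence[PredicateTerm]) -> int:
    """Count rows whose merged location label satisfies any predicate term.

    A row with several matched hosts satisfies the predicate if the union of
    its labels does.  Monotone in the predicate: adding a disjunct never
    decreases the count.  Unparseable labels raise, naming the row.
    """
    count = 0
    for row in rows:
        if not row.location_labels:
            continue
        try:
            merged = merge_labels(row.location_labels)
            if merged != "gene-body" and _label_satisfies(merged, terms):
                count += 1
        except ValueError as exc:
            raise ValueError(f"row {row.query!r}: {exc}") from exc
    return count


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Table1Row:
    """One conserved miRNA/host co-location, as printed, per species."""

    human_mirna: str
    human_location: str
    human_host: str
    mouse_mirna: str
    mouse_location: str
    mouse_host: str
    chicken_mirna: str
    chicken_location: str
    chicken_host: str


@dataclass(frozen=True)
class Table2Row:
    """One epigenetically-silenced miRNA / host line, as printed."""

    mirna: str
    location: str
    host: str
    host_class: str  # protein_coding | ncRNA


def _read_fixture(name: str) -> list[list[str]]:
    text = (resources.files("mirhost") / "fixtures" / name).read_text("utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    return [ln.split("\t") for ln in lines[1:]]


def load_table1() -> list[Table1Row]:
    return [Table1Row(*fields) for fields in _read_fixture("table1_conserved_pairs.tsv")]


def load_table2() -> list[Table2Row]:
    return [Table2Row(*fields) for fields in _read_fixture("table2_epigenetic.tsv")]


def table2_mirna_records(rows: Iterable[Table2Row] | None = None) -> list[CrossRefRow]:
    """Collapse the epigenetic table to one record per distinct miRNA gene
    (secondary-host lines merge into the same record), ready for tallying."""
    rows = list(rows) if rows is not None else load_table2()
    order: list[str] = []
    grouped: dict[str, list[Table2Row]] = {}
    for r in rows:
        if r.mirna not in grouped:
            order.append(r.mirna)
            grouped[r.mirna] = []
        grouped[r.mirna].append(r)
    out = []
    for name in order:
        members = grouped[name]
        out.append(CrossRefRow(
            query=name,
            matched_precursors=[name],
            matched_genes=[strip_annotation(m.host) for m in members],
            location_labels=[m.location for m in members],
            categories=[],
            host_biotypes=sorted({m.host_class for m in members}),
        ))
    return out
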