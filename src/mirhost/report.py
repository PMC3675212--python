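"""Human- and machine-readable rendering of screen results."""

from __future__ import annotations

import json
from typing import Mapping, Sequence

from .model import SummaryStats

__all__ = ["render_summary", "render_venn", "summary_to_dict"]


def summary_to_dict(summary: SummaryStats) -> dict:
    return {
        "total_mirnas": summary.total_mirnas,
        "intragenic_count": summary.intragenic_count,
        "intragenic_fraction": summary.intragenic_fraction,
        "category_counts": dict(sorted(summary.category_counts.items())),
        "biotype_class_counts": dict(sorted(summary.biotype_class_counts.items())),
        "ncrna_host_subclass_counts": dict(sorted(summary.ncrna_host_subclass_counts.items())),
        "host_gene_count": summary.host_gene_count,
        "cluster_count": summary.cluster_count,
        "cluster_size_histogram": {str(k): v for k, v in
                                   sorted(summary.cluster_size_histogram.items())},
        "multi_host_mirna_count": summary.multi_host_mirna_count,
        "per_chromosome_counts": dict(sorted(summary.per_chromosome_counts.items())),
        "antisense_count": summary.antisense_count,
        "partial_sense_count": summary.partial_sense_count,
    }


def _flatten(d: Mapping, prefix: str = "") -> list[tuple[str, object]]:
    items: list[tuple[str, object]] = []
    for k, v in d.items():
        key = f"{prefix}.{k}" if prefix else str(k)
        if isinstance(v, Mapping):
            items.extend(_flatten(v, key))
        else:
            items.append((key, v))
    return items


def render_summary(summary: SummaryStats, format: str = "text") -> str:
    """Serialize a catalog summary as ``tsv``, ``json`` or ``text``.

    Deterministic; the text mode prints the category/biotype breakdown and
    the intragenic fraction to one decimal.
    """
    data = summary_to_dict(summary)
    if format == "json":
        return json.dumps(data, indent=2, sort_keys=False) + "\n"
    if format == "tsv":
        return "".join(f"{k}\t{v}\n" for k, v in _flatten(data))
    if format == "text":
        lines = [
            f"miRNA genes screened:      {summary.total_mirnas}",
            f"intragenic miRNA genes:    {summary.intragenic_count}"
            + (f" ({summary.intragenic_fraction}%)"
               if summary.intragenic_fraction is not None else ""),
            f"host genes:                {summary.host_gene_count}",
            f"clusters (>=2 per host):   {summary.cluster_count}",
            f"multi-host miRNA genes:    {summary.multi_host_mirna_count}",
            f"antisense overlaps (excl): {summary.antisense_count}",
            f"partial overlaps (excl):   {summary.partial_sense_count}",
            "location categories:",
        ]
        for k, v in sorted(summary.category_counts.items()):
            lines.append(f"  {k:<12} {v}")
        lines.append("host biotype classes:")
        for k, v in sorted(summary.biotype_class_counts.items()):
            lines.append(f"  {k:<20} {v}")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown summary format: {format!r}")


def render_venn(cells: Mapping[frozenset, int],
                species: Sequence[str] | None = None) -> str:
    """One row per species subset in fixed order (singletons, pairs, triple).

    Subsets absent from ``cells`` print 0, so the row set depends only on
    the species list.
    """
    if species is None:
        seen: set[str] = set()
        for subset in cells:
            seen.update(subset)
        species = sorted(seen)
    subsets: list[frozenset] = []
    n = len(species)
    for size in range(1, n + 1):
        from itertools import combinations
        for combo in combinations(species, size):
            subsets.append(frozenset(combo))
    lines = []
    for subset in subsets:
        label = "∩".join(sorted(subset))
        lines.append(f"{label}\t{cells.get(subset, 0)}")
    return "\n".join(lines) + "\n"
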