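"""Species-wide screen for conserved miRNA / host gene co-location.

miRNA gene names differ across species in their species prefix, paralog
counters, and letter variants (human ``mir-103a-1`` vs mouse ``mir-103-1``),
so matching is tiered: exact stem (tier 1), letter-stripped stem (tier 2,
with the let-7 family exempted because its letters distinguish genuine
family members), and explicit user overrides for cases name normalization
cannot infer (e.g. chicken ``mir-204-2`` as the orthologue of mammalian
``mir-211``).  A conserved pair additionally requires all host genes to be
pairwise linked in the orthology map.
"""

from __future__ import annotations

import re
from collections import Counter
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .model import (
    Catalog,
    ConservedEntry,
    ConservedPair,
    MiRNAStem,
    ModelError,
    OrthologyMap,
)

__all__ = [
    "normalize_mirna_name",
    "find_conserved_pairs",
    "subset_counts",
]

_PREFIX_RE = re.compile(r"^[a-z0-9]{2,4}-(?=(?:mir|let)-)")
_COUNTER_RE = re.compile(r"-(\d+)$")
_STEM_RE = re.compile(r"^(?:mir|let)-\d+[a-z]?$")
_LETTER_VARIANT_RE = re.compile(r"\d[a-z]$")


def normalize_mirna_name(name: str) -> MiRNAStem:
    """Tiered normalization of a miRNA gene name.

    Deterministic and idempotent: normalizing a tier-1 stem returns it
    unchanged.  The trailing ``-<int>`` is treated as a paralog counter only
    when the remainder still looks like a stem (so ``mir-21`` keeps its 21).
    """
    if not name:
        raise ValueError("miRNA name must be non-empty")
    s = name.strip().lower()
    s = _PREFIX_RE.sub("", s)
    m = _COUNTER_RE.search(s)
    if m and _STEM_RE.match(s[: m.start()]):
        s = s[: m.start()]
    tier1 = s
    if tier1.startswith("let-7"):
        tier2 = tier1
    elif _LETTER_VARIANT_RE.search(tier1):
        tier2 = tier1[:-1]
    else:
        tier2 = None
    return MiRNAStem(raw_name=name, tier1_stem=tier1, tier2_stem=tier2)


def _override_keys(
    name: str, stem: MiRNAStem, overrides: Mapping[str, set[str]]
) -> frozenset[str]:
    """Canonical override stems this name belongs to."""
    candidates = {name.strip().lower(), stem.tier1_stem, stem.tier2_key}
    keys = set()
    for canonical, members in overrides.items():
        if canonical in candidates or candidates & members:
            keys.add(canonical)
    return frozenset(keys)


class _Node:
    __slots__ = ("species", "name", "gene_id", "gene_symbol", "location_label",
                 "stem", "ovr")

    def __init__(self, species, name, gene_id, gene_symbol, location_label, overrides):
        self.species = species
        self.name = name
        self.gene_id = gene_id
        self.gene_symbol = gene_symbol
        self.location_label = location_label
        self.stem = normalize_mirna_name(name)
        self.ovr = _override_keys(name, self.stem, overrides)


def _match_tier(a: _Node, b: _Node) -> str | None:
    """Lowest sufficient tier at which two names match, or None."""
    if a.stem.tier1_stem == b.stem.tier1_stem:
        return "1"
    if a.stem.tier2_key == b.stem.tier2_key:
        return "2"
    if a.ovr & b.ovr:
        return "override"
    return None


def find_conserved_pairs(
    catalogs: Sequence[Catalog],
    orthology: OrthologyMap,
    overrides: Mapping[str, set[str]] | None = None,
) -> list[ConservedPair]:
    """Report every maximal species set with a co-located conserved miRNA.

    Two catalog entries from different species are compatible when their
    miRNA names match at some tier (overrides included) and their host genes
    are linked in the orthology map; a conserved pair is a maximal clique of
    pairwise-compatible entries.  The recorded ``match_tier`` is the lowest
    tier sufficient for every pair of members ("1" < "2" < "override").
    Output is sorted by stem; input catalog order does not matter.
    """
    overrides = dict(overrides or {})
    species_seen = [c.species for c in catalogs]
    if len(set(species_seen)) != len(species_seen):
        raise ModelError(f"duplicate species tags among catalogs: {species_seen}")
    if len(catalogs) < 2:
        raise ModelError("conservation screening needs >= 2 catalogs")
    nodes: list[_Node] = []
    for cat in catalogs:
        for e in cat.entries:
            nodes.append(_Node(cat.species, e.mirna_name, e.gene_id,
                               e.gene_symbol, e.location_label, overrides))
    graph = nx.Graph()
    graph.add_nodes_from(range(len(nodes)))
    # candidate pairs share a coarse key (tier-2 stem or an override group),
    # which every matching tier implies; avoids the all-pairs scan
    buckets: dict[str, list[int]] = {}
    for idx, n in enumerate(nodes):
        for key in {n.stem.tier2_key, *n.ovr}:
            buckets.setdefault(key, []).append(idx)
    seen: set[tuple[int, int]] = set()
    for bucket in buckets.values():
        for i, j in combinations(bucket, 2):
            if (i, j) in seen:
                continue
            seen.add((i, j))
            a, b = nodes[i], nodes[j]
            if a.species == b.species:
                continue
            if _match_tier(a, b) is None:
                continue
            if not orthology.linked(a.species, a.gene_id, b.species, b.gene_id):
                continue
            graph.add_edge(i, j)
    pairs: list[ConservedPair] = []
    for clique in nx.find_cliques(graph):
        if len(clique) < 2:
            continue
        members = [nodes[i] for i in clique]
        tiers = {_match_tier(a, b) for a, b in combinations(members, 2)}
        if "override" in tiers:
            tier = "override"
            shared = frozenset.intersection(*(m.ovr for m in members)) \
                if all(m.ovr for m in members) else frozenset()
            stem = min(shared) if shared else min(m.stem.tier2_key for m in members)
        elif "2" in tiers:
            tier = "2"
            stem = members[0].stem.tier2_key
        else:
            tier = "1"
            stem = members[0].stem.tier1_stem
        entries = sorted(
            (ConservedEntry(m.species, m.name, m.gene_id, m.gene_symbol,
                            m.location_label) for m in members),
            key=lambda e: e.species,
        )
        pairs.append(ConservedPair(stem=stem, match_tier=tier, entries=entries))
    pairs.sort(key=lambda p: (p.stem, sorted(p.species_set),
                              [e.precursor_name for e in p.entries]))
    return pairs


def subset_counts(pairs: Iterable[ConservedPair]) -> dict[frozenset, int]:
    """Venn-cell counts: pairs whose species set is exactly each subset."""
    return dict(Counter(p.species_set for p in pairs))
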