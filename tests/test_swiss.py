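"""Species-wide conservation screen: name normalization, conserved-pair
detection, overrides, and species-subset counts."""

import itertools

import pytest

from mirhost.model import Catalog, CatalogEntry, ModelError, OrthologyMap
from mirhost.swiss import find_conserved_pairs, normalize_mirna_name, subset_counts


def entry(species, name, gene, label="intron 2", symbol=None):
    return CatalogEntry(
        species=species, precursor_id=f"{species}:{name}", mirna_name=name,
        chrom="1", start=1000, end=1100, strand="+", gene_id=gene,
        gene_symbol=symbol or gene, gene_biotype="protein_coding",
        containment="full", location_label=label, category="intron",
        cluster_id="")


def catalog(species, *entries):
    return Catalog(species=species, source="test",
                   total_mirnas=len(entries), entries=list(entries))


class TestNormalizeMirnaName:
    def test_letter_variant_only_matches_at_tier_two(self):
        """hsa-mir-103a-1 vs mmu-mir-103-1: tier-1 stems differ, tier-2 agree."""
        h = normalize_mirna_name("hsa-mir-103a-1")
        m = normalize_mirna_name("mmu-mir-103-1")
        assert (h.tier1_stem, m.tier1_stem) == ("mir-103a", "mir-103")
        assert h.tier2_stem == "mir-103"
        assert h.tier2_key == m.tier2_key == "mir-103"

    def test_let7_family_letters_are_never_stripped(self):
        stems = [normalize_mirna_name(n).tier1_stem
                 for n in ("hsa-let-7g", "mmu-let-7g", "gga-let-7g")]
        assert stems == ["let-7g"] * 3
        assert normalize_mirna_name("hsa-let-7g").tier2_stem == "let-7g"

    def test_plain_number_keeps_its_number(self):
        s = normalize_mirna_name("mir-21")
        assert s.tier1_stem == "mir-21" and s.tier2_stem is None

    @pytest.mark.parametrize("name,tier1", [
        ("hsa-mir-101-2", "mir-101"),
        ("mmu-mir-101b", "mir-101b"),
        ("gga-mir-204-2", "mir-204"),
        ("hsa-mir-30c-1", "mir-30c"),
        ("MIR-128-1", "mir-128"),
    ])
    def test_prefix_and_paralog_counter_stripping(self, name, tier1):
        assert normalize_mirna_name(name).tier1_stem == tier1

    def test_idempotent_on_normalized_stems(self):
        for name in ("hsa-mir-103a-1", "let-7g", "mir-21", "mmu-mir-499"):
            once = normalize_mirna_name(name).tier1_stem
            assert normalize_mirna_name(once).tier1_stem == once


def _trio_fixture():
    """let-7g inside WDR82 orthologues in all three species (tier-1 case)."""
    cats = [
        catalog("human", entry("human", "hsa-let-7g", "ENSG_WDR82", symbol="WDR82")),
        catalog("mouse", entry("mouse", "mmu-let-7g", "ENSMUSG_Wdr82", symbol="Wdr82")),
        catalog("chicken", entry("chicken", "gga-let-7g", "ENSGALG_WDR82",
                                 symbol="WDR82_CHICK")),
    ]
    omap = OrthologyMap()
    omap.add_link("human", "ENSG_WDR82", "mouse", "ENSMUSG_Wdr82")
    omap.add_link("human", "ENSG_WDR82", "chicken", "ENSGALG_WDR82")
    omap.add_link("mouse", "ENSMUSG_Wdr82", "chicken", "ENSGALG_WDR82")
    return cats, omap


class TestFindConservedPairs:
    def test_tier1_triple_recovered_across_three_species(self):
        cats, omap = _trio_fixture()
        (pair,) = find_conserved_pairs(cats, omap)
        assert pair.stem == "let-7g"
        assert pair.match_tier == "1"
        assert pair.species_set == frozenset({"human", "mouse", "chicken"})

    def test_missing_orthology_link_breaks_the_triple(self):
        cats, omap = _trio_fixture()
        del omap.gene_links[frozenset({("mouse", "ENSMUSG_Wdr82"),
                                       ("chicken", "ENSGALG_WDR82")})]
        pairs = find_conserved_pairs(cats, omap)
        # no 3-clique anymore; two 2-species pairs remain maximal
        assert all(len(p.species_set) == 2 for p in pairs)
        assert {frozenset(p.species_set) for p in pairs} == {
            frozenset({"human", "mouse"}), frozenset({"human", "chicken"})}

    def test_override_required_for_renamed_chicken_orthologue(self):
        """mir-204-2 in chicken matches mammalian mir-211 only through the
        override map."""
        cats = [
            catalog("human", entry("human", "hsa-mir-211", "ENSG_TRPM1")),
            catalog("mouse", entry("mouse", "mmu-mir-211", "ENSMUSG_Trpm1")),
            catalog("chicken", entry("chicken", "gga-mir-204-2", "ENSGALG_TRPM1")),
        ]
        omap = OrthologyMap()
        for (sa, ga), (sb, gb) in itertools.combinations(
                [("human", "ENSG_TRPM1"), ("mouse", "ENSMUSG_Trpm1"),
                 ("chicken", "ENSGALG_TRPM1")], 2):
            omap.add_link(sa, ga, sb, gb)
        without = find_conserved_pairs(cats, omap)
        assert all(p.species_set != frozenset({"human", "mouse", "chicken"})
                   for p in without)
        with_ovr = find_conserved_pairs(
            cats, omap, overrides={"mir-211": {"gga-mir-204-2"}})
        (triple,) = [p for p in with_ovr if len(p.species_set) == 3]
        assert triple.match_tier == "override"
        assert triple.stem == "mir-211"

    def test_catalog_order_does_not_change_the_pair_set(self):
        cats, omap = _trio_fixture()
        reference = None
        for perm in itertools.permutations(cats):
            pairs = find_conserved_pairs(list(perm), omap)
            key = {(p.stem, p.match_tier,
                    tuple((e.species, e.precursor_name, e.gene_id)
                          for e in p.entries)) for p in pairs}
            if reference is None:
                reference = key
            assert key == reference

    def test_two_cluster_members_in_one_host_are_two_pairs(self):
        """mir-15b and mir-16-2 both inside SMC4 orthologues stay separate."""
        cats = [
            catalog("human",
                    entry("human", "hsa-mir-15b", "ENSG_SMC4"),
                    entry("human", "hsa-mir-16-2", "ENSG_SMC4")),
            catalog("mouse",
                    entry("mouse", "mmu-mir-15b", "ENSMUSG_Smc4"),
                    entry("mouse", "mmu-mir-16-2", "ENSMUSG_Smc4")),
        ]
        omap = OrthologyMap()
        omap.add_link("human", "ENSG_SMC4", "mouse", "ENSMUSG_Smc4")
        pairs = find_conserved_pairs(cats, omap)
        assert sorted(p.stem for p in pairs) == ["mir-15b", "mir-16"]

    def test_duplicate_species_tags_rejected(self):
        cats, omap = _trio_fixture()
        with pytest.raises(ModelError):
            find_conserved_pairs([cats[0], cats[0]], omap)

    def test_every_pair_component_exists_in_its_source_catalog(self, small_config):
        from mirhost.gwiss import assign_hosts, build_catalog
        from mirhost.simulate import generate_trio
        trio = generate_trio(small_config, seed=19)
        cats = []
        for b in trio.bundles:
            a, _ = assign_hosts(b.mirnas, b.genes)
            cats.append(build_catalog(b.species, b.mirnas, b.genes, a))
        by_species = {c.species: {(e.mirna_name, e.gene_id) for e in c.entries}
                      for c in cats}
        pairs = find_conserved_pairs(cats, trio.orthology, trio.overrides)
        assert pairs
        for p in pairs:
            for e in p.entries:
                assert (e.precursor_name, e.gene_id) in by_species[e.species]

    def test_planted_trio_recovery_and_override_ablation(self, small_config):
        from mirhost.gwiss import assign_hosts, build_catalog
        from mirhost.simulate import generate_trio
        trio = generate_trio(small_config, seed=23)
        cats = []
        for b in trio.bundles:
            a, _ = assign_hosts(b.mirnas, b.genes)
            cats.append(build_catalog(b.species, b.mirnas, b.genes, a))
        triple = frozenset({"human", "mouse", "chicken"})

        pairs = find_conserved_pairs(cats, trio.orthology, trio.overrides)
        triples = [p for p in pairs if p.species_set == triple]
        assert len(triples) == len(trio.conserved_groups(with_overrides=True))
        assert len(triples) == small_config.conserved_triples

        ablated = find_conserved_pairs(cats, trio.orthology, {})
        ablated_triples = [p for p in ablated if p.species_set == triple]
        assert len(ablated_triples) == len(trio.conserved_groups(with_overrides=False))


class TestSubsetCounts:
    def test_explicit_cells(self):
        cats, omap = _trio_fixture()
        (triple,) = find_conserved_pairs(cats, omap)
        doubles_cat = [
            catalog("human", entry("human", "hsa-mir-9000", "ENSG_A"),
                    entry("human", "hsa-mir-9001", "ENSG_B")),
            catalog("mouse", entry("mouse", "mmu-mir-9000", "ENSMUSG_A"),
                    entry("mouse", "mmu-mir-9001", "ENSMUSG_B")),
        ]
        omap2 = OrthologyMap()
        omap2.add_link("human", "ENSG_A", "mouse", "ENSMUSG_A")
        omap2.add_link("human", "ENSG_B", "mouse", "ENSMUSG_B")
        doubles = find_conserved_pairs(doubles_cat, omap2)
        cells = subset_counts([triple, *doubles])
        assert cells == {frozenset({"human", "mouse", "chicken"}): 1,
                         frozenset({"human", "mouse"}): 2}

    def test_empty_pairs_empty_cells(self):
        assert subset_counts([]) == {}

    def test_cell_sum_equals_total_pairs(self, small_config):
        from mirhost.gwiss import assign_hosts, build_catalog
        from mirhost.simulate import generate_trio
        trio = generate_trio(small_config, seed=29)
        cats = []
        for b in trio.bundles:
            a, _ = assign_hosts(b.mirnas, b.genes)
            cats.append(build_catalog(b.species, b.mirnas, b.genes, a))
        pairs = find_conserved_pairs(cats, trio.orthology, trio.overrides)
        assert sum(subset_counts(pairs).values()) == len(pairs)
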