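"""Genome-wide screen: host assignment, placement classification,
aggregation, clusters, biotype partition and summaries."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirhost.gwiss import (
    aggregate_assignment,
    assign_hosts,
    build_catalog,
    classify_in_transcript,
    detect_clusters,
    parse_location_label,
    partition_biotypes,
    printed_percentage,
    round_half_up,
    summarize_catalog,
)
from mirhost.model import (
    Biotype,
    Catalog,
    Category,
    GenomicInterval,
    Placement,
    PlacementKind,
    Strand,
)

from conftest import (
    brute_force_pairs,
    make_gene,
    make_mirna,
    make_transcript,
    perbase_placement,
    random_instance,
    reflect_gene,
    reflect_mirna,
)


def iv(start, end, strand="+", chrom="1"):
    return GenomicInterval(chrom, start, end, Strand(strand))


class TestAssignHosts:
    def test_mirna_in_two_overlapping_genes_gets_two_assignments(self):
        """Mirrors the hsa-mir-10a case: one precursor inside both HOXB3
        and HOXB4, which overlap on the same strand."""
        hoxb3 = make_gene("HOXB3", transcripts=[make_transcript(
            exons=((1000, 1400), (5000, 5400), (9000, 9400)),
            tid="HOXB3.t1", gene_id="HOXB3")])
        hoxb4 = make_gene("HOXB4", transcripts=[make_transcript(
            exons=((5600, 5900), (8000, 8300), (12000, 12400)),
            tid="HOXB4.t1", gene_id="HOXB4")])
        mir10a = make_mirna("MI10A", "hsa-mir-10a", start=6200, end=6310)
        assignments, tallies = assign_hosts([mir10a], [hoxb3, hoxb4])
        assert sorted(a.gene_id for a in assignments) == ["HOXB3", "HOXB4"]
        assert all(a.orientation == "sense" and a.containment == "full"
                   for a in assignments)
        assert tallies.antisense == 0 and tallies.partial_sense == 0

    def test_antisense_containment_is_tallied_not_assigned(self):
        gene = make_gene()
        mirna = make_mirna(start=310, end=390, strand="-")
        assignments, tallies = assign_hosts([mirna], [gene])
        assert assignments == []
        assert tallies.antisense == 1

    def test_partial_sense_overlap_is_tallied_not_assigned(self):
        gene = make_gene()  # span [100, 600)
        mirna = make_mirna(start=550, end=700)
        assignments, tallies = assign_hosts([mirna], [gene])
        assert assignments == []
        assert tallies.partial_sense == 1

    def test_coterminous_precursor_counts_as_contained(self):
        gene = make_gene()  # span [100, 600)
        mirna = make_mirna(start=100, end=180)
        assignments, _ = assign_hosts([mirna], [gene])
        assert len(assignments) == 1

    def test_zero_genes_zero_assignments(self):
        assignments, _ = assign_hosts([make_mirna()], [])
        assert assignments == []

    def test_indexed_assignment_equals_brute_force_scan(self):
        rng = random.Random(2024)
        for _ in range(60):
            mirnas, genes = random_instance(rng, n_mirnas=25, n_genes=12)
            assignments, tallies = assign_hosts(mirnas, genes)
            pairs = {(a.precursor_id, a.gene_id) for a in assignments}
            exp_pairs, exp_anti, exp_partial = brute_force_pairs(mirnas, genes)
            assert pairs == exp_pairs
            assert (tallies.antisense, tallies.partial_sense) == (exp_anti, exp_partial)


class TestClassifyInTranscript:
    def test_five_utr_takes_precedence_over_exon(self):
        """Mirrors mir-1306 inside the 5'-UTR of DGCR8: the UTR label wins
        over 'exon 1'."""
        t = make_transcript(exons=((1000, 1500), (2000, 2400), (3000, 3400)),
                            utr5=((1000, 1300),), gene_id="DGCR8")
        p = classify_in_transcript(iv(1050, 1160), t)
        assert p.kind is PlacementKind.FIVE_UTR and p.ordinal is None

    def test_gap_between_first_exons_is_intron_1_on_plus(self):
        t = make_transcript()
        p = classify_in_transcript(iv(210, 290), t)
        assert (p.kind, p.ordinal) == (PlacementKind.INTRON, 1)

    @pytest.mark.parametrize("gap", [1, 2, 3, 4])
    def test_minus_strand_intron_ordinals_count_from_the_right(self, gap):
        exons = tuple((1000 * k, 1000 * k + 300) for k in range(1, 6))  # E = 5
        t = make_transcript(strand="-", exons=exons)
        gap_start = exons[gap - 1][1]
        p = classify_in_transcript(iv(gap_start + 100, gap_start + 180, "-"), t)
        assert (p.kind, p.ordinal) == (PlacementKind.INTRON, 5 - gap)
        # the per-base labelling oracle agrees
        assert perbase_placement(iv(gap_start + 100, gap_start + 180, "-"), t) == \
            ("intron", 5 - gap)

    def test_outside_span_is_none(self):
        t = make_transcript()
        assert classify_in_transcript(iv(700, 780), t) is None

    def test_straddling_boundary_is_junction(self):
        t = make_transcript()
        p = classify_in_transcript(iv(180, 260), t)
        assert p.kind is PlacementKind.JUNCTION

    def test_random_intervals_agree_with_perbase_oracle(self):
        rng = random.Random(7)
        for _ in range(300):
            n_exons = rng.randint(2, 6)
            exons = []
            pos = rng.randrange(1000)
            for _ in range(n_exons):
                length = rng.randint(50, 400)
                exons.append((pos, pos + length))
                pos += length + rng.randint(50, 800)
            strand = rng.choice("+-")
            utr_len = rng.randint(20, 40)
            first = exons[0] if strand == "+" else exons[-1]
            t = make_transcript(strand=strand, exons=tuple(exons),
                                utr5=((first[0], first[0] + utr_len),)
                                if strand == "+" else
                                ((first[1] - utr_len, first[1]),))
            start = rng.randrange(exons[0][0] - 50, exons[-1][1] + 50)
            probe = iv(start, start + rng.randint(10, 120), strand)
            got = classify_in_transcript(probe, t)
            expected = perbase_placement(probe, t)
            if expected is None:
                assert got is None
            else:
                assert (got.kind.value, got.ordinal) == expected


class TestAggregateAssignment:
    def test_multi_transcript_intron_exon_mix_matches_printed_style(self):
        """The mir-24-1 pattern: introns 4-6 and 14-15 plus exon 7 across
        transcripts aggregates to a mixed-category label."""
        placements = [Placement(f"t{i}", PlacementKind.INTRON, o)
                      for i, o in enumerate([4, 5, 6, 14, 15])]
        placements.append(Placement("t9", PlacementKind.EXON, 7))
        label, category = aggregate_assignment(placements)
        assert label == "exon 7; intron 4, 5, 6, 14, 15"
        assert category is Category.MIXED

    def test_single_intron(self):
        label, category = aggregate_assignment([Placement("t1", PlacementKind.INTRON, 2)])
        assert (label, category) == ("intron 2", Category.INTRON)

    def test_utr_plus_intron_is_mixed(self):
        label, category = aggregate_assignment([
            Placement("t1", PlacementKind.FIVE_UTR),
            Placement("t2", PlacementKind.INTRON, 1)])
        assert (label, category) == ("5′-UTR; intron 1", Category.MIXED)

    def test_empty_placements_is_gene_body(self):
        assert aggregate_assignment([]) == ("gene-body", Category.GENE_BODY)

    def test_junction_forces_mixed(self):
        label, category = aggregate_assignment([Placement("t1", PlacementKind.JUNCTION)])
        assert (label, category) == ("junction", Category.MIXED)

    def test_duplicate_ordinals_across_transcripts_deduplicate(self):
        label, _ = aggregate_assignment([
            Placement("t1", PlacementKind.INTRON, 3),
            Placement("t2", PlacementKind.INTRON, 3)])
        assert label == "intron 3"

    @given(st.lists(
        st.tuples(st.sampled_from(list(PlacementKind)), st.integers(1, 30)),
        min_size=1, max_size=8))
    @settings(max_examples=100, derandomize=True)
    def test_labels_parse_back_to_the_aggregated_kinds(self, raw):
        placements = [
            Placement(f"t{i}", kind,
                      o if kind in (PlacementKind.INTRON, PlacementKind.EXON) else None)
            for i, (kind, o) in enumerate(raw)]
        label, _ = aggregate_assignment(placements)
        parsed = parse_location_label(label)
        assert set(parsed) == {p.kind for p in placements}
        for kind in (PlacementKind.INTRON, PlacementKind.EXON):
            if kind in parsed:
                assert parsed[kind] == frozenset(
                    p.ordinal for p in placements if p.kind is kind)


class TestStrandSymmetry:
    def test_reflection_preserves_labels_and_categories(self, small_config):
        from mirhost.simulate import generate_species
        bundle = generate_species(small_config, seed=13)
        assignments, _ = assign_hosts(bundle.mirnas, bundle.genes)
        r_genes = [reflect_gene(g) for g in bundle.genes]
        r_mirnas = [reflect_mirna(m) for m in bundle.mirnas]
        r_assignments, _ = assign_hosts(r_mirnas, r_genes)
        original = {(a.precursor_id, a.gene_id): (a.location_label, a.category)
                    for a in assignments}
        reflected = {(a.precursor_id, a.gene_id): (a.location_label, a.category)
                     for a in r_assignments}
        assert original == reflected
        assert len(original) > 0


class TestClustersAndPartition:
    def _toy_catalog(self, entries):
        return Catalog("human", "test", max(len(entries), 10), entries)

    def test_two_mirnas_in_one_lincRNA_form_one_cluster(self):
        """Mirrors the FTX case: hsa-mir-374a and hsa-mir-545 in one
        lincRNA host."""
        ftx = make_gene("FTX", biotype=Biotype.LINCRNA, transcripts=[
            make_transcript(exons=((1000, 1200), (5000, 5200), (9000, 9200)),
                            tid="FTX.t1", gene_id="FTX")])
        m1 = make_mirna("MI374A", "hsa-mir-374a", start=2000, end=2090)
        m2 = make_mirna("MI545", "hsa-mir-545", start=6000, end=6090)
        assignments, _ = assign_hosts([m1, m2], [ftx])
        catalog = build_catalog("human", [m1, m2], [ftx], assignments)
        clusters, histogram = detect_clusters(catalog.entries)
        assert len(clusters) == 1
        assert clusters[0].members == ["MI374A", "MI545"]  # sorted by start
        assert histogram == {2: 1}

    def test_all_distinct_hosts_means_no_clusters(self):
        g1, g2 = make_gene("G1"), make_gene("G2", transcripts=[
            make_transcript(exons=((10100, 10200), (10300, 10400), (10500, 10600)),
                            tid="G2.t1", gene_id="G2")])
        m1 = make_mirna("M1", start=310, end=390)
        m2 = make_mirna("M2", start=10310, end=10390)
        assignments, _ = assign_hosts([m1, m2], [g1, g2])
        catalog = build_catalog("s", [m1, m2], [g1, g2], assignments)
        clusters, _ = detect_clusters(catalog.entries)
        assert clusters == []

    def test_cluster_sizes_equal_group_by_count(self, default_bundle):
        from collections import Counter
        assignments, _ = assign_hosts(default_bundle.mirnas, default_bundle.genes)
        catalog = build_catalog("s", default_bundle.mirnas, default_bundle.genes,
                                assignments)
        clusters, histogram = detect_clusters(catalog.entries)
        group_by = Counter()
        for e in catalog.entries:
            group_by[e.gene_id] = len({x.precursor_id for x in catalog.entries
                                       if x.gene_id == e.gene_id})
        expected = {g: n for g, n in group_by.items() if n >= 2}
        assert {c.gene_id: c.size for c in clusters} == expected
        assert sum(histogram.values()) == len(clusters)

    def test_mirna_in_coding_and_ncrna_hosts_counts_as_both(self):
        pc = make_gene("PC")
        linc = make_gene("LINC", biotype=Biotype.LINCRNA, transcripts=[
            make_transcript(exons=((150, 250), (300, 450), (470, 620)),
                            tid="LINC.t1", gene_id="LINC")])
        m = make_mirna(start=320, end=400)
        assignments, _ = assign_hosts([m], [pc, linc])
        catalog = build_catalog("s", [m], [pc, linc], assignments)
        assert partition_biotypes(catalog.entries) == {
            "protein_coding_only": 0, "ncRNA_only": 0, "both": 1}

    def test_empty_assignments_all_zero(self):
        assert partition_biotypes([]) == {
            "protein_coding_only": 0, "ncRNA_only": 0, "both": 0}

    def test_biotype_classes_partition_the_intragenic_set(self, default_bundle):
        assignments, _ = assign_hosts(default_bundle.mirnas, default_bundle.genes)
        catalog = build_catalog("s", default_bundle.mirnas, default_bundle.genes,
                                assignments)
        counts = partition_biotypes(catalog.entries)
        assert sum(counts.values()) == len(catalog.intragenic_precursors)


class TestSummarize:
    def test_intragenic_fraction_truncates_to_printed_precision(self):
        # 849/1600 = 53.0625% prints as 53.0, never 53.1
        assert printed_percentage(849, 1600) == 53.0
        assert printed_percentage(418, 855) == 48.8
        assert printed_percentage(210, 499) == 42.0
        assert printed_percentage(121, 849) == 14.2
        assert round_half_up(0.05, 1) == 0.1

    def test_summary_of_planted_catalog_matches_manifest(self, default_bundle):
        assignments, tallies = assign_hosts(default_bundle.mirnas, default_bundle.genes)
        catalog = build_catalog(default_bundle.species, default_bundle.mirnas,
                                default_bundle.genes, assignments)
        summary = summarize_catalog(catalog, tallies)
        manifest = default_bundle.manifest
        assert summary.total_mirnas == len(default_bundle.mirnas)
        assert summary.intragenic_count == len(manifest.planted)
        assert sum(summary.category_counts.values()) == summary.intragenic_count
        assert sum(summary.biotype_class_counts.values()) == summary.intragenic_count
        assert sum(summary.per_chromosome_counts.values()) == summary.intragenic_count
        assert summary.antisense_count == len(
            [r for r in manifest.decoys if r.klass == "antisense"])
        assert summary.multi_host_mirna_count == len(
            [r for r in manifest.planted if len(r.hosts) == 2])
        expected_clusters = {r.cluster_id for r in manifest.planted if r.cluster_id}
        assert summary.cluster_count >= len(expected_clusters)

    def test_zero_total_reports_absent_fraction(self):
        summary = summarize_catalog(Catalog("s", "", 0, []))
        assert summary.intragenic_fraction is None
        assert summary.intragenic_count == 0

    def test_zero_intragenic_of_nonzero_total_is_zero_percent(self):
        summary = summarize_catalog(Catalog("s", "", 25, []))
        assert summary.intragenic_fraction == 0.0
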