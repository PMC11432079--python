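"""Splitting proxy regions into pseudo-genes and grafting terminal exons."""

import pytest

from exonproxy.annotation_editor import (
    GraftError,
    IdCollisionError,
    SplitError,
    add_gene,
    graft_terminal_exon,
    split_gene,
)
from exonproxy.genomic_model import (
    GeneModel,
    GenomicInterval,
    TranscriptModel,
    read_gtf,
    total_length,
    write_gtf,
)
from exonproxy.proxy_finder import ProxyRegion, find_proxies
from exonproxy.quantifier import count_overlaps
from exonproxy.simulator import (
    GORILLA_EXON10_DONOR,
    MixtureSpec,
    gorilla_thra1_locus,
    simulate_reads,
)


@pytest.fixture
def split_thra(thra_fixture):
    proxies, _, _ = find_proxies(thra_fixture.gene, thra_fixture.grouping)
    edited, plan = split_gene(thra_fixture.annotation, thra_fixture.gene.gene_id, proxies)
    return thra_fixture, proxies, edited, plan


class TestSplitGene:
    def test_pseudo_genes_carry_expected_names_and_coordinates(self, split_thra):
        _, _, edited, _ = split_thra
        names = {g.gene_name for g in edited.genes}
        assert names == {"THRA", "THRA1", "THRA2"}
        thra2 = edited.gene_by_name("THRA2")
        assert thra2.transcripts[0].exons == [
            GenomicInterval("chr17", 40_093_020, 40_093_867, "+")
        ]
        thra1 = edited.gene_by_name("THRA1")
        assert thra1.transcripts[0].exons == [
            GenomicInterval("chr17", 40_089_334, 40_092_627, "+")
        ]
        # required attributes for reference builders present on every record
        for rec in edited.records:
            assert "gene_id" in rec.attributes
            if rec.feature_type != "gene":
                assert "transcript_id" in rec.attributes
            assert "gene_name" in rec.attributes and "gene_biotype" in rec.attributes

    def test_base_conservation(self, split_thra):
        fixture, proxies, edited, plan = split_thra
        original = total_length(fixture.gene.exonic_union())
        retained = total_length(
            r.interval
            for r in edited.records
            if r.gene_id == fixture.gene.gene_id and r.feature_type == "exon"
        )
        pseudo = total_length(
            r.interval
            for r in edited.records
            if r.attributes.get("gene_name") in ("THRA1", "THRA2")
            and r.feature_type == "exon"
        )
        assert retained + pseudo == original
        # and they are disjoint: no pseudo exon overlaps a retained exon
        retained_ivs = [
            r.interval
            for r in edited.records
            if r.gene_id == fixture.gene.gene_id and r.feature_type == "exon"
        ]
        for rec in edited.records:
            if rec.attributes.get("gene_name") in ("THRA1", "THRA2"):
                assert not any(rec.interval.overlaps(iv) for iv in retained_ivs)

    def test_retained_gene_keeps_original_ids(self, split_thra):
        fixture, _, edited, _ = split_thra
        retained = edited.gene(fixture.gene.gene_id)
        assert retained.gene_name == "THRA"
        # exon 9a and the shared exons survive under THRA
        assert GenomicInterval("chr17", 40_088_900, 40_089_333, "+") in retained.exonic_union()

    def test_double_split_is_an_error_not_a_double_split(self, split_thra):
        fixture, proxies, edited, _ = split_thra
        with pytest.raises(IdCollisionError):
            split_gene(edited, fixture.gene.gene_id, proxies)
        same, _ = split_gene(edited, fixture.gene.gene_id, proxies, on_existing="skip")
        assert same is edited

    def test_overlapping_proxies_rejected(self, thra_fixture):
        p1 = ProxyRegion("A", (GenomicInterval("chr17", 40_093_020, 40_093_500, "+"),))
        p2 = ProxyRegion("B", (GenomicInterval("chr17", 40_093_400, 40_093_867, "+"),))
        with pytest.raises(SplitError, match="overlap"):
            split_gene(thra_fixture.annotation, thra_fixture.gene.gene_id, [p1, p2])

    def test_single_group_whole_terminal_exon(self):
        """Splitting out an entire terminal exon leaves the rest untouched."""
        tx = TranscriptModel(
            transcript_id="t1", gene_id="g1", seqname="c", strand="+",
            exons=[GenomicInterval("c", 100, 200, "+"), GenomicInterval("c", 300, 400, "+")],
        )
        other = TranscriptModel(
            transcript_id="u1", gene_id="g2", seqname="c", strand="+",
            exons=[GenomicInterval("c", 1000, 1100, "+")],
        )
        from exonproxy.simulator import _annotation_from_genes

        ann = _annotation_from_genes([
            GeneModel("g1", "G1", [tx]), GeneModel("g2", "G2", [other]),
        ])
        proxy = ProxyRegion("GRP", (GenomicInterval("c", 300, 400, "+"),))
        edited, _ = split_gene(ann, "g1", [proxy])
        assert edited.gene("g1").exonic_union() == [GenomicInterval("c", 100, 200, "+")]
        g2_before = [r for r in ann.records if r.gene_id == "g2"]
        g2_after = [r for r in edited.records if r.gene_id == "g2"]
        assert [r.to_gtf_line() for r in g2_before] == [r.to_gtf_line() for r in g2_after]

    def test_split_output_passes_gtf_validation(self, split_thra, tmp_path):
        _, _, edited, _ = split_thra
        p = tmp_path / "edited.gtf"
        write_gtf(edited, p)
        back = read_gtf(p)
        assert {g.gene_name for g in back.genes} == {"THRA", "THRA1", "THRA2"}
        assert not back.orphans

    def test_count_conservation_after_split(self, toy_fixture):
        """Reads counted over (retained gene + pseudo-genes) plus the reads
        that span a split boundary (ambiguous, hence dropped) equal the reads
        counted over the unsplit gene."""
        proxies, _, _ = find_proxies(toy_fixture.gene, toy_fixture.grouping)
        reads = simulate_reads(
            toy_fixture, MixtureSpec(fractions=(0.5, 0.5), n_reads=5_000, seed=3)
        )
        whole = ProxyRegion("GENE", tuple(toy_fixture.gene.exonic_union()))
        n_whole = count_overlaps(reads, [whole]).values.sum()

        edited, _ = split_gene(toy_fixture.annotation, toy_fixture.gene.gene_id, proxies)
        parts = []
        for g in edited.genes:
            parts.append(ProxyRegion(g.gene_name, tuple(g.exonic_union())))
        n_parts = count_overlaps(reads, parts).values.sum()

        # brute-force count of boundary-spanning placements
        n_ambiguous = 0
        for rd in reads:
            hit = {
                p.group_name
                for p in parts
                if any(b.overlap_length(iv) >= 1 for b in rd.blocks for iv in p.intervals)
            }
            if len(hit) > 1:
                n_ambiguous += 1
        assert n_parts + n_ambiguous == n_whole
        assert n_ambiguous < 0.05 * n_whole  # boundary spanners are rare

    def test_plan_sidecar_roundtrips_to_json(self, split_thra):
        import json

        _, _, _, plan = split_thra
        data = json.loads(plan.to_json())
        assert data["source_gene_id"] == "ENSG00000126351"
        groups = {g["gene_name"]: g for g in data["groups"]}
        assert groups["THRA2"]["intervals"] == [
            {"seqname": "chr17", "start": 40_093_020, "end": 40_093_867, "strand": "+"}
        ]


class TestGraft:
    def test_gorilla_locus_graft_matches_published_span(self):
        gene = gorilla_thra1_locus()
        donor = GenomicInterval("chr5", *GORILLA_EXON10_DONOR, "-")
        new = graft_terminal_exon(
            gene, donor,
            {"gene_id": "THRA2_GGO", "transcript_id": "THRA2_GGO_T1",
             "gene_name": "THRA2"},
            utr_length=487,
        )
        tx = new.transcripts[0]
        assert tx.span == GenomicInterval("chr5", 41_857_944, 41_888_473, "-")
        assert len(tx.exons) == 10  # nine recipient exons + the donor
        utr = tx.records_of_type("three_prime_utr")[0].interval
        assert utr.end == donor.start - 1  # immediately downstream on "-"
        assert utr.length == 487

    def test_plus_strand_toy_graft(self):
        gene = GeneModel("g", "G", [TranscriptModel(
            transcript_id="t", gene_id="g", seqname="c", strand="+",
            exons=[GenomicInterval("c", 100, 200, "+"), GenomicInterval("c", 300, 400, "+")],
        )])
        donor = GenomicInterval("c", 500, 600, "+")
        new = graft_terminal_exon(
            gene, donor, {"gene_id": "g2", "transcript_id": "t2", "gene_name": "G2"}
        )
        tx = new.transcripts[0]
        assert tx.span == GenomicInterval("c", 100, 600, "+")
        assert len(tx.exons) == 3

    def test_overlapping_donor_rejected(self):
        gene = GeneModel("g", "G", [TranscriptModel(
            transcript_id="t", gene_id="g", seqname="c", strand="+",
            exons=[GenomicInterval("c", 100, 200, "+"), GenomicInterval("c", 300, 400, "+")],
        )])
        with pytest.raises(GraftError, match="overlaps"):
            graft_terminal_exon(
                gene, GenomicInterval("c", 350, 450, "+"),
                {"gene_id": "g2", "transcript_id": "t2", "gene_name": "G2"},
            )

    def test_wrong_strand_donor_rejected(self):
        gene = gorilla_thra1_locus()
        with pytest.raises(GraftError, match="strand"):
            graft_terminal_exon(
                gene, GenomicInterval("chr5", *GORILLA_EXON10_DONOR, "+"),
                {"gene_id": "x", "transcript_id": "y", "gene_name": "Z"},
            )

    def test_grafted_gene_appends_to_annotation(self, tmp_path):
        gene = gorilla_thra1_locus(seqname="chr5")
        donor = GenomicInterval("chr5", *GORILLA_EXON10_DONOR, "-")
        new = graft_terminal_exon(
            gene, donor,
            {"gene_id": "THRA2_GGO", "transcript_id": "THRA2_GGO_T1", "gene_name": "THRA2"},
        )
        from exonproxy.simulator import _annotation_from_genes

        ann = _annotation_from_genes([gene])
        merged = add_gene(ann, new)
        assert {g.gene_id for g in merged.genes} == {"THRA_GGO", "THRA2_GGO"}
        with pytest.raises(IdCollisionError):
            add_gene(merged, new)
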