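"""Discrepancy classification: category rules, precedence and strand logic."""

import pytest

from genecat.catalogue_io import GENCODE, REFSEQ, UNIPROT, Catalogue, GeneRecord
from genecat.discrepancy import build_index, classify_all, classify_gene
from genecat.merge import match_catalogues


def coding(gene_id, start, end, strand="+", source=GENCODE, symbol=None,
           exons=None, utrs=None):
    return GeneRecord(gene_id, source, symbol or gene_id, "1", start, end,
                      strand, exons=exons or [], utr_intervals=utrs or [])


def side(gene_id, status, start, end, strand="+", source=GENCODE, exons=None):
    return GeneRecord(gene_id, source, gene_id, "1", start, end, strand,
                      status=status, exons=exons or [])


def query(gene, *, coding_recs=(), side_recs=(), cfg=None):
    cat = Catalogue(GENCODE, list(coding_recs), side_records=list(side_recs))
    return classify_gene(gene, build_index(cat), cfg)


HOST = coding("HOST", 1000, 9000, "+",
              exons=[(1000, 3000), (6000, 9000)],
              utrs=[(1000, 1500, "5"), (8500, 9000, "3")])


class TestCategoryRules:
    def test_opposite_strand_gene_over_utr_is_antisense(self):
        g = coding("X", 8600, 9400, "-")
        assert query(g, coding_recs=[HOST]).value == "antisense"

    def test_opposite_strand_gene_near_utr_within_distance_is_antisense(self):
        g = coding("X", 9300, 9900, "-")  # 300 bp from the 3' UTR end
        assert query(g, coding_recs=[HOST]).value == "antisense"

    def test_opposite_strand_gene_far_from_utr_not_antisense(self):
        g = coding("X", 20000, 21000, "-")
        assert query(g, coding_recs=[HOST]).value == "intergenic"

    def test_same_strand_exon_overlap_with_lncrna(self):
        lnc = side("LNC1", "lncRNA", 5000, 7000, "+", exons=[(5000, 5600)])
        g = coding("X", 5400, 6200, "+", exons=[(5400, 5500)])
        assert query(g, side_recs=[lnc]).value == "lncRNA"

    def test_opposite_strand_lncrna_exon_overlap_not_lncrna(self):
        lnc = side("LNC1", "lncRNA", 5000, 7000, "-", exons=[(5000, 5600)])
        g = coding("X", 5400, 6200, "+", exons=[(5400, 5500)])
        assert query(g, side_recs=[lnc]).value == "intergenic"

    def test_gene_overlapping_nothing_between_genes_is_intergenic(self):
        g = coding("X", 50000, 51000, "+")
        res = query(g, coding_recs=[HOST])
        assert res.value == "intergenic"

    def test_pseudogene_span_overlap_any_strand(self):
        ps = side("PS1", "processed_pseudogene", 800, 2000, "-")
        g = coding("X", 1500, 2500, "+")
        assert query(g, side_recs=[ps]).value == "pseudogene"

    def test_same_strand_utr_overlap_is_utr_orf(self):
        g = coding("X", 1100, 1400, "+")
        assert query(g, coding_recs=[HOST]).value == "utr_orf"

    def test_gene_wholly_within_intron_is_intronic(self):
        g = coding("X", 3500, 5500, "+")
        assert query(g, coding_recs=[HOST]).value == "intronic"

    def test_gene_straddling_intron_boundary_not_intronic(self):
        g = coding("X", 2500, 5500, "+")
        assert query(g, coding_recs=[HOST]).value == "intergenic"

    def test_tec_overlap_is_artefact(self):
        tec = side("T1", "TEC", 1000, 2000)
        g = coding("X", 1500, 2500, "+")
        assert query(g, side_recs=[tec]).value == "artefact_tec"

    def test_readthrough_tag_wins(self):
        g = coding("X", 1500, 2500, "+")
        g.tags.add("readthrough")
        ps = side("PS1", "pseudogene", 800, 2000)
        assert query(g, side_recs=[ps]).value == "readthrough"

    def test_ig_symbol_wins_over_overlap(self):
        g = coding("X", 1500, 2500, "+", symbol="IGHV3-23")
        ps = side("PS1", "pseudogene", 800, 2000)
        assert query(g, side_recs=[ps]).value == "ig_tr"

    def test_retroviral_exon_overlap(self):
        erv = side("E1", "retroviral", 5000, 7000, "+", exons=[(5000, 5600)])
        g = coding("X", 5400, 6200, "+", exons=[(5400, 5500)])
        assert query(g, side_recs=[erv]).value == "retroviral"


class TestPrecedenceAndFallbacks:
    def test_pseudogene_beats_antisense_when_both_hold(self):
        """A gene satisfying both overlap conditions gets the
        higher-precedence category."""
        ps = side("PS1", "pseudogene", 8600, 9400, "+")
        g = coding("X", 8600, 9400, "-")
        assert query(g, coding_recs=[HOST], side_recs=[ps]).value == "pseudogene"

    @pytest.mark.parametrize("symbol,expected", [
        ("GENE12P1", "pseudogene"), ("FOO-AS1", "antisense"),
        ("LINC00123", "lncRNA"), ("ERVK11", "retroviral"),
    ])
    def test_name_fallback_without_coordinate_evidence(self, symbol, expected):
        g = coding("X", 50000, 51000, "+", symbol=symbol)
        assert query(g).value == expected

    def test_geometry_beats_name_fallback(self):
        ps = side("PS1", "pseudogene", 49000, 50500)
        g = coding("X", 50000, 51000, "+", symbol="FOO-AS1")
        assert query(g, side_recs=[ps]).value == "pseudogene"

    def test_gene_without_coordinates_or_name_signal(self):
        g = GeneRecord("X", UNIPROT, "PLAIN1")
        assert query(g).value == "no_coordinates"

    def test_gene_without_coordinates_but_pseudogene_name(self):
        g = GeneRecord("X", UNIPROT, "PLAIN12P1")
        assert query(g).value == "pseudogene"

    def test_strand_flip_invariance(self):
        """Flipping every strand leaves all categories unchanged."""
        def flip(s):
            return {"+": "-", "-": "+"}.get(s, s)
        cases = [
            (coding("X", 8600, 9400, "-"), [HOST], []),
            (coding("Y", 1100, 1400, "+"), [HOST], []),
            (coding("Z", 5400, 6200, "+", exons=[(5400, 5500)]), [],
             [side("LNC1", "lncRNA", 5000, 7000, "+", exons=[(5000, 5600)])]),
        ]
        for gene, cod, sid in cases:
            before = query(gene, coding_recs=cod, side_recs=sid).value
            gene_f = GeneRecord(gene.gene_id, gene.source, gene.hgnc_symbol,
                                gene.chrom, gene.start, gene.end,
                                flip(gene.strand), exons=list(gene.exons))
            cod_f = [GeneRecord(r.gene_id, r.source, r.hgnc_symbol, r.chrom,
                                r.start, r.end, flip(r.strand),
                                exons=list(r.exons),
                                utr_intervals=list(r.utr_intervals))
                     for r in cod]
            sid_f = [GeneRecord(r.gene_id, r.source, r.hgnc_symbol, r.chrom,
                                r.start, r.end, flip(r.strand), status=r.status,
                                exons=list(r.exons)) for r in sid]
            assert query(gene_f, coding_recs=cod_f, side_recs=sid_f).value == before


class TestClassifyAll:
    def test_no_non_intersection_loci_gives_empty_table(self):
        gs = [coding("ENSG1", 1000, 9000, symbol="A")]
        rs = [GeneRecord("101", REFSEQ, "A", "1", 1000, 9000, "+",
                         status="protein-coding")]
        us = [GeneRecord("P1", UNIPROT, "A", "1", 1000, 9000, "+")]
        res = match_catalogues(Catalogue(GENCODE, gs), Catalogue(REFSEQ, rs),
                               Catalogue(UNIPROT, us))
        table = classify_all(res.loci, {GENCODE: Catalogue(GENCODE, gs),
                                        REFSEQ: Catalogue(REFSEQ, rs),
                                        UNIPROT: Catalogue(UNIPROT, us)})
        assert len(table) == 0

    def test_every_non_intersection_locus_receives_one_category(self, small_bundle,
                                                                small_run):
        table = small_run.tables.categories
        outside = [l for l in small_run.loci if l.venn_cell != "GRU"]
        assert len(table) == len(outside)
        assert table["category"].isin([
            "readthrough", "pseudogene", "ig_tr", "antisense", "lncRNA",
            "intergenic", "no_coordinates", "utr_orf", "intronic",
            "artefact_tec", "retroviral"]).all()
        assert table["locus_id"].is_unique
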