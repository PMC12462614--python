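"""Three-way merge: matching cascade, dedup, exclusions and Venn accounting."""

import random

import pytest

from genecat.catalogue_io import GENCODE, REFSEQ, UNIPROT, Catalogue, GeneRecord
from genecat.merge import (
    apply_exclusions, compute_venn, dedup_uniprot, match_catalogues,
    venn_cell,
)


def g_rec(i, symbol, chrom="1", start=None, end=None, strand="+", **kw):
    start = start if start is not None else 1000 + i * 10000
    end = end if end is not None else start + 5000
    return GeneRecord(f"ENSG{i:05d}", GENCODE, symbol, chrom, start, end,
                      strand, **kw)


def r_rec(i, symbol, chrom="1", start=None, end=None, strand="+", **kw):
    start = start if start is not None else 1000 + i * 10000
    end = end if end is not None else start + 5000
    return GeneRecord(str(100 + i), REFSEQ, symbol, chrom, start, end, strand,
                      status="protein-coding", **kw)


def u_rec(i, symbols, **kw):
    syms = (symbols,) if isinstance(symbols, str) else tuple(symbols)
    return GeneRecord(f"P{i:05d}", UNIPROT, symbols=syms, **kw)


def cats(gs=(), rs=(), us=()):
    return (Catalogue(GENCODE, list(gs)), Catalogue(REFSEQ, list(rs)),
            Catalogue(UNIPROT, list(us)))


class TestSymbolMatching:
    def test_identical_symbol_in_all_three_collapses_to_triple_locus(self):
        res = match_catalogues(*cats([g_rec(1, "AAA")], [r_rec(1, "AAA")],
                                     [u_rec(1, "AAA")]))
        assert len(res.loci) == 1
        assert res.loci[0].venn_cell == "GRU"
        assert res.loci[0].members == {GENCODE: "ENSG00001", REFSEQ: "101",
                                       UNIPROT: "P00001"}

    def test_second_same_symbol_refseq_gene_left_unmatched(self):
        """One locus, two same-symbol RefSeq genes: the second stays single."""
        res = match_catalogues(*cats(
            [g_rec(1, "ERC")], [r_rec(1, "ERC"), r_rec(2, "ERC")], []))
        cells = sorted(l.venn_cell for l in res.loci)
        assert cells == ["GR", "R"]
        assert len(res.ambiguities) == 1

    def test_refseq_and_uniprot_only_locus_still_collapses(self):
        res = match_catalogues(*cats([], [r_rec(1, "BBB")], [u_rec(1, "BBB")]))
        assert [l.venn_cell for l in res.loci] == ["RU"]


class TestCrossRefAndOverlap:
    def test_symbolless_record_matched_via_cross_reference(self):
        r = r_rec(1, None, cross_refs={GENCODE: ["ENSG00001"]})
        res = match_catalogues(*cats([g_rec(1, "CCC")], [r], []))
        assert [l.venn_cell for l in res.loci] == ["GR"]

    def test_cross_reference_in_reverse_direction(self):
        g = g_rec(1, "DDD", cross_refs={REFSEQ: ["101"]})
        res = match_catalogues(*cats([g], [r_rec(1, None)], []))
        assert [l.venn_cell for l in res.loci] == ["GR"]

    def test_nameless_record_matched_by_reciprocal_overlap(self):
        res = match_catalogues(*cats([g_rec(1, "EEE")], [r_rec(1, None)], []))
        assert [l.venn_cell for l in res.loci] == ["GR"]

    def test_opposite_strand_overlap_not_matched(self):
        res = match_catalogues(*cats([g_rec(1, "FFF", strand="+")],
                                     [r_rec(1, None, strand="-")], []))
        assert sorted(l.venn_cell for l in res.loci) == ["G", "R"]

    def test_low_reciprocal_overlap_not_matched(self):
        g = g_rec(1, "GGG", start=1000, end=11000)
        r = r_rec(1, None, start=10500, end=20000)  # ~5% of the shorter span
        res = match_catalogues(*cats([g], [r], []))
        assert sorted(l.venn_cell for l in res.loci) == ["G", "R"]

    def test_symbol_bearing_record_never_merged_by_overlap(self):
        """Same span, different symbols: two distinct loci."""
        res = match_catalogues(*cats([g_rec(1, "HHH")], [r_rec(1, "III")], []))
        assert sorted(l.venn_cell for l in res.loci) == ["G", "R"]


class TestUniprotDedup:
    def test_two_entries_on_one_gene_resolve_to_canonical(self):
        """Alternatively spliced proteins with separate entries: the entry
        with more cross-references wins."""
        u1 = u_rec(1, "TMP", cross_refs={GENCODE: ["ENSG00001"],
                                         REFSEQ: ["101"]}, protein_length=300)
        u2 = u_rec(2, "TMP", protein_length=500)
        res = match_catalogues(*cats([g_rec(1, "TMP")], [r_rec(1, "TMP")],
                                     [u1, u2]))
        loci, log = dedup_uniprot(res.loci)
        assert len(loci) == 1
        assert loci[0].members[UNIPROT] == "P00001"
        assert log

    def test_protein_length_breaks_cross_reference_tie(self):
        u1 = u_rec(1, "TMQ", protein_length=200)
        u2 = u_rec(2, "TMQ", protein_length=500)
        res = match_catalogues(*cats([g_rec(1, "TMQ")], [], [u1, u2]))
        loci, _ = dedup_uniprot(res.loci)
        assert loci[0].members[UNIPROT] == "P00002"

    def test_one_entry_shared_by_gene_family_annotates_every_locus(self):
        symbols = [f"FAM{i}" for i in range(6)]
        shared = u_rec(9, symbols)
        res = match_catalogues(*cats([g_rec(i, s) for i, s in enumerate(symbols)],
                                     [r_rec(i, s) for i, s in enumerate(symbols)],
                                     [shared]))
        loci, _ = dedup_uniprot(res.loci)
        assert len(loci) == 6
        assert all(l.venn_cell == "GRU" for l in loci)
        assert all(l.members[UNIPROT] == "P00009" for l in loci)
        assert all(l.shared_uniprot for l in loci)

    def test_single_entry_locus_unchanged(self):
        res = match_catalogues(*cats([g_rec(1, "ONE")], [], [u_rec(1, "ONE")]))
        before = dict(res.loci[0].members)
        loci, log = dedup_uniprot(res.loci)
        assert loci[0].members == before and log == []


class TestExclusionsAndVenn:
    def _loci(self):
        gs, rs, us = [], [], []
        for i in range(10):
            tags = {"ig_tr_fragment"} if i < 3 else set()
            gs.append(g_rec(i, f"S{i}", tags=tags))
        res = match_catalogues(*cats(gs, rs, us))
        return res.loci

    def test_empty_drop_set_is_identity(self):
        loci = self._loci()
        kept, counts = apply_exclusions(loci, set())
        assert kept == loci and counts == {}

    def test_readthrough_locus_removed(self):
        res = match_catalogues(*cats([g_rec(1, "RT", tags={"readthrough"})],
                                     [], []))
        kept, counts = apply_exclusions(res.loci, {"readthrough"})
        assert kept == [] and counts == {"readthrough": 1}

    def test_three_of_ten_ig_tr_loci_removed(self):
        kept, counts = apply_exclusions(self._loci(), {"ig_tr_fragment"})
        assert len(kept) == 7 and counts == {"ig_tr_fragment": 3}

    def test_unknown_exclusion_tag_rejected(self):
        with pytest.raises(ValueError):
            apply_exclusions([], {"bogus"})

    def test_all_triple_loci_have_zero_outside_intersection(self):
        res = match_catalogues(*cats([g_rec(1, "A")], [r_rec(1, "A")],
                                     [u_rec(1, "A")]))
        v = compute_venn(res.loci)
        assert v.outside_intersection == 0 and v.total == 1

    def test_venn_cell_labels(self):
        assert venn_cell({GENCODE, REFSEQ, UNIPROT}) == "GRU"
        assert venn_cell({GENCODE, UNIPROT}) == "GU"
        assert venn_cell({REFSEQ}) == "R"
        with pytest.raises(ValueError):
            venn_cell(set())


class TestMergeProperties:
    def test_order_invariance(self, small_bundle):
        """Permuting input record order yields identical loci and Venn counts."""
        cats_ = small_bundle.catalogues
        res1 = match_catalogues(cats_[GENCODE], cats_[REFSEQ], cats_[UNIPROT])
        rng = random.Random(42)
        shuffled = {}
        for s, cat in cats_.items():
            records = list(cat.records)
            rng.shuffle(records)
            shuffled[s] = Catalogue(s, records, cat.release_label,
                                    list(cat.side_records))
        res2 = match_catalogues(shuffled[GENCODE], shuffled[REFSEQ],
                                shuffled[UNIPROT])
        key = lambda l: l.locus_id
        assert [(l.locus_id, l.members) for l in sorted(res1.loci, key=key)] == \
            [(l.locus_id, l.members) for l in sorted(res2.loci, key=key)]
        assert compute_venn(res1.loci).cells == compute_venn(res2.loci).cells

    def test_conservation_every_gene_id_in_exactly_one_locus(self, small_bundle):
        cats_ = small_bundle.catalogues
        res = match_catalogues(cats_[GENCODE], cats_[REFSEQ], cats_[UNIPROT])
        loci, _ = dedup_uniprot(res.loci)
        seen = {GENCODE: [], REFSEQ: [], UNIPROT: []}
        for l in loci:
            for s, gid in l.members.items():
                seen[s].append(gid)
            for extra in l.uniprot_entries[1:]:
                seen[UNIPROT].append(extra.gene_id)
        # GENCODE and RefSeq ids appear exactly once
        for s in (GENCODE, REFSEQ):
            assert len(seen[s]) == len(set(seen[s]))
            assert set(seen[s]) == {r.gene_id for r in cats_[s].records}
        # every UniProt id appears (shared entries more than once)
        assert set(seen[UNIPROT]) == {r.gene_id for r in cats_[UNIPROT].records}

    def test_idempotence_merge_of_merge_output(self):
        gs = [g_rec(i, f"Z{i}") for i in range(5)]
        rs = [r_rec(i, f"Z{i}") for i in range(3)]
        res = match_catalogues(*cats(gs, rs, []))
        # re-merging the member records reproduces the same loci
        g2 = [l.records[GENCODE] for l in res.loci if GENCODE in l.records]
        r2 = [l.records[REFSEQ] for l in res.loci if REFSEQ in l.records]
        res2 = match_catalogues(*cats(g2, r2, []))
        assert sorted(l.venn_cell for l in res.loci) == \
            sorted(l.venn_cell for l in res2.loci)
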