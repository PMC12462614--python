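"""Potential non-coding features: definitions, applicability and the
NS/Syn qualification rule."""

import pytest
from hypothesis import given, strategies as st

from genecat.catalogue_io import GENCODE, REFSEQ, UNIPROT
from genecat.noncoding_features import (
    FEATURES, FeatureCriterionConfig, FeatureEvidence, classify_symbol,
    evaluate_features, feature_applicability, phylocsf_max,
    qualify_feature_by_nssyn,
)


class TestPhyloCsfMax:
    @pytest.mark.parametrize("exons,expected", [
        ([(-20, 12), (5, 8)], -20),     # the 8-codon exon is ineligible
        ([(-14, 30)], -14),
        ([(3, 15), (7, 40)], 7),
        ([], None),
        ([(10, 9)], None),              # no exon reaches 10 codons
    ])
    def test_best_eligible_exon(self, exons, expected):
        assert phylocsf_max(exons) == expected

    def test_min_codons_configurable(self):
        assert phylocsf_max([(5, 8)], min_exon_codons=5) == 5


def evidence(**kw):
    defaults = dict(
        gene_id="g",
        phylocsf_exons=[(8.0, 40)],
        gene_age_depth="vertebrata",
        has_functional_residues=True, has_structure_homology=False,
        has_domain=True, has_conservation=True, has_tm_helix=False,
        uniprot_caution=set(), uniprot_evidence="protein_level",
        description_text="A well characterised protein",
        hgnc_name_class="coding-like", readthrough=False,
    )
    defaults.update(kw)
    return FeatureEvidence(**defaults)


class TestEvaluateFeatures:
    def test_all_benign_evidence_not_flagged(self):
        a = evaluate_features(evidence())
        assert a.features == set() and not a.flagged

    def test_readthrough_only(self):
        a = evaluate_features(evidence(readthrough=True))
        assert a.features == {"readthrough_gene"} and a.flagged

    def test_recent_gene_age_at_catarrhini_cutoff(self):
        a = evaluate_features(evidence(gene_age_depth="catarrhini"))
        assert a.features == {"recent_gene_age"}

    def test_age_beyond_catarrhini_not_recent(self):
        a = evaluate_features(evidence(gene_age_depth="mammalia"))
        assert "recent_gene_age" not in a.features

    def test_phylocsf_at_cutoff_flagged(self):
        a = evaluate_features(evidence(phylocsf_exons=[(-14.0, 30)]))
        assert "phylocsf_max" in a.features

    def test_no_protein_features_needs_negative_phylocsf(self):
        blank = dict(has_functional_residues=False, has_structure_homology=False,
                     has_domain=False, has_conservation=False, has_tm_helix=False)
        a = evaluate_features(evidence(phylocsf_exons=[(-5.0, 20)], **blank))
        assert a.features == {"no_protein_features"}
        b = evaluate_features(evidence(phylocsf_exons=[(5.0, 20)], **blank))
        assert "no_protein_features" not in b.features

    def test_no_protein_features_with_undefined_phylocsf(self):
        blank = dict(has_functional_residues=False, has_structure_homology=False,
                     has_domain=False, has_conservation=False, has_tm_helix=False)
        a = evaluate_features(evidence(phylocsf_exons=[], **blank))
        assert "no_protein_features" in a.features
        cfg = FeatureCriterionConfig(undefined_phylocsf_is_negative=False)
        b = evaluate_features(evidence(phylocsf_exons=[], **blank), cfg)
        assert "no_protein_features" not in b.features

    def test_description_with_pseudogene_word(self):
        a = evaluate_features(evidence(
            description_text="Putative uncharacterized protein, pseudogene candidate"))
        assert "described_pseudogene" in a.features

    def test_pseudogene_word_match_is_token_bounded(self):
        a = evaluate_features(evidence(description_text="pseudogenes abound"))
        assert "described_pseudogene" in a.features
        b = evaluate_features(evidence(description_text="pseudogenomic region"))
        assert "described_pseudogene" not in b.features

    def test_caution_and_uncertain(self):
        a = evaluate_features(evidence(uniprot_caution={"dubious_CDS"},
                                       uniprot_evidence="uncertain"))
        assert {"caution_note", "uncertain_evidence"} <= a.features

    def test_legacy_evidence_codes_reported_but_never_flag(self):
        a = evaluate_features(evidence(uniprot_evidence="homology"))
        assert a.features == set() and not a.flagged
        assert a.legacy_features == {"homology_evidence"}
        cfg = FeatureCriterionConfig(include_legacy_features=True)
        b = evaluate_features(evidence(uniprot_evidence="predicted"), cfg)
        assert "predicted_evidence" in b.features and b.flagged

    def test_noncoding_name_class(self):
        a = evaluate_features(evidence(hgnc_name_class="noncoding-like"))
        assert "non_coding_name" in a.features

    def test_applicability_restricts_result(self):
        ev = evidence(gene_age_depth="catarrhini", readthrough=True)
        a = evaluate_features(ev, applicable=frozenset({"readthrough_gene"}))
        assert a.features == {"readthrough_gene"}

    def test_monotonicity_adding_a_feature_never_unflags(self):
        base = evidence(readthrough=True)
        a = evaluate_features(base)
        more = evidence(readthrough=True, gene_age_depth="catarrhini",
                        uniprot_caution={"dubious_CDS"})
        b = evaluate_features(more)
        assert a.flagged and b.flagged and a.features <= b.features


class TestApplicability:
    def test_gencode_gene_can_carry_all_eight(self):
        assert feature_applicability(GENCODE) == frozenset(FEATURES)

    def test_refseq_only_gene_has_exactly_three(self):
        assert feature_applicability(REFSEQ) == frozenset(
            {"readthrough_gene", "described_pseudogene", "non_coding_name"})

    def test_uniprot_only_gene(self):
        assert feature_applicability(UNIPROT) == frozenset(
            {"caution_note", "uncertain_evidence", "described_pseudogene",
             "non_coding_name"})

    def test_multi_source_locus_unions_channels(self):
        assert feature_applicability({REFSEQ, UNIPROT}) == \
            feature_applicability(REFSEQ) | feature_applicability(UNIPROT)

    def test_empty_override_makes_nothing_flaggable(self):
        cfg = FeatureCriterionConfig(applicability={})
        assert feature_applicability(GENCODE, cfg) == frozenset()
        ev = evidence(readthrough=True, gene_age_depth="catarrhini")
        a = evaluate_features(ev, cfg, applicable=frozenset())
        assert not a.flagged


class TestQualificationRule:
    @pytest.mark.parametrize("rare,common,expected", [
        (2.31, 2.24, True),     # no purifying selection in either stratum
        (1.96, 0.9, False),     # the peptide-supported control
        (2.40, 2.05, False),    # gap 0.35 >= 0.3
        (2.0, 2.0, False),      # floor is strict
        (2.01, 2.29, True),
        (2.30, 2.00, False),    # common not > 2.0
        (2.31, 2.62, False),    # gap 0.31
    ])
    def test_rule(self, rare, common, expected):
        assert qualify_feature_by_nssyn(rare, common) is expected

    def test_undefined_ratio_is_undecidable(self):
        assert qualify_feature_by_nssyn(None, 2.2) is None
        assert qualify_feature_by_nssyn(2.2, None) is None

    @given(st.floats(0.1, 5.0), st.floats(0.1, 5.0))
    def test_rule_symmetric_under_stratum_swap(self, a, b):
        assert qualify_feature_by_nssyn(a, b) == qualify_feature_by_nssyn(b, a)


class TestSymbolClass:
    @pytest.mark.parametrize("symbol,expected", [
        ("GENE12P1", "noncoding-like"), ("WASH6P", "noncoding-like"),
        ("FOO-AS1", "noncoding-like"), ("LINC00999", "noncoding-like"),
        ("TP53", "coding-like"), ("ATP5F1A", "coding-like"),
        (None, "coding-like"),
    ])
    def test_patterns(self, symbol, expected):
        assert classify_symbol(symbol) == expected
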