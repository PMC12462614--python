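"""The eight potential non-coding features and the NS/Syn qualification rule.

A gene is flagged as potentially non-coding when it carries at least one of:

* ``recent_gene_age``       — no homologues beyond catarrhini (gene family age)
* ``no_protein_features``   — no functional residues, structure/domain
                              homology, cross-species conservation or
                              transmembrane helices, and a negative PhyloCSFMax
* ``readthrough_gene``      — all transcripts are readthrough transcripts
* ``phylocsf_max``          — PhyloCSFMax of -14 or lower
* ``caution_note``          — a curator caution (dubious CDS / possible pseudogene)
* ``uncertain_evidence``    — protein-existence evidence code 'uncertain'
* ``described_pseudogene``  — the word 'pseudogene' in the protein description
* ``non_coding_name``       — a pseudogene/antisense/lncRNA-style HGNC name

PhyloCSFMax is the best per-exon PhyloCSF score among exons of at least 10
codons.  A feature only applies to a gene when the catalogue that provides
its evidence channel annotates the gene: tool-based features need the GTF
catalogue, curator-note features need a protein entry, and so on.

Candidate features qualify through germline variation: the feature's gene
subset must have an NS/Syn ratio above 2.0 in both the rare and the common
allele stratum with the two ratios less than 0.3 apart — i.e. no visible
purifying selection.  Two legacy evidence-code features (``homology`` and
``predicted``) fail the gap test; they are still computed and reported but
never flag a gene unless explicitly re-enabled.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .catalogue_io import GENCODE, REFSEQ, UNIPROT, SOURCES

FEATURES = (
    "recent_gene_age", "no_protein_features", "readthrough_gene",
    "phylocsf_max", "caution_note", "uncertain_evidence",
    "described_pseudogene", "non_coding_name",
)

LEGACY_FEATURES = ("homology_evidence", "predicted_evidence")

#: evidence channel of each feature: which annotating sources make it
#: evaluable.  The features were designed for the GTF catalogue's genes, so
#: all eight apply there (curator-note features reach GTF-annotated genes
#: through their protein-entry cross-references and simply carry no evidence
#: when no entry exists); a gene-table-only gene can carry exactly three.
DEFAULT_APPLICABILITY: dict[str, frozenset[str]] = {
    "recent_gene_age": frozenset({GENCODE}),               # tool-based
    "no_protein_features": frozenset({GENCODE}),           # tool-based
    "phylocsf_max": frozenset({GENCODE}),                  # tool-based
    "readthrough_gene": frozenset({GENCODE, REFSEQ}),      # annotation tag
    "caution_note": frozenset({GENCODE, UNIPROT}),         # curator note
    "uncertain_evidence": frozenset({GENCODE, UNIPROT}),   # curator note
    "described_pseudogene": frozenset(SOURCES),            # description text
    "non_coding_name": frozenset(SOURCES),                 # HGNC-style name
}

#: ordinal taxonomic depths for the gene-family-age feature, youngest first
AGE_DEPTHS = ("homininae", "hominidae", "catarrhini", "mammalia",
              "amniota", "vertebrata")

PSEUDOGENE_WORD_RE = re.compile(r"\bpseudogenes?\b", re.IGNORECASE)

#: noncoding-like HGNC symbol patterns (pseudogene suffix, antisense, lncRNA).
#: The pseudogene suffix requires a parent-gene stem of >= 3 characters so
#: that symbols like TP53 (T + P + digits) are not misread as pseudogenes.
NONCODING_NAME_RES = (
    r"^[A-Z][A-Z0-9\.-]*[0-9]P[0-9]*$", r"^[A-Z][A-Z0-9\.-]{2,}P[0-9]+$",
    r"-AS[0-9]*$", r"^LINC[0-9]+",
)


@dataclass
class FeatureEvidence:
    """Per-gene inputs to the eight potential non-coding features."""

    gene_id: str
    phylocsf_exons: list[tuple[float, int]] = field(default_factory=list)  # (score, codons)
    gene_age_depth: str | None = None
    has_functional_residues: bool | None = None
    has_structure_homology: bool | None = None
    has_domain: bool | None = None
    has_conservation: bool | None = None
    has_tm_helix: bool | None = None
    uniprot_caution: set[str] = field(default_factory=set)
    uniprot_evidence: str | None = None
    description_text: str | None = None
    hgnc_name_class: str | None = None   # coding-like / noncoding-like
    readthrough: bool = False

    def __post_init__(self):
        if self.gene_age_depth is not None and self.gene_age_depth not in AGE_DEPTHS:
            raise ValueError(f"unknown gene_age_depth {self.gene_age_depth!r}")
        for s, n in self.phylocsf_exons:
            if n <= 0:
                raise ValueError("phylocsf exon length (codons) must be positive")


@dataclass
class FeatureAssignment:
    gene_id: str
    features: set[str] = field(default_factory=set)
    legacy_features: set[str] = field(default_factory=set)

    @property
    def flagged(self) -> bool:
        return bool(self.features)


@dataclass
class FeatureCriterionConfig:
    ratio_floor: float = 2.0
    max_stratum_gap: float = 0.3
    phylocsf_cutoff: float = -14.0
    min_exon_codons: int = 10
    age_cutoff: str = "catarrhini"
    #: undefined PhyloCSFMax (no scorable exon of >= 10 codons) counts as
    #: negative for no_protein_features: absence of a scorable coding exon is
    #: itself non-coding-like
    undefined_phylocsf_is_negative: bool = True
    include_legacy_features: bool = False
    applicability: dict[str, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_APPLICABILITY))
    noncoding_name_patterns: tuple[str, ...] = NONCODING_NAME_RES

    def __post_init__(self):
        if self.ratio_floor <= 0:
            raise ValueError("ratio_floor must be positive")
        if self.min_exon_codons < 1:
            raise ValueError("min_exon_codons must be >= 1")
        if self.age_cutoff not in AGE_DEPTHS:
            raise ValueError(f"unknown age_cutoff {self.age_cutoff!r}")


def phylocsf_max(
    exons: Sequence[tuple[float, int]],
    min_exon_codons: int = 10,
) -> float | None:
    """Best PhyloCSF score over exons of at least ``min_exon_codons`` codons.

    Returns None when no exon qualifies (including the empty list).
    """
    scores = [s for s, n in exons if n >= min_exon_codons]
    return max(scores) if scores else None


def classify_symbol(symbol: str | None,
                    patterns: Iterable[str] = NONCODING_NAME_RES) -> str:
    """'noncoding-like' for pseudogene/antisense/lncRNA-style symbols."""
    if symbol:
        for pat in patterns:
            if re.search(pat, symbol):
                return "noncoding-like"
    return "coding-like"


def evaluate_features(
    ev: FeatureEvidence,
    cfg: FeatureCriterionConfig | None = None,
    applicable: frozenset[str] | set[str] | None = None,
) -> FeatureAssignment:
    """Evaluate the eight features on one gene's evidence.

    ``applicable`` restricts the result to the features whose evidence
    channel exists for this gene (see :func:`feature_applicability`); missing
    evidence fields are treated as feature-not-applicable.
    """
    cfg = cfg or FeatureCriterionConfig()
    feats: set[str] = set()

    pmax = phylocsf_max(ev.phylocsf_exons, cfg.min_exon_codons)

    if ev.gene_age_depth is not None:
        if AGE_DEPTHS.index(ev.gene_age_depth) <= AGE_DEPTHS.index(cfg.age_cutoff):
            feats.add("recent_gene_age")

    if pmax is not None and pmax <= cfg.phylocsf_cutoff:
        feats.add("phylocsf_max")

    protein_evidence = (ev.has_functional_residues, ev.has_structure_homology,
                        ev.has_domain, ev.has_conservation, ev.has_tm_helix)
    if all(v is not None for v in protein_evidence):
        negative_pmax = (pmax < 0.0 if pmax is not None
                         else cfg.undefined_phylocsf_is_negative)
        if not any(protein_evidence) and negative_pmax:
            feats.add("no_protein_features")

    if ev.readthrough:
        feats.add("readthrough_gene")
    if ev.uniprot_caution:
        feats.add("caution_note")
    if ev.uniprot_evidence == "uncertain":
        feats.add("uncertain_evidence")
    if ev.description_text and PSEUDOGENE_WORD_RE.search(ev.description_text):
        feats.add("described_pseudogene")
    if ev.hgnc_name_class == "noncoding-like":
        feats.add("non_coding_name")

    legacy = set()
    if ev.uniprot_evidence in ("homology", "predicted"):
        legacy.add(ev.uniprot_evidence + "_evidence")
    if cfg.include_legacy_features:
        feats |= legacy

    if applicable is not None:
        feats &= set(applicable) | (set(LEGACY_FEATURES) if cfg.include_legacy_features else set())
    return FeatureAssignment(gene_id=ev.gene_id, features=feats,
                             legacy_features=legacy)


def feature_applicability(
    sources: str | Iterable[str],
    cfg: FeatureCriterionConfig | None = None,
) -> frozenset[str]:
    """Features whose evidence channel is available given the annotating source(s).

    A GENCODE-annotated gene can carry all eight; a RefSeq-only gene exactly
    three (readthrough, described pseudogene, non-coding name).
    """
    cfg = cfg or FeatureCriterionConfig()
    if isinstance(sources, str):
        sources = {sources}
    sources = set(sources)
    return frozenset(f for f, chan in cfg.applicability.items() if sources & chan)


def qualify_feature_by_nssyn(
    rare_ratio: float | None,
    common_ratio: float | None,
    cfg: FeatureCriterionConfig | None = None,
) -> bool | None:
    """The feature-qualification rule on a subset's NS/Syn ratios.

    True iff both stratum ratios exceed the floor (strictly > 2.0) and the
    ratios differ by less than the gap (strictly < 0.3).  Returns None when
    either ratio is undefined (qualification undecidable).
    """
    cfg = cfg or FeatureCriterionConfig()
    if rare_ratio is None or common_ratio is None:
        return None
    return (rare_ratio > cfg.ratio_floor
            and common_ratio > cfg.ratio_floor
            and abs(rare_ratio - common_ratio) < cfg.max_stratum_gap)
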