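"""Why is a locus not annotated as coding by every catalogue?

Every merged locus outside the three-way intersection is assigned exactly one
category explaining why the non-annotating source(s) do not call it coding:
``readthrough``, ``ig_tr``, ``pseudogene``, ``retroviral``, ``lncRNA``,
``antisense``, ``artefact_tec``, ``utr_orf``, ``intronic``, ``intergenic`` or
``no_coordinates``.

Tag- and identity-based evidence (readthrough tags, IG/TR fragment identity)
beats overlap geometry, and specific overlap beats positional defaults; the
full precedence order is configurable.  Name-based fallbacks (pseudogene-
suffixed, ``-AS`` and ``LINC``-style symbols) apply only when no coordinate
evidence is found.

UniProtKB records have no genome annotation of their own, so when the only
non-annotating source is UniProtKB the classifier can consult the coordinate
catalogues' coding-gene geometry (excluding the locus's own members) for the
positional rules — a UTR ORF is a UTR ORF regardless of which catalogue's
UTR it sits in.  This replaces the manual record-by-record review a curator
would perform.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .catalogue_io import (
    GENCODE, REFSEQ, UNIPROT, SOURCES,
    Catalogue, GeneRecord, TAG_IG_TR, TAG_READTHROUGH, looks_ig_tr,
)
from .merge import MergedGene

CATEGORIES = (
    "readthrough", "pseudogene", "ig_tr", "antisense", "lncRNA", "intergenic",
    "no_coordinates", "utr_orf", "intronic", "artefact_tec", "retroviral",
)

DEFAULT_PRECEDENCE = (
    "readthrough", "ig_tr", "pseudogene", "retroviral", "lncRNA", "antisense",
    "artefact_tec", "utr_orf", "intronic", "intergenic", "no_coordinates",
)


@dataclass
class DiscrepancyCategory:
    value: str
    evidence: str = ""

    def __post_init__(self):
        if self.value not in CATEGORIES:
            raise ValueError(f"unknown category {self.value!r}")


@dataclass
class ClassificationConfig:
    precedence: tuple[str, ...] = DEFAULT_PRECEDENCE
    #: "close to" a UTR, in bp, for the antisense rule
    antisense_utr_distance: int = 1000
    #: consult coordinate catalogues' coding geometry when only UniProt
    #: fails to annotate the locus
    uniprot_neighbour_geometry: bool = True
    pseudogene_name_re: str = r"^[A-Z][A-Z0-9\.-]*[0-9]P[0-9]*$|^[A-Z][A-Z0-9\.-]{2,}P[0-9]+$"
    antisense_name_re: str = r"-AS[0-9]*$"
    lncrna_name_re: str = r"^LINC[0-9]+"
    retroviral_name_re: str = r"^(H?ERV|LTR)"


def _status_kind(status: str) -> str | None:
    s = status.lower()
    if "pseudogene" in s:
        return "pseudogene"
    if "lncrna" in s or "lincrna" in s or s == "long_noncoding":
        return "lncrna"
    if "retro" in s or s.startswith("erv"):
        return "retroviral"
    if "tec" in s or "artefact" in s or "artifact" in s:
        return "tec"
    if s == "other":
        return "other_fragment"
    return None


class AnnotationIndex:
    """Strand-aware interval index over one source's annotation.

    Kinds: ``coding`` (gene spans), ``utr``, ``intron``, ``pseudogene``,
    ``lncrna``, ``retroviral``, ``tec``, ``other_fragment``.  Exon-bearing
    side features are indexed exon-wise; structure-less side records are
    treated as single-exon spans.
    """

    def __init__(self, source: str = ""):
        self.source = source
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        self.n_features = 0

    def _add(self, kind: str, chrom: str, start: int, end: int, data):
        key = (kind, chrom)
        self._trees.setdefault(key, IntervalTree()).addi(start, end + 1, data)
        self.n_features += 1

    def add_coding(self, rec: GeneRecord):
        if not rec.has_coordinates:
            return
        self._add("coding", rec.chrom, rec.start, rec.end, rec)
        for s, e, side in rec.utr_intervals:
            self._add("utr", rec.chrom, s, e, rec)
        for s, e in rec.introns():
            self._add("intron", rec.chrom, s, e, rec)

    def add_side(self, rec: GeneRecord):
        kind = _status_kind(rec.status)
        if kind is None or not rec.has_coordinates:
            return
        if kind in ("lncrna", "retroviral") and rec.exons:
            for s, e in rec.exons:
                self._add(kind, rec.chrom, s, e, rec)
        else:
            self._add(kind, rec.chrom, rec.start, rec.end, rec)

    def query(self, kind: str, chrom: str, start: int, end: int,
              strand: str | None = None, same_strand: bool | None = None,
              exclude_ids: frozenset[str] = frozenset()):
        """Overlap hits of ``kind``; ``same_strand`` filters relative to ``strand``."""
        tree = self._trees.get((kind, chrom))
        if tree is None:
            return []
        hits = []
        for iv in tree.overlap(start, end + 1):
            rec = iv.data
            if rec.gene_id in exclude_ids:
                continue
            if same_strand is not None and strand and rec.strand:
                if (rec.strand == strand) != same_strand:
                    continue
            hits.append((rec, iv.begin, iv.end - 1))
        hits.sort(key=lambda h: (h[1], h[2], h[0].gene_id))
        return hits

    def contains(self, kind: str, chrom: str, start: int, end: int,
                 exclude_ids: frozenset[str] = frozenset()):
        """Hits of ``kind`` whose interval wholly contains [start, end]."""
        return [h for h in self.query(kind, chrom, start, end, exclude_ids=exclude_ids)
                if h[1] <= start and h[2] >= end]


def build_index(catalogue: Catalogue, coding: bool = True, side: bool = True) -> AnnotationIndex:
    idx = AnnotationIndex(catalogue.source)
    if coding:
        for r in catalogue.records:
            idx.add_coding(r)
    if side:
        for r in catalogue.side_records:
            idx.add_side(r)
    return idx


def build_neighbour_index(*catalogues: Catalogue) -> AnnotationIndex:
    """Coding-gene geometry of the coordinate catalogues, for the UniProt rule."""
    idx = AnnotationIndex("NEIGHBOUR")
    for cat in catalogues:
        for r in cat.records:
            idx.add_coding(r)
    return idx


def classify_gene(
    gene: GeneRecord | MergedGene,
    indexes: list[AnnotationIndex] | AnnotationIndex,
    cfg: ClassificationConfig | None = None,
    exclude_ids: frozenset[str] = frozenset(),
) -> DiscrepancyCategory:
    """Assign one category to a gene outside the triple intersection.

    ``indexes`` are the annotation index(es) of the source(s) that do not
    annotate the gene as coding.
    """
    cfg = cfg or ClassificationConfig()
    if isinstance(indexes, AnnotationIndex):
        indexes = [indexes]

    if isinstance(gene, MergedGene):
        rec = gene.record_priority()
        tags = gene.tags
        symbol = gene.symbol
        chrom, start, end, strand = gene.chrom, gene.start, gene.end, gene.strand
        exons = rec.exons if rec is not None else []
    else:
        rec = gene
        tags, symbol = gene.tags, gene.hgnc_symbol
        chrom, start, end, strand = gene.chrom, gene.start, gene.end, gene.strand
        exons = gene.exons
    has_coords = chrom is not None and start is not None and end is not None
    exon_ivs = exons or ([(start, end)] if has_coords else [])

    def geometric(category: str):
        if not has_coords:
            return None
        for idx in indexes:
            if category == "pseudogene":
                hits = idx.query("pseudogene", chrom, start, end, exclude_ids=exclude_ids)
                if hits:
                    return f"overlaps pseudogene {hits[0][0].gene_id} in {idx.source}"
            elif category in ("retroviral", "lncRNA"):
                kind = "retroviral" if category == "retroviral" else "lncrna"
                for es, ee in exon_ivs:
                    hits = idx.query(kind, chrom, es, ee, strand=strand,
                                     same_strand=True, exclude_ids=exclude_ids)
                    if hits:
                        return f"exon overlap with {kind} {hits[0][0].gene_id} in {idx.source}"
            elif category == "antisense":
                d = cfg.antisense_utr_distance
                hits = idx.query("utr", chrom, max(1, start - d), end + d,
                                 strand=strand, same_strand=False,
                                 exclude_ids=exclude_ids)
                if hits:
                    return (f"opposite strand of {hits[0][0].gene_id} "
                            f"near/overlapping its UTR in {idx.source}")
            elif category == "artefact_tec":
                hits = idx.query("tec", chrom, start, end, exclude_ids=exclude_ids)
                if hits:
                    return f"TEC/artefact {hits[0][0].gene_id} in {idx.source}"
            elif category == "utr_orf":
                hits = idx.query("utr", chrom, start, end, strand=strand,
                                 same_strand=True, exclude_ids=exclude_ids)
                if hits:
                    return f"within/overlapping UTR of {hits[0][0].gene_id} in {idx.source}"
            elif category == "intronic":
                hits = idx.contains("intron", chrom, start, end, exclude_ids=exclude_ids)
                if hits:
                    return f"wholly within intron of {hits[0][0].gene_id} in {idx.source}"
        return None

    for category in cfg.precedence:
        if category == "readthrough":
            if TAG_READTHROUGH in tags:
                return DiscrepancyCategory("readthrough", "readthrough-tagged")
        elif category == "ig_tr":
            if TAG_IG_TR in tags or looks_ig_tr(symbol):
                return DiscrepancyCategory("ig_tr", f"IG/TR fragment symbol {symbol}")
            if has_coords:
                for idx in indexes:
                    hits = idx.query("other_fragment", chrom, start, end,
                                     exclude_ids=exclude_ids)
                    if hits:
                        return DiscrepancyCategory(
                            "ig_tr", f"overlaps '{hits[0][0].status}' fragment "
                                     f"{hits[0][0].gene_id} in {idx.source}")
        elif category in ("pseudogene", "retroviral", "lncRNA", "antisense",
                          "artefact_tec", "utr_orf", "intronic"):
            ev = geometric(category)
            if ev is not None:
                return DiscrepancyCategory(category, ev)
        elif category in ("intergenic", "no_coordinates"):
            # positional defaults handled after the loop (name fallback first)
            continue

    if symbol:
        for pat, cat in ((cfg.pseudogene_name_re, "pseudogene"),
                         (cfg.antisense_name_re, "antisense"),
                         (cfg.lncrna_name_re, "lncRNA"),
                         (cfg.retroviral_name_re, "retroviral")):
            if re.search(pat, symbol):
                return DiscrepancyCategory(cat, f"HGNC-style name {symbol}")

    if not has_coords:
        return DiscrepancyCategory("no_coordinates", "no genomic mapping")
    return DiscrepancyCategory("intergenic", "no overlapping feature; falls between genes")


def classify_all(
    loci: list[MergedGene],
    catalogues: dict[str, Catalogue],
    cfg: ClassificationConfig | None = None,
) -> pd.DataFrame:
    """One category per non-intersection locus.

    Returns a table with columns locus_id, symbol, venn_cell, category,
    evidence.  Intersection loci are not classified.
    """
    cfg = cfg or ClassificationConfig()
    indexes = {s: build_index(catalogues[s]) for s in SOURCES if s in catalogues}
    neighbour = None
    if cfg.uniprot_neighbour_geometry:
        coord_cats = [catalogues[s] for s in (GENCODE, REFSEQ) if s in catalogues]
        neighbour = build_neighbour_index(*coord_cats)

    rows = []
    for loc in loci:
        non_annot = sorted(set(SOURCES) - loc.sources)
        if not non_annot:
            continue
        idxs = [indexes[s] for s in non_annot if s in indexes]
        if neighbour is not None and UNIPROT in non_annot:
            idxs = idxs + [neighbour]
        own = frozenset(loc.members.values())
        cat = classify_gene(loc, idxs, cfg, exclude_ids=own)
        rows.append({
            "locus_id": loc.locus_id,
            "symbol": loc.symbol or "",
            "venn_cell": loc.venn_cell,
            "category": cat.value,
            "evidence": cat.evidence,
        })
    return pd.DataFrame(
        rows, columns=["locus_id", "symbol", "venn_cell", "category", "evidence"])
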