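"""Synthetic catalogue fixtures with a known ground truth.

The real inputs are public database releases that cannot be redistributed,
so this module generates complete, internally consistent stand-ins: three
catalogues with a configurable Venn structure, discrepancy categories
realised as actual coordinate geometry (an antisense case really is an
opposite-strand gene overlapping a UTR), feature-evidence tables, VEP-style
variant tables with configurable NS/Syn composition per maxAF stratum, and
peptide tables — plus a truth table recording every gene's intended Venn
cell, category, features and peptide support for oracle testing.

Layout strategy: every locus gets its own non-overlapping slot laid down
left-to-right along the chromosomes, so the intended category is the only
applicable one.  Categories that require a coding gene in another catalogue
(antisense, UTR ORF, intronic) are realised inside the slot of a designated
triple-intersection "host" locus.

Everything is deterministic under the seed: the same spec and seed produce
byte-identical files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .catalogue_io import (
    GENCODE, REFSEQ, UNIPROT,
    Catalogue, GeneRecord, TAG_READTHROUGH, TAG_NO_COORDS, TAG_SCAFFOLD,
)
from .merge import VENN_CELLS, cell_sources
from .discrepancy import CATEGORIES
from .noncoding_features import FEATURES
from .peptide_support import PeptideRecord


class FixtureError(ValueError):
    """The spec cannot be realised (counts or geometry infeasible)."""


# --------------------------------------------------------------------------
# spec dataclasses
# --------------------------------------------------------------------------

@dataclass
class FeatureBlock:
    """``count`` genes of ``cell`` that all carry ``features``.

    ``n_supported`` of them get two qualifying peptides.  ``category``
    constrains which discrepancy-category pool the genes are drawn from
    (mandatory for readthrough blocks outside the intersection);
    ``realise='name'`` forces name-based realisation of that category.
    """
    cell: str
    features: tuple[str, ...]
    count: int
    n_supported: int = 0
    category: str | None = None
    realise: str | None = None


@dataclass
class VariantSubsetModel:
    """A simulated variant subset with true per-stratum NS/Syn ratios."""
    label: str
    selector: str            # refseq_outside | peptide_supported | intersection |
                             # outside | all | flagged | unflagged | cell:<CELL>
    rare_ratio: float
    common_ratio: float
    n_variants: int
    rare_fraction: float = 0.5
    sampling: str = "exact"  # exact (largest-remainder counts) or binomial


@dataclass
class VariantDecoySpec:
    """Rows that every filter stage must remove."""
    frameshift: int = 0
    splice_region_only: int = 0
    zero_af: int = 0
    missing_af: int = 0
    bad_allele: int = 0
    non_principal: int = 0


@dataclass
class PeptideDecoySpec:
    multi_gene: int = 0
    single_observation: int = 0
    non_tryptic: int = 0
    #: emulate the one readthrough transcript with a single peptide
    readthrough_single_peptide: bool = False


@dataclass
class MergeQuirkSpec:
    """Triple-intersection loci that exercise the merge cascade's later passes."""
    xref_matched: int = 0        # RefSeq member has no symbol, only a cross-ref
    overlap_matched: int = 0     # RefSeq member has neither symbol nor cross-ref
    multi_uniprot: int = 0       # a second UniProt entry on the same gene
    shared_uniprot_span: int = 0 # k loci sharing one sequence-identical entry
    unreviewed_entries: int = 0  # TrEMBL-role rows, skipped by the reader
    scaffold_entries: int = 0    # reviewed entries placed only on scaffolds


LAYOUT_CHROMS = tuple(str(i) for i in range(1, 23)) + ("X", "Y")


@dataclass
class FixtureSpec:
    seed: int = 0
    venn_cells: dict[str, int] = field(default_factory=dict)
    #: per-cell category counts for non-intersection cells; any shortfall is
    #: filled with 'intergenic'
    category_cells: dict[str, dict[str, int]] = field(default_factory=dict)
    feature_blocks: list[FeatureBlock] = field(default_factory=list)
    #: per-cell counts of UNFLAGGED genes that get peptide support
    unflagged_supported: dict[str, int] = field(default_factory=dict)
    #: per-cell (n_homology, n_predicted) legacy evidence codes on unflagged genes
    legacy_evidence: dict[str, tuple[int, int]] = field(default_factory=dict)
    variant_models: list[VariantSubsetModel] = field(default_factory=list)
    variant_decoys: VariantDecoySpec = field(default_factory=VariantDecoySpec)
    peptide_decoys: PeptideDecoySpec = field(default_factory=PeptideDecoySpec)
    quirks: MergeQuirkSpec = field(default_factory=MergeQuirkSpec)
    chroms: tuple[str, ...] = LAYOUT_CHROMS
    chrom_size: int = 250_000_000
    slot_width: int = 10_000

    @property
    def category_mix(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for cats in self.category_cells.values():
            for c, n in cats.items():
                out[c] = out.get(c, 0) + n
        return out

    @property
    def feature_mix(self) -> dict[str, int]:
        out = {f: 0 for f in FEATURES}
        for b in self.feature_blocks:
            for f in b.features:
                out[f] += b.count
        return out


# category realisation constraints ------------------------------------------------

HOSTED_CATEGORIES = ("antisense", "utr_orf", "intronic")
SIDE_CATEGORIES = ("pseudogene", "lncRNA", "retroviral", "artefact_tec")
NAMEABLE = ("pseudogene", "lncRNA", "retroviral", "antisense")


def _non_annotators(cell: str) -> frozenset[str]:
    return frozenset({GENCODE, REFSEQ, UNIPROT}) - cell_sources(cell)


def _auto_realise(category: str, cell: str) -> str:
    """How a category is realised in a given cell: tag, symbol, geometry or name."""
    non = _non_annotators(cell)
    if category == "readthrough":
        return "tag"
    if category == "ig_tr":
        return "symbol"
    if category in ("intergenic", "no_coordinates"):
        return "plain"
    if category in HOSTED_CATEGORIES:
        # needs a UTR/intron-bearing catalogue among the non-annotators: GENCODE
        # directly, or the neighbour-geometry rule when UniProt is one of them
        if GENCODE in non or UNIPROT in non:
            return "geometry"
        if category == "antisense":
            return "name"
        raise FixtureError(f"{category} cannot be realised in cell {cell}")
    if category in SIDE_CATEGORIES:
        if non & {GENCODE, REFSEQ}:
            return "geometry"
        if category in NAMEABLE:
            return "name"
        raise FixtureError(f"{category} cannot be realised in cell {cell}")
    raise FixtureError(f"unknown category {category!r}")


# --------------------------------------------------------------------------
# truth model
# --------------------------------------------------------------------------

@dataclass
class TruthGene:
    idx: int
    cell: str
    symbol: str | None = None
    category: str | None = None
    realise: str | None = None
    features: set[str] = field(default_factory=set)
    supported: bool = False
    readthrough: bool = False
    legacy_code: str | None = None
    quirk: str | None = None
    host_idx: int | None = None
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str | None = None
    exons: list[tuple[int, int]] = field(default_factory=list)
    utrs: list[tuple[int, int, str]] = field(default_factory=list)
    ids: dict[str, str] = field(default_factory=dict)
    principal: str | None = None
    principal_gene: str | None = None   # the gene_id variants are keyed by
    description: str | None = None

    @property
    def sources(self) -> frozenset[str]:
        return cell_sources(self.cell)


@dataclass
class FixtureBundle:
    spec: FixtureSpec
    catalogues: dict[str, Catalogue]
    variants: pd.DataFrame
    evidence: pd.DataFrame
    peptides: list[PeptideRecord]
    truth_genes: list[TruthGene]
    model_truth: list[dict]

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for g in self.truth_genes:
            rows.append({
                "idx": g.idx, "cell": g.cell, "symbol": g.symbol or "",
                "gencode_id": g.ids.get(GENCODE, ""),
                "refseq_id": g.ids.get(REFSEQ, ""),
                "uniprot_id": g.ids.get(UNIPROT, ""),
                "chrom": g.chrom or "", "start": g.start or "",
                "end": g.end or "", "strand": g.strand or "",
                "category": g.category or "", "realise": g.realise or "",
                "features": ";".join(sorted(g.features)),
                "flagged": int(bool(g.features)),
                "supported": int(g.supported),
                "readthrough": int(g.readthrough),
                "legacy_code": g.legacy_code or "",
                "quirk": g.quirk or "",
                "host_idx": "" if g.host_idx is None else g.host_idx,
                "principal_transcript": g.principal or "",
                "principal_gene": g.principal_gene or "",
            })
        return pd.DataFrame(rows)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        from .variant_selection import write_variant_table
        from .peptide_support import write_peptide_table
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "gencode_gtf": out / "gencode.gtf",
            "refseq_tsv": out / "refseq.tsv",
            "uniprot_tsv": out / "uniprot.tsv",
            "variants_tsv": out / "variants.tsv",
            "evidence_tsv": out / "evidence.tsv",
            "peptides_tsv": out / "peptides.tsv",
            "truth_tsv": out / "truth_genes.tsv",
            "truth_json": out / "truth.json",
        }
        _write_gencode_gtf(self.catalogues[GENCODE], paths["gencode_gtf"])
        _write_refseq_tsv(self.catalogues[REFSEQ], paths["refseq_tsv"])
        _write_uniprot_tsv(self.catalogues[UNIPROT], paths["uniprot_tsv"])
        write_variant_table(self.variants, paths["variants_tsv"])
        with open(paths["evidence_tsv"], "w", encoding="utf-8", newline="\n") as fh:
            self.evidence.to_csv(fh, sep="\t", index=False, lineterminator="\n")
        write_peptide_table(self.peptides, paths["peptides_tsv"])
        with open(paths["truth_tsv"], "w", encoding="utf-8", newline="\n") as fh:
            self.truth_table().to_csv(fh, sep="\t", index=False, lineterminator="\n")
        truth = {
            "venn_cells": {c: sum(1 for g in self.truth_genes if g.cell == c)
                           for c in VENN_CELLS},
            "models": self.model_truth,
        }
        with open(paths["truth_json"], "w", encoding="utf-8", newline="\n") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return paths


# --------------------------------------------------------------------------
# validation
# --------------------------------------------------------------------------

def validate_spec(spec: FixtureSpec) -> None:
    for cell in spec.venn_cells:
        if cell not in VENN_CELLS:
            raise FixtureError(f"unknown Venn cell {cell!r}")
        if spec.venn_cells[cell] < 0:
            raise FixtureError("negative cell count")
    n_gru = spec.venn_cells.get("GRU", 0)

    hosted = 0
    for cell, cats in spec.category_cells.items():
        if cell == "GRU":
            raise FixtureError("intersection loci cannot carry a category")
        total = sum(cats.values())
        if total > spec.venn_cells.get(cell, 0):
            raise FixtureError(
                f"cell {cell}: {total} categories > {spec.venn_cells.get(cell, 0)} loci")
        for cat, n in cats.items():
            if cat not in CATEGORIES:
                raise FixtureError(f"unknown category {cat!r}")
            if n < 0:
                raise FixtureError("negative category count")
            if n and cat == "no_coordinates" and cell != "U":
                raise FixtureError("no_coordinates loci must be UniProt-only")
            if n:
                _auto_realise(cat, cell)  # raises if unrealisable
            if cat in HOSTED_CATEGORIES and _auto_realise(cat, cell) == "geometry":
                hosted += n
    if hosted > n_gru:
        raise FixtureError(
            f"{hosted} hosted discrepancy loci need intersection hosts, "
            f"only {n_gru} available")

    # feature blocks
    consumed: dict[tuple[str, str | None], int] = {}
    for b in spec.feature_blocks:
        if b.cell not in VENN_CELLS:
            raise FixtureError(f"feature block on unknown cell {b.cell!r}")
        for f in b.features:
            if f not in FEATURES:
                raise FixtureError(f"unknown feature {f!r}")
        srcs = cell_sources(b.cell)
        if ("caution_note" in b.features or "uncertain_evidence" in b.features) \
                and UNIPROT not in srcs:
            raise FixtureError(f"[U] feature block in cell {b.cell} without UniProt")
        if {"recent_gene_age", "no_protein_features", "phylocsf_max"} & set(b.features) \
                and GENCODE not in srcs:
            raise FixtureError(f"[T] feature block in cell {b.cell} without GENCODE")
        if "readthrough_gene" in b.features and not srcs & {GENCODE, REFSEQ}:
            raise FixtureError("readthrough feature needs a GENCODE or RefSeq member")
        if b.n_supported > b.count:
            raise FixtureError("n_supported > block count")
        key = (b.cell, b.category)
        consumed[key] = consumed.get(key, 0) + b.count

    for (cell, cat), n in consumed.items():
        if cat is not None:
            avail = spec.category_cells.get(cell, {}).get(cat, 0)
            if n > avail:
                raise FixtureError(
                    f"cell {cell}: blocks need {n} '{cat}' genes, only {avail}")
    for cell in VENN_CELLS:
        total_blocks = sum(b.count for b in spec.feature_blocks if b.cell == cell)
        extra = (spec.unflagged_supported.get(cell, 0)
                 + sum(spec.legacy_evidence.get(cell, (0, 0))))
        if total_blocks + extra > spec.venn_cells.get(cell, 0):
            raise FixtureError(f"cell {cell}: feature/support allocation exceeds size")

    # readthrough bookkeeping: every readthrough-category gene in a cell with a
    # GENCODE or RefSeq member is readthrough-tagged, hence carries the feature;
    # blocks must own them all so that flag counts stay exact
    for cell, cats in spec.category_cells.items():
        n_rt = cats.get("readthrough", 0)
        if n_rt and cell_sources(cell) & {GENCODE, REFSEQ}:
            n_block = sum(b.count for b in spec.feature_blocks
                          if b.cell == cell and b.category == "readthrough")
            if n_block != n_rt:
                raise FixtureError(
                    f"cell {cell}: {n_rt} readthrough loci but feature blocks "
                    f"cover {n_block}")

    # geometry capacity
    n_slots_needed = sum(spec.venn_cells.values()) \
        - spec.category_cells.get("U", {}).get("no_coordinates", 0)
    capacity = len(spec.chroms) * (spec.chrom_size // spec.slot_width)
    if n_slots_needed > capacity:
        raise FixtureError(f"{n_slots_needed} slots needed, capacity {capacity}")

    for m in spec.variant_models:
        if m.sampling not in ("exact", "binomial"):
            raise FixtureError("variant sampling must be exact or binomial")
        if not (0.0 <= m.rare_fraction <= 1.0):
            raise FixtureError("rare_fraction out of range")


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------

def _digit_peptide(n: int, tail: str = "R") -> str:
    """Deterministic distinct peptide sequence from an integer."""
    alphabet = "ACDEFGHILM"
    digits = f"{n:07d}"
    return "".join(alphabet[int(d)] for d in digits) + tail


def generate_fixture(spec: FixtureSpec) -> FixtureBundle:
    """Realise a spec as catalogues, tables and a truth table."""
    validate_spec(spec)
    rng = np.random.default_rng(spec.seed)

    # ---- 1. truth genes per cell, categories assigned deterministically ----
    genes: list[TruthGene] = []
    by_cell: dict[str, list[TruthGene]] = {c: [] for c in VENN_CELLS}
    idx = 0
    for cell in VENN_CELLS:
        n = spec.venn_cells.get(cell, 0)
        cats = spec.category_cells.get(cell, {})
        cat_list: list[str] = []
        for cat in sorted(cats):
            cat_list += [cat] * cats[cat]
        if cell != "GRU":
            cat_list += ["intergenic"] * (n - len(cat_list))
        for i in range(n):
            g = TruthGene(idx=idx, cell=cell)
            if cell != "GRU":
                g.category = cat_list[i]
                g.realise = _auto_realise(g.category, cell)
                if g.category == "readthrough":
                    g.readthrough = True
            genes.append(g)
            by_cell[cell].append(g)
            idx += 1

    # ---- 2. feature blocks consume genes from per-category pools ----------
    pools: dict[str, dict[str | None, list[TruthGene]]] = {}
    for cell in VENN_CELLS:
        d: dict[str | None, list[TruthGene]] = {}
        for g in by_cell[cell]:
            d.setdefault(g.category, []).append(g)
        pools[cell] = d

    def take(cell: str, category: str | None, k: int) -> list[TruthGene]:
        if category is not None:
            pool = pools[cell].get(category, [])
            if len(pool) < k:
                raise FixtureError(f"cell {cell}: pool '{category}' exhausted")
            out, pools[cell][category] = pool[:k], pool[k:]
            return out
        out = []
        for cat in [c for c in sorted(pools[cell], key=lambda x: (x is None, x))
                    if c != "readthrough"]:
            while pools[cell][cat] and len(out) < k:
                out.append(pools[cell][cat].pop(0))
            if len(out) == k:
                break
        if len(out) < k:
            raise FixtureError(f"cell {cell}: only {len(out)} of {k} genes available")
        return out

    # category-constrained blocks first, so unconstrained ones cannot
    # exhaust a pool another block needs
    for b in sorted(spec.feature_blocks, key=lambda b: b.category is None):
        chosen = take(b.cell, b.category, b.count)
        for j, g in enumerate(chosen):
            g.features |= set(b.features)
            if "readthrough_gene" in b.features:
                g.readthrough = True
            if j < b.n_supported:
                g.supported = True
            if b.realise and g.category:
                g.realise = b.realise

    for cell, n_sup in spec.unflagged_supported.items():
        for g in take(cell, None, n_sup):
            g.supported = True
    for cell, (n_hom, n_pred) in spec.legacy_evidence.items():
        for g in take(cell, None, n_hom):
            g.legacy_code = "homology"
        for g in take(cell, None, n_pred):
            g.legacy_code = "predicted"

    quirk_list = (["xref_matched"] * spec.quirks.xref_matched
                  + ["overlap_matched"] * spec.quirks.overlap_matched
                  + ["multi_uniprot"] * spec.quirks.multi_uniprot)
    for q, g in zip(quirk_list, take("GRU", None, len(quirk_list))):
        g.quirk = q
    shared = take("GRU", None, spec.quirks.shared_uniprot_span) \
        if spec.quirks.shared_uniprot_span else []
    for g in shared:
        g.quirk = "shared_uniprot"

    # ---- 3. symbols ---------------------------------------------------------
    ig_styles = ("IGHV1-{}", "IGKV2-{}", "IGLV3-{}", "TRBV{}-1", "TRAV{}-2")
    n_ig = 0
    for g in genes:
        base = f"SYN{g.idx:05d}"
        if g.category == "ig_tr":
            g.symbol = ig_styles[n_ig % len(ig_styles)].format(n_ig + 1)
            n_ig += 1
        elif g.realise == "name":
            style = {"pseudogene": base + "P1", "lncRNA": f"LINC{g.idx:05d}",
                     "retroviral": f"ERVK{g.idx}", "antisense": base + "-AS1"}
            g.symbol = style[g.category]
        elif "non_coding_name" in g.features:
            if g.category == "lncRNA":
                g.symbol = f"LINC{g.idx:05d}"
            elif g.category == "antisense":
                g.symbol = base + "-AS1"
            else:
                g.symbol = f"LINC{g.idx:05d}"
        else:
            g.symbol = base
    # name-feature truth must match what the symbol implies
    for g in genes:
        from .noncoding_features import classify_symbol
        if classify_symbol(g.symbol) == "noncoding-like":
            g.features.add("non_coding_name")

    # ---- 4. geometry --------------------------------------------------------
    slots_per_chrom = spec.chrom_size // spec.slot_width
    host_pool = [g for g in by_cell["GRU"]]
    host_cursor = len(host_pool) - 1
    slot_no = 0

    def slot_origin(s: int) -> tuple[str, int]:
        return spec.chroms[s // slots_per_chrom], (s % slots_per_chrom) * spec.slot_width

    def place_base(g: TruthGene, s: int):
        chrom, o = slot_origin(s)
        g.chrom, g.strand = chrom, ("+" if s % 2 == 0 else "-")
        g.start, g.end = o + 1001, o + 8000
        g.exons = [(o + 1001, o + 3000), (o + 6001, o + 8000)]
        g.utrs = [(o + 1001, o + 1500, "5"), (o + 7601, o + 8000, "3")]

    hosted_of: dict[int, TruthGene] = {}
    for g in genes:
        if g.category == "no_coordinates":
            g.realise = "plain"
            continue
        if g.category in HOSTED_CATEGORIES and g.realise == "geometry":
            if host_cursor < 0:
                raise FixtureError("ran out of intersection hosts")
            host = host_pool[host_cursor]
            host_cursor -= 1
            g.host_idx = host.idx
            hosted_of[host.idx] = g
            continue
        place_base(g, slot_no)
        slot_no += 1

    for g in genes:
        if g.host_idx is None:
            continue
        host = genes[g.host_idx]
        o = host.start - 1001
        if g.category == "antisense":
            g.strand = "-" if host.strand == "+" else "+"
            g.chrom, g.start, g.end = host.chrom, o + 7701, o + 8300
        elif g.category == "utr_orf":
            g.strand = host.strand
            g.chrom, g.start, g.end = host.chrom, o + 1101, o + 1450
        elif g.category == "intronic":
            g.strand = host.strand
            g.chrom, g.start, g.end = host.chrom, o + 3501, o + 5500
        g.exons = [(g.start, g.end)]

    # ---- 5. records and side features --------------------------------------
    gc_records: list[GeneRecord] = []
    gc_side: list[GeneRecord] = []
    rs_records: list[GeneRecord] = []
    rs_side: list[GeneRecord] = []
    up_records: list[GeneRecord] = []
    side_no = 0

    shared_acc = None
    if shared:
        shared_acc = f"Q{shared[0].idx % 100000:05d}"

    for g in genes:
        srcs = g.sources
        gid = f"ENSG{g.idx:011d}"
        rid = str(100000 + g.idx)
        uacc = f"P{g.idx % 100000:05d}"
        tagset = set()
        if g.readthrough:
            tagset.add(TAG_READTHROUGH)
        if GENCODE in srcs:
            g.ids[GENCODE] = gid
            g.principal = f"ENST{g.idx:011d}"
            g.principal_gene = gid
            xr = {}
            if REFSEQ in srcs and g.quirk != "overlap_matched":
                xr[REFSEQ] = [rid]
            if UNIPROT in srcs and g.quirk not in ("overlap_matched",):
                xr[UNIPROT] = [shared_acc if g.quirk == "shared_uniprot" else uacc]
            gc_records.append(GeneRecord(
                gene_id=gid, source=GENCODE, hgnc_symbol=g.symbol,
                chrom=g.chrom, start=g.start, end=g.end, strand=g.strand,
                status="protein_coding", tags=set(tagset),
                exons=list(g.exons), utr_intervals=list(g.utrs),
                cross_refs=xr, principal_transcript_id=g.principal))
        if REFSEQ in srcs:
            g.ids[REFSEQ] = rid
            pr = f"NM_{g.idx:06d}.1"
            if g.principal is None:
                g.principal, g.principal_gene = pr, rid
            symbol = g.symbol
            xr: dict[str, list[str]] = {}
            if g.quirk == "xref_matched":
                symbol = None
                xr[GENCODE] = [gid]
            elif g.quirk == "overlap_matched":
                symbol = None
            rs_records.append(GeneRecord(
                gene_id=rid, source=REFSEQ, hgnc_symbol=symbol,
                chrom=g.chrom, start=g.start, end=g.end, strand=g.strand,
                status="protein-coding", tags=set(tagset),
                cross_refs=xr, principal_transcript_id=pr,
                description=g.description))
        if UNIPROT in srcs:
            if g.quirk == "shared_uniprot":
                g.ids[UNIPROT] = shared_acc
            else:
                g.ids[UNIPROT] = uacc
                xr = {}
                if GENCODE in srcs:
                    xr[GENCODE] = [gid]
                if REFSEQ in srcs:
                    xr[REFSEQ] = [rid]
                up_records.append(GeneRecord(
                    gene_id=uacc, source=UNIPROT, symbols=(g.symbol,),
                    chrom=g.chrom, start=g.start, end=g.end, strand=g.strand,
                    tags=set(tagset) if g.category != "no_coordinates"
                         else {TAG_NO_COORDS},
                    cross_refs=xr, protein_length=200 + (g.idx % 700),
                    description=g.description,
                    evidence_code=("uncertain" if "uncertain_evidence" in g.features
                                   else g.legacy_code or "protein_level"),
                    caution_notes=({"dubious_CDS"} if "caution_note" in g.features
                                   else set())))

        # side features realising the geometric categories
        if g.realise == "geometry" and g.category in SIDE_CATEGORIES:
            non = _non_annotators(g.cell)
            target = GENCODE if GENCODE in non else REFSEQ
            status = {"pseudogene": "processed_pseudogene", "lncRNA": "lncRNA",
                      "retroviral": "retroviral", "artefact_tec": "TEC"}[g.category]
            side_id = (f"ENSG9{side_no:010d}" if target == GENCODE
                       else str(900000 + side_no))
            side_no += 1
            exon = [g.exons[0]] if g.category in ("lncRNA", "retroviral") else []
            rec = GeneRecord(
                gene_id=side_id, source=target, hgnc_symbol=f"SIDE{side_no:05d}",
                chrom=g.chrom, start=g.start, end=g.end, strand=g.strand,
                status=status if target == GENCODE
                       else {"processed_pseudogene": "pseudogene"}.get(status, status),
                exons=exon)
            (gc_side if target == GENCODE else rs_side).append(rec)
        if g.category == "ig_tr":
            # RefSeq types the fragment cluster as 'other'
            if REFSEQ in _non_annotators(g.cell):
                rs_side.append(GeneRecord(
                    gene_id=str(900000 + side_no), source=REFSEQ,
                    hgnc_symbol=g.symbol + "-FRAG", chrom=g.chrom,
                    start=g.start, end=g.end, strand=g.strand, status="other"))
                side_no += 1

    # extra UniProt entries for the quirks
    for g in genes:
        if g.quirk == "multi_uniprot":
            up_records.append(GeneRecord(
                gene_id=f"X{g.idx % 100000:05d}", source=UNIPROT,
                symbols=(g.symbol,), chrom=g.chrom, start=g.start, end=g.end,
                strand=g.strand, protein_length=100,
                evidence_code="protein_level"))
    if shared:
        up_records.append(GeneRecord(
            gene_id=shared_acc, source=UNIPROT,
            symbols=tuple(g.symbol for g in shared),
            chrom=shared[0].chrom, start=shared[0].start, end=shared[0].end,
            strand=shared[0].strand, protein_length=150,
            evidence_code="protein_level"))

    up_extra_rows: list[dict] = []
    for i in range(spec.quirks.unreviewed_entries):
        up_extra_rows.append({"accession": f"T{i:05d}", "reviewed": "no",
                              "gene_symbols": f"TREMBL{i}", "placement": "genome"})
    scaffold_records = []
    for i in range(spec.quirks.scaffold_entries):
        scaffold_records.append(GeneRecord(
            gene_id=f"S{i:05d}", source=UNIPROT, symbols=(f"SCAF{i}",),
            tags={TAG_SCAFFOLD}, protein_length=120,
            evidence_code="protein_level"))
    up_records += scaffold_records

    # keep in-memory records identical to what the file readers reconstruct:
    # the readers derive the IG/TR tag from the symbol
    from .catalogue_io import looks_ig_tr, TAG_IG_TR
    for rec in gc_records + gc_side + rs_records + rs_side + up_records:
        if any(looks_ig_tr(s) for s in rec.symbols):
            rec.tags.add(TAG_IG_TR)

    catalogues = {
        GENCODE: Catalogue(GENCODE, gc_records, "synthetic", gc_side),
        REFSEQ: Catalogue(REFSEQ, rs_records, "synthetic", rs_side),
        UNIPROT: Catalogue(UNIPROT, up_records, "synthetic"),
    }
    catalogues[UNIPROT].skip_counts["unreviewed_rows_pending"] = len(up_extra_rows)
    catalogues[UNIPROT].__dict__["_unreviewed_rows"] = up_extra_rows  # for writers

    # ---- 6. evidence table (GENCODE-membered loci) --------------------------
    ev_rows = []
    for g in genes:
        if GENCODE not in g.sources:
            continue
        feats = g.features
        if "phylocsf_max" in feats:
            phylo = "-20.0:15"
        elif "no_protein_features" in feats:
            phylo = "-5.0:15"
        else:
            phylo = "8.0:40;3.0:8"
        booleans = "no_protein_features" not in feats
        ev_rows.append({
            "gene_id": g.ids[GENCODE],
            "phylocsf_exons": phylo,
            "gene_age_depth": ("catarrhini" if "recent_gene_age" in feats
                               else "vertebrata"),
            "has_functional_residues": int(booleans),
            "has_structure_homology": 0,
            "has_domain": int(booleans),
            "has_conservation": int(booleans),
            "has_tm_helix": 0,
        })
    evidence = pd.DataFrame(ev_rows, columns=[
        "gene_id", "phylocsf_exons", "gene_age_depth", "has_functional_residues",
        "has_structure_homology", "has_domain", "has_conservation", "has_tm_helix"])

    # descriptions for the described_pseudogene feature
    for g in genes:
        if "described_pseudogene" in g.features:
            g.description = "Putative uncharacterized protein, pseudogene candidate"
    for rec_list in (rs_records, up_records):
        by = {r.gene_id: r for r in rec_list}
        for g in genes:
            if g.description:
                for src in (REFSEQ, UNIPROT):
                    r = by.get(g.ids.get(src, ""))
                    if r is not None:
                        r.description = g.description

    # ---- 7. peptides --------------------------------------------------------
    peptides: list[PeptideRecord] = []
    pep_no = 0

    def peptide_gene(g: TruthGene) -> str:
        for s in (GENCODE, REFSEQ, UNIPROT):
            if s in g.ids:
                return g.ids[s]
        raise AssertionError

    for g in genes:
        if not g.supported:
            continue
        target = peptide_gene(g)
        for _ in range(2):
            peptides.append(PeptideRecord(
                sequence=_digit_peptide(pep_no), preceding_residue="K",
                following_residue="A", n_observations=3,
                mapped_genes=frozenset({target})))
            pep_no += 1
    supported_ids = [peptide_gene(g) for g in genes if g.supported]
    unsupported = [g for g in genes if not g.supported]
    pd_spec = spec.peptide_decoys
    for i in range(pd_spec.multi_gene):
        pair = supported_ids[:2] if len(supported_ids) >= 2 else ["GX1", "GX2"]
        peptides.append(PeptideRecord(
            sequence=_digit_peptide(pep_no, "K"), preceding_residue="R",
            following_residue="G", n_observations=4,
            mapped_genes=frozenset(pair)))
        pep_no += 1
    for i in range(pd_spec.single_observation):
        g = unsupported[i % len(unsupported)]
        peptides.append(PeptideRecord(
            sequence=_digit_peptide(pep_no), preceding_residue="K",
            following_residue="S", n_observations=1,
            mapped_genes=frozenset({peptide_gene(g)})))
        pep_no += 1
    for i in range(pd_spec.non_tryptic):
        g = unsupported[(i + 7) % len(unsupported)]
        peptides.append(PeptideRecord(
            sequence=_digit_peptide(pep_no, "G"), preceding_residue="L",
            following_residue="A", n_observations=5,
            mapped_genes=frozenset({peptide_gene(g)})))
        pep_no += 1
    if pd_spec.readthrough_single_peptide:
        rt = [g for g in genes if g.readthrough and not g.supported]
        if rt:
            peptides.append(PeptideRecord(
                sequence=_digit_peptide(pep_no), preceding_residue="K",
                following_residue="V", n_observations=5,
                mapped_genes=frozenset({peptide_gene(rt[0])})))
            pep_no += 1

    # ---- 8. variants --------------------------------------------------------
    def select_genes(selector: str) -> list[TruthGene]:
        def has_principal(g):
            return g.principal is not None
        if selector == "all":
            out = genes
        elif selector == "intersection":
            out = by_cell["GRU"]
        elif selector == "outside":
            out = [g for g in genes if g.cell != "GRU"]
        elif selector == "refseq_outside":
            out = [g for g in genes if g.cell != "GRU" and REFSEQ in g.sources]
        elif selector == "peptide_supported":
            out = [g for g in genes if g.supported]
        elif selector == "flagged":
            out = [g for g in genes if g.features]
        elif selector == "unflagged":
            out = [g for g in genes if not g.features]
        elif selector.startswith("cell:"):
            out = by_cell[selector[5:]]
        else:
            raise FixtureError(f"unknown variant selector {selector!r}")
        out = [g for g in out if has_principal(g)]
        if not out:
            raise FixtureError(f"variant selector {selector!r} matches no genes")
        return out

    var_rows: list[dict] = []
    model_truth: list[dict] = []
    var_no = 0

    def af_value(stratum: str) -> float:
        if stratum == "rare":
            lo, hi = math.log10(1e-5), math.log10(0.005) - 1e-9
        else:
            lo, hi = math.log10(0.0051), math.log10(0.5)
        return float(10 ** rng.uniform(lo, hi))

    for m in spec.variant_models:
        subset = select_genes(m.selector)
        n_rare = int(round(m.n_variants * m.rare_fraction))
        n_common = m.n_variants - n_rare
        counts = {}
        for stratum, n_str, ratio in (("rare", n_rare, m.rare_ratio),
                                      ("common", n_common, m.common_ratio)):
            p = ratio / (1.0 + ratio)
            if m.sampling == "exact":
                ns = int(round(n_str * p))
            else:
                ns = int(rng.binomial(n_str, p))
            counts[stratum] = (ns, n_str - ns)
        gene_ids = [g.principal_gene for g in subset]
        tx = {g.principal_gene: g.principal for g in subset}
        for stratum in ("rare", "common"):
            ns, syn = counts[stratum]
            for effect, k in (("missense_variant", ns), ("synonymous_variant", syn)):
                for _ in range(k):
                    gid = gene_ids[int(rng.integers(len(gene_ids)))]
                    terms = effect
                    if var_no % 20 == 7:
                        terms = effect + "&splice_region_variant"
                    var_rows.append({
                        "variant_id": f"var{var_no:07d}", "gene_id": gid,
                        "transcript_id": tx[gid],
                        "alt_allele": "ACGT"[var_no % 4],
                        "consequence_terms": terms,
                        "max_af": round(af_value(stratum), 8)})
                    var_no += 1
        model_truth.append({
            "label": m.label, "selector": m.selector,
            "n_genes": len(subset), "n_variants": m.n_variants,
            "true_rare_ratio": m.rare_ratio, "true_common_ratio": m.common_ratio,
            "rare_ns": counts["rare"][0], "rare_syn": counts["rare"][1],
            "common_ns": counts["common"][0], "common_syn": counts["common"][1],
            "sampling": m.sampling})

    # decoy rows, none of which survives filtering
    pg = [g for g in genes if g.principal is not None]
    d = spec.variant_decoys
    decoy_defs = (
        ("frameshift", d.frameshift,
         dict(consequence_terms="frameshift_variant", alt_allele="A", max_af=0.01)),
        ("splice_region_only", d.splice_region_only,
         dict(consequence_terms="splice_region_variant", alt_allele="C", max_af=0.01)),
        ("zero_af", d.zero_af,
         dict(consequence_terms="missense_variant", alt_allele="G", max_af=0.0)),
        ("missing_af", d.missing_af,
         dict(consequence_terms="missense_variant", alt_allele="T", max_af="")),
        ("bad_allele", d.bad_allele,
         dict(consequence_terms="missense_variant", alt_allele="AT", max_af=0.01)),
        ("non_principal", d.non_principal,
         dict(consequence_terms="missense_variant", alt_allele="A", max_af=0.01)),
    )
    n_decoys = 0
    for kind, n, proto in decoy_defs:
        for i in range(n):
            g = pg[(i * 13 + n_decoys) % len(pg)]
            row = {"variant_id": f"var{var_no:07d}", "gene_id": g.principal_gene,
                   "transcript_id": g.principal, **proto}
            if kind == "non_principal":
                row["transcript_id"] = g.principal + "alt"
            var_rows.append(row)
            var_no += 1
            n_decoys += 1
    variants = pd.DataFrame(var_rows, columns=[
        "variant_id", "gene_id", "transcript_id", "alt_allele",
        "consequence_terms", "max_af"])

    return FixtureBundle(spec=spec, catalogues=catalogues, variants=variants,
                         evidence=evidence, peptides=peptides,
                         truth_genes=genes, model_truth=model_truth)


# --------------------------------------------------------------------------
# file writers for the source dialects
# --------------------------------------------------------------------------

def _gtf_attrs(pairs: list[tuple[str, str]]) -> str:
    return " ".join(f'{k} "{v}";' for k, v in pairs)


def _write_gencode_gtf(cat: Catalogue, path: Path) -> None:
    lines: list[str] = ["##provider: synthetic"]

    def emit(rec: GeneRecord, coding: bool):
        base = [("gene_id", rec.gene_id)]
        if rec.hgnc_symbol:
            base.append(("gene_name", rec.hgnc_symbol))
        base.append(("gene_type", rec.status))
        from .catalogue_io import _fmt_xrefs
        if rec.cross_refs:
            base.append(("cross_refs", _fmt_xrefs(rec.cross_refs)))
        chrom = f"chr{rec.chrom}"
        lines.append("\t".join([chrom, "SYNTH", "gene", str(rec.start),
                                str(rec.end), ".", rec.strand or "+", ".",
                                _gtf_attrs(base)]))
        tid = rec.principal_transcript_id or (rec.gene_id + "T")
        tattrs = base + [("transcript_id", tid), ("tag", "appris_principal")]
        if TAG_READTHROUGH in rec.tags:
            tattrs.append(("tag", "readthrough_gene"))
        lines.append("\t".join([chrom, "SYNTH", "transcript", str(rec.start),
                                str(rec.end), ".", rec.strand or "+", ".",
                                _gtf_attrs(tattrs)]))
        for s, e in (rec.exons or [(rec.start, rec.end)]):
            lines.append("\t".join([chrom, "SYNTH", "exon", str(s), str(e), ".",
                                    rec.strand or "+", ".", _gtf_attrs(tattrs)]))
        for s, e, side in rec.utr_intervals:
            feat = "five_prime_utr" if side == "5" else "three_prime_utr"
            lines.append("\t".join([chrom, "SYNTH", feat, str(s), str(e), ".",
                                    rec.strand or "+", ".", _gtf_attrs(tattrs)]))

    for rec in cat.records:
        emit(rec, True)
    for rec in cat.side_records:
        emit(rec, False)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def _write_refseq_tsv(cat: Catalogue, path: Path) -> None:
    from .catalogue_io import _fmt_xrefs
    cols = ["gene_id", "symbol", "chromosome", "start", "end", "strand",
            "gene_type", "assembly", "tags", "cross_refs",
            "principal_transcript_id", "description"]
    rows = []
    for rec in list(cat.records) + list(cat.side_records):
        rows.append({
            "gene_id": rec.gene_id, "symbol": rec.hgnc_symbol or "",
            "chromosome": rec.chrom or "", "start": rec.start or "",
            "end": rec.end or "", "strand": rec.strand or "",
            "gene_type": rec.status, "assembly": "GRCh38",
            "tags": ";".join(sorted(rec.tags - {"ig_tr_fragment"})),
            "cross_refs": _fmt_xrefs(rec.cross_refs),
            "principal_transcript_id": rec.principal_transcript_id or "",
            "description": rec.description or "",
        })
    df = pd.DataFrame(rows, columns=cols)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def _write_uniprot_tsv(cat: Catalogue, path: Path) -> None:
    cols = ["accession", "reviewed", "gene_symbols", "chrom", "start", "end",
            "strand", "placement", "cross_refs_gencode", "cross_refs_refseq",
            "protein_length", "description", "evidence_code", "caution_notes",
            "tags"]
    rows = []
    for rec in cat.records:
        placement = "genome"
        if TAG_SCAFFOLD in rec.tags:
            placement = "scaffold"
        elif TAG_NO_COORDS in rec.tags:
            placement = "none"
        rows.append({
            "accession": rec.gene_id, "reviewed": "yes",
            "gene_symbols": ";".join(rec.symbols),
            "chrom": rec.chrom or "", "start": rec.start or "",
            "end": rec.end or "", "strand": rec.strand or "",
            "placement": placement,
            "cross_refs_gencode": ";".join(rec.cross_refs.get(GENCODE, [])),
            "cross_refs_refseq": ";".join(rec.cross_refs.get(REFSEQ, [])),
            "protein_length": rec.protein_length or "",
            "description": rec.description or "",
            "evidence_code": rec.evidence_code or "",
            "caution_notes": ";".join(sorted(rec.caution_notes)),
            "tags": ";".join(sorted(rec.tags - {"ig_tr_fragment", TAG_SCAFFOLD,
                                                TAG_NO_COORDS})),
        })
    for extra in cat.__dict__.get("_unreviewed_rows", []):
        rows.append({**{c: "" for c in cols}, **extra})
    df = pd.DataFrame(rows, columns=cols)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


# --------------------------------------------------------------------------
# shrinking
# --------------------------------------------------------------------------

def largest_remainder(counts: dict, target_total: int) -> dict:
    """Apportion ``target_total`` across keys proportionally to ``counts``."""
    total = sum(counts.values())
    if total == 0:
        return {k: 0 for k in counts}
    quotas = {k: target_total * v / total for k, v in counts.items()}
    out = {k: int(math.floor(q)) for k, q in quotas.items()}
    short = target_total - sum(out.values())
    order = sorted(counts, key=lambda k: (-(quotas[k] - out[k]), str(k)))
    for k in order[:short]:
        out[k] += 1
    return out


def shrink_fixture(spec: FixtureSpec, factor: float) -> FixtureSpec:
    """Scale a spec's cardinalities by ``factor`` with largest-remainder
    apportionment so that cell and category proportions are preserved to ±1."""
    if not (0.0 < factor <= 1.0):
        raise FixtureError("factor must be in (0, 1]")
    if factor == 1.0:
        return replace(spec)

    total = sum(spec.venn_cells.values())
    new_cells = largest_remainder(spec.venn_cells, int(round(factor * total)))

    new_cat: dict[str, dict[str, int]] = {}
    for cell, cats in spec.category_cells.items():
        n_catted = sum(cats.values())
        share = int(round(new_cells.get(cell, 0) * n_catted
                          / max(spec.venn_cells.get(cell, 1), 1)))
        new_cat[cell] = largest_remainder(cats, min(share, new_cells.get(cell, 0)))

    new_blocks: list[FeatureBlock] = []
    taken: dict[tuple[str, str | None], int] = {}
    for b in spec.feature_blocks:
        if b.category is not None:
            avail = new_cat.get(b.cell, {}).get(b.category, 0)
        else:
            avail = new_cells.get(b.cell, 0)
        key = (b.cell, b.category)
        avail -= taken.get(key, 0)
        count = min(int(round(b.count * factor)), max(avail, 0))
        if b.category == "readthrough":
            # readthrough blocks must cover the scaled category exactly
            count = max(avail, 0)
        if count <= 0:
            continue
        taken[key] = taken.get(key, 0) + count
        new_blocks.append(replace(b, count=count,
                                  n_supported=min(int(round(b.n_supported * factor)),
                                                  count)))

    def scale_map(m: dict[str, int]) -> dict[str, int]:
        return {k: int(round(v * factor)) for k, v in m.items()}

    new_spec = replace(
        spec,
        venn_cells=new_cells,
        category_cells=new_cat,
        feature_blocks=new_blocks,
        unflagged_supported=scale_map(spec.unflagged_supported),
        legacy_evidence={c: (int(round(h * factor)), int(round(p * factor)))
                         for c, (h, p) in spec.legacy_evidence.items()},
        variant_models=[replace(m, n_variants=max(int(round(m.n_variants * factor)), 100))
                        for m in spec.variant_models],
        variant_decoys=VariantDecoySpec(**{
            k: int(round(v * factor))
            for k, v in asdict(spec.variant_decoys).items()}),
        peptide_decoys=replace(spec.peptide_decoys, **{
            k: int(round(v * factor))
            for k, v in asdict(spec.peptide_decoys).items()
            if k != "readthrough_single_peptide"}),
        quirks=MergeQuirkSpec(**{
            k: int(round(v * factor)) for k, v in asdict(spec.quirks).items()}),
    )
    # clamp allocations that rounding pushed past the shrunken cell sizes
    for cell in VENN_CELLS:
        cap = new_spec.venn_cells.get(cell, 0)
        blocks = sum(b.count for b in new_spec.feature_blocks if b.cell == cell)
        extra = (new_spec.unflagged_supported.get(cell, 0)
                 + sum(new_spec.legacy_evidence.get(cell, (0, 0))))
        over = blocks + extra - cap
        if cell == "GRU":
            over += sum(v for v in asdict(new_spec.quirks).values())
            hosted = sum(n for c, cats in new_spec.category_cells.items()
                         for cat, n in cats.items()
                         if cat in HOSTED_CATEGORIES
                         and _auto_realise(cat, c) == "geometry")
            over += hosted
        if over > 0 and cell in new_spec.unflagged_supported:
            new_spec.unflagged_supported[cell] = max(
                new_spec.unflagged_supported[cell] - over, 0)
    validate_spec(new_spec)
    return new_spec


# --------------------------------------------------------------------------
# the study-scale spec
# --------------------------------------------------------------------------

def full_scale_spec(seed: int = 0) -> FixtureSpec:
    """The full-scale fixture: 21 871 loci with the published Venn structure,
    discrepancy-category mix, feature tallies, peptide-support rates and
    NS/Syn variant regimes."""
    venn = {"GRU": 19268, "G": 776, "R": 511, "U": 847,
            "GR": 100, "GU": 299, "RU": 70}
    category_cells = {
        "G": {"readthrough": 582, "pseudogene": 60, "antisense": 50,
              "lncRNA": 40, "intergenic": 20, "utr_orf": 10, "intronic": 9,
              "retroviral": 5},
        "R": {"readthrough": 20, "artefact_tec": 55, "pseudogene": 60,
              "antisense": 130, "lncRNA": 120, "intergenic": 60,
              "utr_orf": 30, "intronic": 20, "retroviral": 16},
        "U": {"no_coordinates": 150, "ig_tr": 200, "pseudogene": 350,
              "antisense": 50, "lncRNA": 53, "intergenic": 24, "utr_orf": 10,
              "intronic": 5, "retroviral": 5},
        "GR": {"readthrough": 7, "utr_orf": 40, "intronic": 40,
               "antisense": 3, "intergenic": 10},
        "GU": {"readthrough": 60, "ig_tr": 229, "pseudogene": 6, "lncRNA": 4},
        "RU": {"pseudogene": 8, "antisense": 6, "intronic": 10,
               "retroviral": 46},
    }
    blocks = [
        # intersection: 275 flagged genes
        FeatureBlock("GRU", ("readthrough_gene",), 6),
        FeatureBlock("GRU", ("recent_gene_age", "caution_note"), 60),
        FeatureBlock("GRU", ("recent_gene_age", "uncertain_evidence"), 55),
        FeatureBlock("GRU", ("recent_gene_age", "described_pseudogene"), 30),
        FeatureBlock("GRU", ("recent_gene_age", "non_coding_name"), 24),
        FeatureBlock("GRU", ("caution_note",), 1),
        FeatureBlock("GRU", ("recent_gene_age",), 63, n_supported=19),
        FeatureBlock("GRU", ("described_pseudogene",), 22, n_supported=19),
        FeatureBlock("GRU", ("non_coding_name",), 14, n_supported=5),
        # GENCODE-only: 701 flagged
        FeatureBlock("G", ("readthrough_gene",), 582, category="readthrough"),
        FeatureBlock("G", ("no_protein_features", "phylocsf_max"), 88),
        FeatureBlock("G", ("no_protein_features",), 30, n_supported=20),
        FeatureBlock("G", ("phylocsf_max",), 1, n_supported=1),
        # RefSeq-only: 390 flagged
        FeatureBlock("R", ("readthrough_gene",), 20, category="readthrough"),
        FeatureBlock("R", ("described_pseudogene",), 250),
        FeatureBlock("R", ("non_coding_name",), 120, category="lncRNA"),
        # UniProt-only: 532 flagged
        FeatureBlock("U", ("caution_note",), 200),
        FeatureBlock("U", ("uncertain_evidence",), 180),
        FeatureBlock("U", ("described_pseudogene",), 99),
        FeatureBlock("U", ("non_coding_name",), 53, category="lncRNA",
                     realise="name"),
        # GENCODE+RefSeq: 25 flagged
        FeatureBlock("GR", ("readthrough_gene",), 7, category="readthrough"),
        FeatureBlock("GR", ("recent_gene_age",), 9),
        FeatureBlock("GR", ("phylocsf_max",), 9, n_supported=9),
        # GENCODE+UniProt: 120 flagged
        FeatureBlock("GU", ("readthrough_gene",), 60, category="readthrough"),
        FeatureBlock("GU", ("caution_note",), 30, n_supported=24),
        FeatureBlock("GU", ("uncertain_evidence",), 28, n_supported=22),
        FeatureBlock("GU", ("described_pseudogene",), 2),
        # RefSeq+UniProt: 16 flagged
        FeatureBlock("RU", ("described_pseudogene",), 16),
    ]
    return FixtureSpec(
        seed=seed,
        venn_cells=venn,
        category_cells=category_cells,
        feature_blocks=blocks,
        unflagged_supported={"GRU": 17235},
        legacy_evidence={"GRU": (30, 30)},
        variant_models=[
            VariantSubsetModel("refseq_outside", "refseq_outside",
                               rare_ratio=2.31, common_ratio=2.24,
                               n_variants=20000),
            VariantSubsetModel("peptide_supported", "peptide_supported",
                               rare_ratio=1.96, common_ratio=0.9,
                               n_variants=20000),
        ],
        variant_decoys=VariantDecoySpec(frameshift=500, splice_region_only=300,
                                        zero_af=200, missing_af=200,
                                        bad_allele=100, non_principal=200),
        peptide_decoys=PeptideDecoySpec(multi_gene=50, single_observation=100,
                                        non_tryptic=80,
                                        readthrough_single_peptide=True),
        quirks=MergeQuirkSpec(xref_matched=40, overlap_matched=20,
                              multi_uniprot=5, shared_uniprot_span=6,
                              unreviewed_entries=30, scaffold_entries=10),
    )
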