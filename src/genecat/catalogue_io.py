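"""Readers and writers for the three coding-gene catalogue dialects.

Three sources are normalised into a common :class:`GeneRecord` model:

* ``GENCODE`` — a GTF annotation (gene/transcript/exon/UTR feature lines),
  restricted to protein-coding genes on the 24 nuclear chromosomes plus MT.
* ``REFSEQ``  — a tab-separated gene table (gene id, symbol, coordinates,
  strand, gene type, assembly).  Rows typed ``other`` (immunoglobulin and
  T-cell receptor fragments) and other non-coding rows are kept on a side
  list for overlap queries but are not coding records.
* ``UNIPROT`` — a tab-separated protein-entry table with cross-references.
  Only reviewed entries are kept; scaffold-only and unplaced entries are
  tagged so the merge stage can exclude them.

All coordinates are 1-based inclusive throughout (GTF native); no 0-based
dialect is accepted.  Writers emit UTF-8, tab-delimited, LF line endings.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd

GENCODE = "GENCODE"
REFSEQ = "REFSEQ"
UNIPROT = "UNIPROT"
SOURCES = (GENCODE, REFSEQ, UNIPROT)

#: chromosomes of the primary assembly: 1..22, X, Y and the mitochondrial chromosome
DEFAULT_CHROMS = frozenset([str(i) for i in range(1, 23)] + ["X", "Y", "MT"])

#: record-level tags with pipeline meaning
TAG_READTHROUGH = "readthrough"
TAG_IG_TR = "ig_tr_fragment"
TAG_SCAFFOLD = "scaffold_only"
TAG_NO_COORDS = "no_coordinates"
KNOWN_TAGS = frozenset({TAG_READTHROUGH, TAG_IG_TR, TAG_SCAFFOLD, TAG_NO_COORDS})

#: immunoglobulin / T-cell receptor fragment symbols: IGHV1-69, IGKC, TRBV5-1 ...
IG_TR_SYMBOL_RE = re.compile(r"^(IG[HKL][VDJC]|TR[ABGD][VDJC])[0-9\-]*")

UNIPROT_EVIDENCE_CODES = frozenset(
    {"protein_level", "transcript_level", "homology", "predicted", "uncertain"}
)


class CatalogueError(Exception):
    """Base error for catalogue parsing problems."""


class GtfParseError(CatalogueError):
    def __init__(self, path, line_no, message):
        self.line_no = line_no
        super().__init__(f"{path}: line {line_no}: {message}")


class SchemaError(CatalogueError):
    def __init__(self, path, missing):
        self.missing = tuple(missing)
        super().__init__(f"{path}: missing required column(s): {', '.join(missing)}")


class DuplicateAccessionError(CatalogueError):
    pass


def looks_ig_tr(symbol: str | None) -> bool:
    """Symbol-pattern heuristic for immunoglobulin / T-cell receptor fragments."""
    return bool(symbol) and IG_TR_SYMBOL_RE.match(symbol) is not None


def normalise_chrom(chrom: str | None) -> str | None:
    if chrom is None or chrom == "" or chrom == ".":
        return None
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return "MT" if c in ("M", "mt") else c


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals, sorted and non-overlapping."""
    ivs = sorted(intervals)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


@dataclass
class GeneRecord:
    """One gene in one source catalogue, in the normalised model."""

    gene_id: str
    source: str
    hgnc_symbol: str | None = None
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str | None = None
    status: str = "protein_coding"
    tags: set[str] = field(default_factory=set)
    exons: list[tuple[int, int]] = field(default_factory=list)
    utr_intervals: list[tuple[int, int, str]] = field(default_factory=list)
    cross_refs: dict[str, list[str]] = field(default_factory=dict)
    principal_transcript_id: str | None = None
    #: all symbols attached to the entry (UniProt entries may carry several);
    #: hgnc_symbol is the first
    symbols: tuple[str, ...] = ()
    protein_length: int | None = None
    description: str | None = None
    evidence_code: str | None = None
    caution_notes: set[str] = field(default_factory=set)

    def __post_init__(self):
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if self.hgnc_symbol and not self.symbols:
            self.symbols = (self.hgnc_symbol,)
        if self.symbols and not self.hgnc_symbol:
            self.hgnc_symbol = self.symbols[0]
        self.symbols = tuple(s.strip() for s in self.symbols if s and s.strip())
        if self.hgnc_symbol:
            self.hgnc_symbol = self.hgnc_symbol.strip()
        if TAG_NO_COORDS in self.tags:
            self.chrom = self.start = self.end = None
            self.exons = []
            self.utr_intervals = []
        if self.start is not None and self.end is not None:
            if self.start > self.end:
                raise ValueError(
                    f"{self.gene_id}: start {self.start} > end {self.end}"
                )
            for s, e in self.exons:
                if s < self.start or e > self.end:
                    raise ValueError(
                        f"{self.gene_id}: exon ({s}, {e}) outside gene span"
                    )
            self.exons = _merge_intervals(self.exons)

    @property
    def has_coordinates(self) -> bool:
        return self.chrom is not None and self.start is not None and self.end is not None

    @property
    def span_length(self) -> int:
        return 0 if not self.has_coordinates else self.end - self.start + 1

    def introns(self) -> list[tuple[int, int]]:
        """Intervals strictly between consecutive (merged) exons."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return out


@dataclass
class Catalogue:
    """All records of one source, plus non-coding side records for overlap queries."""

    source: str
    records: list[GeneRecord] = field(default_factory=list)
    release_label: str = ""
    side_records: list[GeneRecord] = field(default_factory=list)
    skip_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for r in self.records:
            if r.source != self.source:
                raise ValueError(
                    f"record {r.gene_id} has source {r.source}, catalogue is {self.source}"
                )

    def __len__(self):
        return len(self.records)

    def by_id(self) -> dict[str, GeneRecord]:
        return {r.gene_id: r for r in self.records}


# ---------------------------------------------------------------------------
# GENCODE-role GTF
# ---------------------------------------------------------------------------

def _validate_gtf_lines(path: str | Path):
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GtfParseError(path, line_no, f"expected 9 columns, found {len(fields)}")
            attrs = fields[8]
            if '"' in attrs and attrs.count('"') % 2 != 0:
                raise GtfParseError(path, line_no, "unbalanced quotes in attribute column")
            if "gene_id" not in attrs:
                raise GtfParseError(path, line_no, "attribute column lacks gene_id")


def read_gencode_gtf(
    path: str | Path,
    chrom_whitelist: frozenset[str] | set[str] = DEFAULT_CHROMS,
    readthrough_tag_value: str = "readthrough_gene",
    readthrough_mode: str = "all",
    release_label: str = "",
) -> Catalogue:
    """Read a GENCODE-role GTF into a :class:`Catalogue`.

    Protein-coding genes on whitelisted chromosomes become records; genes of
    any other biotype on those chromosomes are kept as side records (the
    discrepancy classifier queries them).  A gene is tagged ``readthrough``
    when all of its transcripts carry the readthrough tag attribute
    (``readthrough_mode="any"`` relaxes this to at least one transcript).
    """
    if readthrough_mode not in ("all", "any"):
        raise ValueError("readthrough_mode must be 'all' or 'any'")
    _validate_gtf_lines(path)
    db = gffutils.create_db(
        str(path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
    )

    # transcript-level readthrough tags, and exon/UTR aggregation per gene
    rt_by_gene: dict[str, list[bool]] = {}
    exons_by_gene: dict[str, list[tuple[int, int]]] = {}
    utrs_by_gene: dict[str, list[tuple[int, int, str]]] = {}
    principal_by_gene: dict[str, str] = {}
    for t in db.features_of_type("transcript"):
        gid = t.attributes["gene_id"][0]
        tags = t.attributes.get("tag", [])
        rt_by_gene.setdefault(gid, []).append(readthrough_tag_value in tags)
        if "appris_principal" in tags or gid not in principal_by_gene:
            principal_by_gene[gid] = t.attributes.get("transcript_id", [None])[0]
    for x in db.features_of_type("exon"):
        gid = x.attributes["gene_id"][0]
        exons_by_gene.setdefault(gid, []).append((x.start, x.end))
    for feat, side in (("five_prime_utr", "5"), ("three_prime_utr", "3"), ("UTR", "5")):
        for x in db.features_of_type(feat):
            gid = x.attributes["gene_id"][0]
            utrs_by_gene.setdefault(gid, []).append((x.start, x.end, side))

    records: list[GeneRecord] = []
    side: list[GeneRecord] = []
    skipped_chrom = 0
    for g in db.features_of_type("gene"):
        gid = g.attributes["gene_id"][0]
        chrom = normalise_chrom(g.seqid)
        if chrom not in chrom_whitelist:
            skipped_chrom += 1
            continue
        biotype = (g.attributes.get("gene_type") or g.attributes.get("gene_biotype") or ["?"])[0]
        symbol = (g.attributes.get("gene_name") or [None])[0]
        tags: set[str] = set()
        flags = rt_by_gene.get(gid, [])
        if flags and (all(flags) if readthrough_mode == "all" else any(flags)):
            tags.add(TAG_READTHROUGH)
        if looks_ig_tr(symbol):
            tags.add(TAG_IG_TR)
        rec = GeneRecord(
            gene_id=gid,
            source=GENCODE,
            hgnc_symbol=symbol,
            chrom=chrom,
            start=g.start,
            end=g.end,
            strand=g.strand if g.strand in ("+", "-") else None,
            status=biotype,
            tags=tags,
            exons=exons_by_gene.get(gid, []),
            utr_intervals=utrs_by_gene.get(gid, []),
            cross_refs=_parse_xrefs((g.attributes.get("cross_refs") or [""])[0]),
            principal_transcript_id=principal_by_gene.get(gid),
        )
        (records if biotype == "protein_coding" else side).append(rec)

    return Catalogue(
        source=GENCODE,
        records=records,
        release_label=release_label,
        side_records=side,
        skip_counts={"chromosome_not_whitelisted": skipped_chrom},
    )


# ---------------------------------------------------------------------------
# RefSeq-role gene table
# ---------------------------------------------------------------------------

REFSEQ_REQUIRED = ("gene_id", "symbol", "chromosome", "start", "end", "strand",
                   "gene_type", "assembly")


def read_refseq_table(
    path: str | Path,
    assembly: str = "GRCh38",
    release_label: str = "",
) -> Catalogue:
    """Read a RefSeq-role TSV.  Only rows of the configured assembly are used;
    ``protein-coding`` rows become records and every other gene type goes to
    the side list (``other`` rows are the IG/TR fragment clusters)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REFSEQ_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(path, missing)

    records: list[GeneRecord] = []
    side: list[GeneRecord] = []
    skipped_assembly = 0
    for row in df.itertuples(index=False):
        if row.assembly != assembly:
            skipped_assembly += 1
            continue
        symbol = row.symbol or None
        tags = _parse_set(getattr(row, "tags", "")) & KNOWN_TAGS
        if looks_ig_tr(symbol):
            tags.add(TAG_IG_TR)
        rec = GeneRecord(
            gene_id=str(row.gene_id),
            source=REFSEQ,
            hgnc_symbol=symbol,
            chrom=normalise_chrom(row.chromosome),
            start=int(row.start) if row.start else None,
            end=int(row.end) if row.end else None,
            strand=row.strand if row.strand in ("+", "-") else None,
            status=row.gene_type,
            tags=tags,
            cross_refs=_parse_xrefs(getattr(row, "cross_refs", "")),
            principal_transcript_id=getattr(row, "principal_transcript_id", "") or None,
            description=getattr(row, "description", "") or None,
        )
        (records if row.gene_type == "protein-coding" else side).append(rec)

    return Catalogue(
        source=REFSEQ,
        records=records,
        release_label=release_label,
        side_records=side,
        skip_counts={"other_assembly": skipped_assembly},
    )


# ---------------------------------------------------------------------------
# UniProt-role protein-entry table
# ---------------------------------------------------------------------------

UNIPROT_REQUIRED = ("accession", "reviewed", "gene_symbols")


def read_uniprot_table(path: str | Path, release_label: str = "") -> Catalogue:
    """Read a UniProt-role TSV.  Only reviewed entries are emitted; entries
    placed only on scaffolds are tagged ``scaffold_only`` and entries with no
    genomic mapping are tagged ``no_coordinates``."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in UNIPROT_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(path, missing)

    records: list[GeneRecord] = []
    seen: set[str] = set()
    skipped_unreviewed = 0
    for row in df.itertuples(index=False):
        acc = str(row.accession)
        if acc in seen:
            raise DuplicateAccessionError(f"{path}: duplicate accession {acc}")
        seen.add(acc)
        if row.reviewed.strip().lower() not in ("yes", "true", "reviewed", "1"):
            skipped_unreviewed += 1
            continue
        symbols = tuple(s for s in _parse_list(row.gene_symbols))
        placement = getattr(row, "placement", "genome") or "genome"
        tags = _parse_set(getattr(row, "tags", "")) & KNOWN_TAGS
        if placement == "scaffold":
            tags.add(TAG_SCAFFOLD)
        elif placement == "none":
            tags.add(TAG_NO_COORDS)
        if any(looks_ig_tr(s) for s in symbols):
            tags.add(TAG_IG_TR)
        chrom = normalise_chrom(getattr(row, "chrom", "")) if placement == "genome" else None
        start = getattr(row, "start", "")
        end = getattr(row, "end", "")
        xrefs = {}
        for src, col in ((GENCODE, "cross_refs_gencode"), (REFSEQ, "cross_refs_refseq")):
            vals = _parse_list(getattr(row, col, ""))
            if vals:
                xrefs[src] = vals
        plen = getattr(row, "protein_length", "")
        evcode = getattr(row, "evidence_code", "") or None
        if evcode is not None and evcode not in UNIPROT_EVIDENCE_CODES:
            raise CatalogueError(f"{path}: unknown evidence code {evcode!r} for {acc}")
        records.append(GeneRecord(
            gene_id=acc,
            source=UNIPROT,
            symbols=symbols,
            chrom=chrom,
            start=int(start) if (placement == "genome" and start) else None,
            end=int(end) if (placement == "genome" and end) else None,
            strand=(getattr(row, "strand", "") or None) if placement == "genome" else None,
            status="protein_coding",
            tags=tags,
            cross_refs=xrefs,
            protein_length=int(plen) if plen else None,
            description=getattr(row, "description", "") or None,
            evidence_code=evcode,
            caution_notes=_parse_set(getattr(row, "caution_notes", "")),
        ))

    return Catalogue(
        source=UNIPROT,
        records=records,
        release_label=release_label,
        skip_counts={"unreviewed": skipped_unreviewed},
    )


# ---------------------------------------------------------------------------
# Normalised catalogue TSV (round-trippable)
# ---------------------------------------------------------------------------

CATALOGUE_COLUMNS = (
    "gene_id", "source", "hgnc_symbol", "symbols", "chrom", "start", "end",
    "strand", "status", "tags", "exons", "utr_intervals", "cross_refs",
    "principal_transcript_id", "protein_length", "description",
    "evidence_code", "caution_notes", "is_side_record",
)


def _fmt_intervals(ivs: Sequence[tuple[int, int]]) -> str:
    return ";".join(f"{s}-{e}" for s, e in ivs)


def _parse_intervals(text: str) -> list[tuple[int, int]]:
    out = []
    for part in text.split(";"):
        if part:
            s, e = part.split("-")
            out.append((int(s), int(e)))
    return out


def _fmt_utrs(utrs: Sequence[tuple[int, int, str]]) -> str:
    return ";".join(f"{s}-{e}:{side}" for s, e, side in utrs)


def _parse_utrs(text: str) -> list[tuple[int, int, str]]:
    out = []
    for part in text.split(";"):
        if part:
            iv, side = part.rsplit(":", 1)
            s, e = iv.split("-")
            out.append((int(s), int(e), side))
    return out


def _fmt_xrefs(xrefs: Mapping[str, Sequence[str]]) -> str:
    return "|".join(f"{src}:{','.join(accs)}" for src, accs in sorted(xrefs.items()) if accs)


def _parse_xrefs(text: str) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for part in (text or "").split("|"):
        if part and ":" in part:
            src, accs = part.split(":", 1)
            out[src] = [a for a in accs.split(",") if a]
    return out


def _parse_list(text: str) -> list[str]:
    return [t.strip() for t in (text or "").split(";") if t.strip()]


def _parse_set(text: str) -> set[str]:
    return set(_parse_list(text))


def _record_to_row(r: GeneRecord, is_side: bool) -> dict:
    return {
        "gene_id": r.gene_id,
        "source": r.source,
        "hgnc_symbol": r.hgnc_symbol or "",
        "symbols": ";".join(r.symbols),
        "chrom": r.chrom or "",
        "start": "" if r.start is None else str(r.start),
        "end": "" if r.end is None else str(r.end),
        "strand": r.strand or "",
        "status": r.status,
        "tags": ";".join(sorted(r.tags)),
        "exons": _fmt_intervals(r.exons),
        "utr_intervals": _fmt_utrs(r.utr_intervals),
        "cross_refs": _fmt_xrefs(r.cross_refs),
        "principal_transcript_id": r.principal_transcript_id or "",
        "protein_length": "" if r.protein_length is None else str(r.protein_length),
        "description": r.description or "",
        "evidence_code": r.evidence_code or "",
        "caution_notes": ";".join(sorted(r.caution_notes)),
        "is_side_record": "1" if is_side else "0",
    }


def write_catalogue_tsv(catalogue: Catalogue, path: str | Path) -> None:
    rows = [_record_to_row(r, False) for r in catalogue.records]
    rows += [_record_to_row(r, True) for r in catalogue.side_records]
    df = pd.DataFrame(rows, columns=CATALOGUE_COLUMNS)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# source=%s release=%s\n" % (catalogue.source, catalogue.release_label))
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_catalogue_tsv(path: str | Path) -> Catalogue:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    m = re.match(r"# source=(\S+) release=(.*)", header)
    if not m:
        raise SchemaError(path, ["<source header line>"])
    source, release = m.group(1), m.group(2).strip()
    records, side = [], []
    for row in df.itertuples(index=False):
        rec = GeneRecord(
            gene_id=row.gene_id,
            source=row.source,
            hgnc_symbol=row.hgnc_symbol or None,
            symbols=tuple(_parse_list(row.symbols)),
            chrom=row.chrom or None,
            start=int(row.start) if row.start else None,
            end=int(row.end) if row.end else None,
            strand=row.strand or None,
            status=row.status,
            tags=_parse_set(row.tags),
            exons=_parse_intervals(row.exons),
            utr_intervals=_parse_utrs(row.utr_intervals),
            cross_refs=_parse_xrefs(row.cross_refs),
            principal_transcript_id=row.principal_transcript_id or None,
            protein_length=int(row.protein_length) if row.protein_length else None,
            description=row.description or None,
            evidence_code=row.evidence_code or None,
            caution_notes=_parse_set(row.caution_notes),
        )
        (side if row.is_side_record == "1" else records).append(rec)
    return Catalogue(source=source, records=records, release_label=release,
                     side_records=side)
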