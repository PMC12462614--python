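"""Three-way merge of the gene catalogues into loci, with Venn accounting.

The matching cascade is deterministic: exact HGNC symbol first, then
cross-references (in either direction), then reciprocal coordinate overlap
(>= 50% of the shorter gene span, same chromosome and strand).  Records that
match nothing become single-member loci.  Manual curation of discrepancies
is replaced by this cascade plus a reviewable ambiguity log.

UniProt entries are protein-level, so one locus may attract several entries
(alternatively spliced proteins with separate entries) and one entry may map
to several loci (a sequence-identical protein shared by a gene family).
``dedup_uniprot`` resolves the former to a single canonical entry per locus
and keeps the latter as an explicitly shared entry: each of the k loci still
counts as UniProt-annotated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from intervaltree import IntervalTree

from .catalogue_io import (
    GENCODE, REFSEQ, UNIPROT,
    Catalogue, GeneRecord, TAG_SCAFFOLD,
)

#: the seven non-empty Venn cells, canonical order
VENN_CELLS = ("GRU", "GR", "GU", "RU", "G", "R", "U")
_CELL_LETTER = {GENCODE: "G", REFSEQ: "R", UNIPROT: "U"}


def venn_cell(sources) -> str:
    """Canonical cell label for a set of member sources, e.g. {GENCODE, UNIPROT} -> 'GU'."""
    letters = {_CELL_LETTER[s] for s in sources}
    for cell in VENN_CELLS:
        if set(cell) == letters:
            return cell
    raise ValueError(f"empty or unknown source set: {sources!r}")


def cell_sources(cell: str) -> frozenset[str]:
    rev = {v: k for k, v in _CELL_LETTER.items()}
    return frozenset(rev[c] for c in cell)


@dataclass
class MergedGene:
    """One locus across the three sources."""

    locus_id: str
    symbol: str | None
    members: dict[str, str]            # source -> gene_id (UniProt may be shared)
    records: dict[str, GeneRecord]     # source -> chosen record
    tags: set[str] = field(default_factory=set)
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str | None = None
    uniprot_entries: list[GeneRecord] = field(default_factory=list)  # pre-dedup
    shared_uniprot: bool = False

    @property
    def venn_cell(self) -> str:
        return venn_cell(self.members.keys())

    @property
    def sources(self) -> frozenset[str]:
        return frozenset(self.members.keys())

    def record_priority(self) -> GeneRecord | None:
        """The locus's representative coordinate record (GENCODE, then RefSeq, then UniProt)."""
        for s in (GENCODE, REFSEQ, UNIPROT):
            r = self.records.get(s)
            if r is not None and r.has_coordinates:
                return r
        return None


@dataclass
class VennCounts:
    cells: dict[str, int]

    def __post_init__(self):
        self.cells = {c: int(self.cells.get(c, 0)) for c in VENN_CELLS}

    @property
    def total(self) -> int:
        return sum(self.cells.values())

    @property
    def intersection(self) -> int:
        return self.cells["GRU"]

    @property
    def outside_intersection(self) -> int:
        return self.total - self.intersection

    def per_source_total(self, source: str) -> int:
        letter = _CELL_LETTER[source]
        return sum(n for c, n in self.cells.items() if letter in c)

    def to_dict(self) -> dict:
        return {
            **self.cells,
            "total": self.total,
            "intersection": self.intersection,
            "outside_intersection": self.outside_intersection,
        }


@dataclass
class MatchPolicy:
    """Configuration of the matching cascade."""

    use_symbols: bool = True
    use_cross_refs: bool = True
    use_overlap: bool = True
    min_reciprocal_overlap: float = 0.5   # fraction of the shorter gene span


@dataclass
class MergeResult:
    loci: list[MergedGene]
    ambiguities: list[str] = field(default_factory=list)
    log: list[str] = field(default_factory=list)

    def venn(self) -> VennCounts:
        return compute_venn(self.loci)


class _Locus:
    __slots__ = ("records", "extra_uniprot")

    def __init__(self):
        self.records: dict[str, GeneRecord] = {}
        self.extra_uniprot: list[GeneRecord] = []

    def add(self, rec: GeneRecord) -> bool:
        if rec.source == UNIPROT and UNIPROT in self.records:
            self.extra_uniprot.append(rec)
            return True
        if rec.source in self.records:
            return False
        self.records[rec.source] = rec
        return True


def _sorted_records(cat: Catalogue) -> list[GeneRecord]:
    # sorting by gene_id makes the cascade independent of input record order
    return sorted(cat.records, key=lambda r: r.gene_id)


def match_catalogues(
    gencode: Catalogue,
    refseq: Catalogue,
    uniprot: Catalogue,
    policy: MatchPolicy | None = None,
) -> MergeResult:
    """Merge the three catalogues into loci via the matching cascade."""
    policy = policy or MatchPolicy()
    ambiguities: list[str] = []
    log: list[str] = []

    loci: list[_Locus] = []
    by_symbol: dict[str, list[_Locus]] = {}
    by_gene_id: dict[str, _Locus] = {}
    shared_uniprot_ids: set[str] = set()

    def new_locus(rec: GeneRecord) -> _Locus:
        loc = _Locus()
        loc.records[rec.source] = rec
        loci.append(loc)
        by_gene_id[rec.gene_id] = loc
        for sym in rec.symbols:
            by_symbol.setdefault(sym, []).append(loc)
        return loc

    def join(loc: _Locus, rec: GeneRecord, how: str) -> None:
        if rec.source == UNIPROT and UNIPROT in loc.records:
            loc.extra_uniprot.append(rec)
            log.append(f"extra-uniprot {rec.gene_id} at locus of {sorted(loc.records.values(), key=lambda r: r.gene_id)[0].gene_id} ({how})")
        else:
            loc.records[rec.source] = rec
        by_gene_id.setdefault(rec.gene_id, loc)
        for sym in rec.symbols:
            lst = by_symbol.setdefault(sym, [])
            if loc not in lst:
                lst.append(loc)

    # --- pass 1: GENCODE records seed loci -------------------------------
    for rec in _sorted_records(gencode):
        new_locus(rec)

    # --- pass 2: symbol matching for RefSeq then UniProt -----------------
    pending: list[GeneRecord] = []
    if policy.use_symbols:
        for rec in _sorted_records(refseq):
            cands = [l for l in by_symbol.get(rec.hgnc_symbol or "", []) if REFSEQ not in l.records]
            if cands:
                join(cands[0], rec, "symbol")
            elif rec.hgnc_symbol and by_symbol.get(rec.hgnc_symbol):
                # ERCC6-style: a second same-symbol gene stays without a match
                ambiguities.append(
                    f"symbol {rec.hgnc_symbol}: {rec.gene_id} left unmatched "
                    f"(locus already has a {REFSEQ} member)")
                new_locus(rec)
            else:
                pending.append(rec)
        for rec in _sorted_records(uniprot):
            hits = []
            for sym in rec.symbols:
                for l in by_symbol.get(sym, []):
                    if l not in hits:
                        hits.append(l)
            joinable = [l for l in hits if UNIPROT not in l.records]
            if len(joinable) > 1:
                # one protein entry shared by a gene family: annotate every locus
                for l in joinable:
                    join(l, rec, "symbol-shared")
                shared_uniprot_ids.add(rec.gene_id)
                log.append(f"uniprot entry {rec.gene_id} shared across {len(joinable)} loci")
            elif joinable:
                join(joinable[0], rec, "symbol")
            elif hits:
                # all symbol-matched loci already hold an entry: record as extra
                join(hits[0], rec, "symbol-extra")
            else:
                pending.append(rec)
    else:
        pending.extend(_sorted_records(refseq))
        pending.extend(_sorted_records(uniprot))

    # --- pass 3: cross-reference matching --------------------------------
    still_pending: list[GeneRecord] = []
    if policy.use_cross_refs:
        # reverse index: accession mentioned by a locus member -> locus
        xref_target: dict[str, _Locus] = {}
        for loc in loci:
            for r in loc.records.values():
                for accs in r.cross_refs.values():
                    for a in accs:
                        xref_target.setdefault(a, loc)
        for rec in pending:
            loc = None
            for accs in rec.cross_refs.values():
                for a in accs:
                    if a in by_gene_id:
                        loc = by_gene_id[a]
                        break
                if loc:
                    break
            if loc is None:
                loc = xref_target.get(rec.gene_id)
            if loc is not None and (rec.source == UNIPROT or rec.source not in loc.records):
                join(loc, rec, "cross-ref")
            else:
                still_pending.append(rec)
        pending = still_pending

    # --- pass 4: reciprocal coordinate overlap ---------------------------
    if policy.use_overlap:
        tree: dict[tuple[str, str], IntervalTree] = {}
        span_of: dict[int, tuple[int, int]] = {}

        def index_locus(loc: _Locus):
            r = None
            for s in (GENCODE, REFSEQ, UNIPROT):
                rr = loc.records.get(s)
                if rr is not None and rr.has_coordinates:
                    r = rr
                    break
            if r is None:
                return
            key = (r.chrom, r.strand or "+")
            tree.setdefault(key, IntervalTree())
            tree[key].addi(r.start, r.end + 1, loc)
            span_of[id(loc)] = (r.start, r.end)

        for loc in loci:
            index_locus(loc)

        still_pending = []
        for rec in pending:
            # a record carrying a symbol that matched nothing is evidence of a
            # distinct gene: coordinate overlap is only trusted for nameless
            # records (overlapping genes with different symbols stay separate)
            if not rec.has_coordinates or rec.symbols:
                still_pending.append(rec)
                continue
            best = None
            key = (rec.chrom, rec.strand or "+")
            for iv in tree.get(key, IntervalTree()).overlap(rec.start, rec.end + 1):
                loc = iv.data
                if rec.source != UNIPROT and rec.source in loc.records:
                    continue
                ls, le = span_of[id(loc)]
                ov = min(rec.end, le) - max(rec.start, ls) + 1
                shorter = min(rec.span_length, le - ls + 1)
                frac = ov / shorter if shorter else 0.0
                if frac >= policy.min_reciprocal_overlap:
                    cand = (frac, -(ls), loc)
                    if best is None or cand[:2] > best[:2]:
                        best = cand
            if best is not None:
                join(best[2], rec, "overlap")
            else:
                still_pending.append(rec)
        pending = still_pending

    # --- leftovers: collapse same-symbol leftovers, then single-member loci
    order = {GENCODE: 0, REFSEQ: 1, UNIPROT: 2}
    for rec in sorted(pending, key=lambda r: (order[r.source], r.gene_id)):
        joinable = []
        for sym in rec.symbols:
            for l in by_symbol.get(sym, []):
                if (rec.source == UNIPROT or rec.source not in l.records) and l not in joinable:
                    joinable.append(l)
        if len(joinable) > 1 and rec.source == UNIPROT:
            for l in joinable:
                join(l, rec, "symbol-shared")
            shared_uniprot_ids.add(rec.gene_id)
        elif joinable:
            join(joinable[0], rec, "symbol-leftover")
        else:
            new_locus(rec)

    merged = _finalise(loci, shared_uniprot_ids)
    return MergeResult(loci=merged, ambiguities=ambiguities, log=log)


def _finalise(loci: list[_Locus], shared_uniprot_ids: set[str]) -> list[MergedGene]:
    def sort_key(loc: _Locus):
        r = None
        for s in (GENCODE, REFSEQ, UNIPROT):
            rr = loc.records.get(s)
            if rr is not None and rr.has_coordinates:
                r = rr
                break
        min_id = min(x.gene_id for x in list(loc.records.values()) + loc.extra_uniprot)
        if r is None:
            return ("~", 0, 0, min_id)
        return (r.chrom, r.start, r.end, min_id)

    out: list[MergedGene] = []
    for i, loc in enumerate(sorted(loci, key=sort_key)):
        recs = loc.records
        symbol = None
        for s in (GENCODE, REFSEQ, UNIPROT):
            if s in recs and recs[s].hgnc_symbol:
                symbol = recs[s].hgnc_symbol
                break
        tags: set[str] = set()
        for r in recs.values():
            tags |= r.tags
        for r in loc.extra_uniprot:
            tags |= r.tags
        coord = None
        for s in (GENCODE, REFSEQ, UNIPROT):
            if s in recs and recs[s].has_coordinates:
                coord = recs[s]
                break
        entries = ([recs[UNIPROT]] if UNIPROT in recs else []) + loc.extra_uniprot
        out.append(MergedGene(
            locus_id=f"LOC{i:06d}",
            symbol=symbol,
            members={s: r.gene_id for s, r in recs.items()},
            records=dict(recs),
            tags=tags,
            chrom=coord.chrom if coord else None,
            start=coord.start if coord else None,
            end=coord.end if coord else None,
            strand=coord.strand if coord else None,
            uniprot_entries=entries,
            shared_uniprot=UNIPROT in recs and recs[UNIPROT].gene_id in shared_uniprot_ids,
        ))
    return out


def dedup_uniprot(loci: list[MergedGene], uniprot: Catalogue | None = None) -> tuple[list[MergedGene], list[str]]:
    """Resolve loci holding several UniProt entries to one canonical entry each.

    The canonical entry is the one with the most cross-references, then the
    longest protein, then the lexicographically smallest accession.  Entries
    shared across loci (one protein, several genes) are left shared: every
    such locus keeps its UniProt membership.
    """
    log: list[str] = []
    for loc in loci:
        if len(loc.uniprot_entries) <= 1:
            continue
        def rank(r: GeneRecord):
            n_xref = sum(len(v) for v in r.cross_refs.values())
            plen = r.protein_length or 0
            return (-n_xref, -plen, r.gene_id)
        best = sorted(loc.uniprot_entries, key=rank)[0]
        dropped = [r.gene_id for r in loc.uniprot_entries if r is not best]
        loc.records[UNIPROT] = best
        loc.members[UNIPROT] = best.gene_id
        loc.uniprot_entries = [best]
        log.append(f"{loc.locus_id} ({loc.symbol}): kept {best.gene_id}, merged {','.join(dropped)}")
    return loci, log


def apply_exclusions(loci: list[MergedGene], drop: set[str]) -> tuple[list[MergedGene], dict[str, int]]:
    """Remove loci whose tags intersect ``drop``; report removal counts per tag."""
    allowed = {TAG_SCAFFOLD, "readthrough", "ig_tr_fragment"}
    unknown = set(drop) - allowed
    if unknown:
        raise ValueError(f"unknown exclusion tag(s): {sorted(unknown)}")
    counts = {t: 0 for t in sorted(drop)}
    kept = []
    for loc in loci:
        hit = loc.tags & drop
        if hit:
            for t in hit:
                counts[t] += 1
        else:
            kept.append(loc)
    return kept, counts


def compute_venn(loci: list[MergedGene]) -> VennCounts:
    cells = {c: 0 for c in VENN_CELLS}
    for loc in loci:
        cells[loc.venn_cell] += 1
    return VennCounts(cells)
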