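"""Naive brute-force reimplementations used as independent oracles.

Everything here is written as plain loops and conditionals over the raw
fixture inputs (records, side features, variant rows, peptide rows) plus the
generator's truth table for catalogue membership.  No interval trees, no
shared code with the package's classifiers.
"""

from __future__ import annotations

import re
from collections import Counter

from genecat.catalogue_io import GENCODE, REFSEQ, UNIPROT

ALL = (GENCODE, REFSEQ, UNIPROT)
LETTER = {GENCODE: "G", REFSEQ: "R", UNIPROT: "U"}


def _overlap(a_s, a_e, b_s, b_e):
    return a_s <= b_e and b_s <= a_e


def oracle_venn(truth_genes) -> dict:
    return dict(Counter(g.cell for g in truth_genes))


def _ig_symbol(sym):
    if not sym:
        return False
    return bool(re.match(r"^(IG[HKL][VDJC]|TR[ABGD][VDJC])", sym))


def _pseudo_suffix(sym):
    # parent-gene stem (>= 3 chars, or ending in a digit) plus P / P<digits>
    m = re.fullmatch(r"([A-Z][A-Z0-9.-]*)P([0-9]*)", sym)
    if not m:
        return False
    stem, digits = m.group(1), m.group(2)
    return stem[-1].isdigit() or (len(stem) >= 3 and digits != "")


def _name_category(sym):
    if not sym:
        return None
    if _pseudo_suffix(sym):
        return "pseudogene"
    if re.search(r"-AS[0-9]*$", sym):
        return "antisense"
    if sym.startswith("LINC"):
        return "lncRNA"
    if sym.startswith("ERV") or sym.startswith("HERV") or sym.startswith("LTR"):
        return "retroviral"
    return None


def oracle_classify(bundle) -> dict:
    """symbol -> category for every non-intersection truth gene."""
    cats = {}
    side_by_source = {s: list(bundle.catalogues[s].side_records) for s in ALL}
    coding_by_source = {s: list(bundle.catalogues[s].records) for s in ALL}

    for g in bundle.truth_genes:
        if g.cell == "GRU":
            continue
        non = [s for s in ALL if LETTER[s] not in g.cell]
        own = set(g.ids.values())

        sides = [r for s in non for r in side_by_source[s]]
        coding = [r for s in non if s != UNIPROT for r in coding_by_source[s]]
        if UNIPROT in non:
            coding += [r for s in (GENCODE, REFSEQ) for r in coding_by_source[s]]
        coding = [r for r in coding if r.gene_id not in own and r.has_coordinates]
        seen = set()
        coding = [r for r in coding
                  if not (r.gene_id in seen or seen.add(r.gene_id))]

        tags = set()
        for s in ALL:
            for r in coding_by_source[s]:
                if r.gene_id in own:
                    tags |= r.tags
        has_coords = g.chrom is not None

        def side_hits(pred, exonwise=False, same_strand=None):
            for r in sides:
                if not r.has_coordinates or not pred(r.status.lower()):
                    continue
                if same_strand is not None and r.strand and g.strand:
                    if (r.strand == g.strand) != same_strand:
                        continue
                ivs = r.exons if (exonwise and r.exons) else [(r.start, r.end)]
                g_ivs = g.exons if (exonwise and g.exons) else [(g.start, g.end)]
                for s1, e1 in ivs:
                    for s2, e2 in g_ivs:
                        if _overlap(s1, e1, s2, e2):
                            return True
            return False

        cat = None
        if "readthrough" in tags:
            cat = "readthrough"
        elif "ig_tr_fragment" in tags or _ig_symbol(g.symbol):
            cat = "ig_tr"
        elif has_coords and side_hits(lambda st: st == "other"):
            cat = "ig_tr"
        elif has_coords and side_hits(lambda st: "pseudogene" in st):
            cat = "pseudogene"
        elif has_coords and side_hits(lambda st: "retro" in st, exonwise=True,
                                      same_strand=True):
            cat = "retroviral"
        elif has_coords and side_hits(lambda st: "lncrna" in st, exonwise=True,
                                      same_strand=True):
            cat = "lncRNA"
        if cat is None and has_coords:
            for r in coding:
                if r.strand == g.strand or not r.strand or not g.strand:
                    continue
                for us, ue, _ in r.utr_intervals:
                    if _overlap(us, ue, g.start - 1000, g.end + 1000):
                        cat = "antisense"
                        break
                if cat:
                    break
        if cat is None and has_coords and side_hits(
                lambda st: "tec" in st or "artefact" in st):
            cat = "artefact_tec"
        if cat is None and has_coords:
            for r in coding:
                if r.strand and g.strand and r.strand != g.strand:
                    continue
                for us, ue, _ in r.utr_intervals:
                    if _overlap(us, ue, g.start, g.end):
                        cat = "utr_orf"
                        break
                if cat:
                    break
        if cat is None and has_coords:
            for r in coding:
                exons = sorted(r.exons)
                for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                    if e1 + 1 <= g.start and g.end <= s2 - 1:
                        cat = "intronic"
                        break
                if cat:
                    break
        if cat is None:
            cat = _name_category(g.symbol)
        if cat is None:
            cat = "intergenic" if has_coords else "no_coordinates"
        cats[g.symbol] = cat
    return cats


def oracle_filter(variants_df, principal_map) -> set:
    """variant_ids surviving all filters, each filter an independent predicate."""
    keep = set()
    for row in variants_df.to_dict("records"):
        terms = str(row["consequence_terms"]).split("&")
        af = row["max_af"]
        try:
            af = float(af)
        except (TypeError, ValueError):
            af = None
        if af != af:  # NaN
            af = None
        ok = (
            principal_map.get(str(row["gene_id"])) == str(row["transcript_id"])
            and str(row["alt_allele"]) in ("A", "C", "G", "T")
            and "frameshift_variant" not in terms
            and any(t in ("start_lost", "synonymous_variant", "missense_variant",
                          "stop_gained", "stop_lost", "splice_donor_variant",
                          "splice_acceptor_variant") for t in terms)
            and af is not None and af > 0.0
        )
        if ok:
            keep.add(str(row["variant_id"]))
    return keep


def _word_pseudogene(text):
    if not text:
        return False
    tokens = re.split(r"[^A-Za-z]+", text.lower())
    return "pseudogene" in tokens or "pseudogenes" in tokens


def _noncoding_name(sym):
    if not sym:
        return False
    return (sym.startswith("LINC")
            or bool(re.search(r"-AS[0-9]*$", sym))
            or _pseudo_suffix(sym))


def oracle_features(bundle) -> dict:
    """symbol -> frozenset of applicable features, from raw inputs."""
    ev_by_gene = {str(r["gene_id"]): r
                  for r in bundle.evidence.to_dict("records")}
    recs = {}
    for s in ALL:
        for r in bundle.catalogues[s].records:
            recs[r.gene_id] = r

    out = {}
    for g in bundle.truth_genes:
        cell = g.cell
        applicable = set()
        if "G" in cell:
            applicable |= {"recent_gene_age", "no_protein_features",
                           "phylocsf_max", "readthrough_gene"}
        if "R" in cell:
            applicable.add("readthrough_gene")
        if "U" in cell:
            applicable |= {"caution_note", "uncertain_evidence"}
        applicable |= {"described_pseudogene", "non_coding_name"}

        feats = set()
        grow = ev_by_gene.get(g.ids.get(GENCODE, ""))
        if grow is not None:
            if grow["gene_age_depth"] in ("homininae", "hominidae", "catarrhini"):
                feats.add("recent_gene_age")
            scores = []
            for part in str(grow["phylocsf_exons"]).split(";"):
                if part:
                    sc, ln = part.split(":")
                    if int(ln) >= 10:
                        scores.append(float(sc))
            pmax = max(scores) if scores else None
            if pmax is not None and pmax <= -14:
                feats.add("phylocsf_max")
            booleans = [grow["has_functional_residues"], grow["has_structure_homology"],
                        grow["has_domain"], grow["has_conservation"],
                        grow["has_tm_helix"]]
            if not any(int(b) for b in booleans) and (pmax is None or pmax < 0):
                feats.add("no_protein_features")
        tags = set()
        desc = None
        up = recs.get(g.ids.get(UNIPROT, ""))
        rs = recs.get(g.ids.get(REFSEQ, ""))
        gc = recs.get(g.ids.get(GENCODE, ""))
        for r in (gc, rs, up):
            if r is not None:
                tags |= r.tags
        for r in (up, rs, gc):
            if r is not None and r.description and desc is None:
                desc = r.description
        if "readthrough" in tags:
            feats.add("readthrough_gene")
        if up is not None and up.caution_notes:
            feats.add("caution_note")
        if up is not None and up.evidence_code == "uncertain":
            feats.add("uncertain_evidence")
        if _word_pseudogene(desc):
            feats.add("described_pseudogene")
        if _noncoding_name(g.symbol):
            feats.add("non_coding_name")
        out[g.symbol] = frozenset(feats & applicable)
    return out


def oracle_supported(bundle) -> set:
    """gene ids with >= 2 distinct qualifying peptides."""
    seqs = {}
    for p in bundle.peptides:
        if p.n_observations < 2 or len(p.mapped_genes) != 1:
            continue
        if p.preceding_residue not in ("K", "R", "-"):
            continue
        if p.sequence[-1] not in ("K", "R") and p.following_residue != "-":
            continue
        (gene,) = p.mapped_genes
        seqs.setdefault(gene, set()).add(p.sequence)
    return {g for g, s in seqs.items() if len(s) >= 2}
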