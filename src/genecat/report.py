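"""End-to-end pipeline and study-style summary tables.

``run_pipeline`` executes the stages in order — read, merge, dedup,
exclusions, Venn, discrepancy classification, variant filtering and NS/Syn
ratios, feature flagging, peptide support — and ``summarize`` assembles the
cross-consistent summary tables: the three-set Venn accounting, the
per-category discrepancy table, the feature-count/peptide-support table and
the per-subset flagged percentages.

All percentages are recomputed from the adjacent counts and rounded half-up
to one decimal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import pandas as pd

from .catalogue_io import (
    GENCODE, REFSEQ, UNIPROT, SOURCES, TAG_READTHROUGH,
    read_gencode_gtf, read_refseq_table, read_uniprot_table,
)
from .merge import (
    MergedGene, VennCounts, MatchPolicy, match_catalogues, dedup_uniprot,
    apply_exclusions, compute_venn,
)
from .discrepancy import ClassificationConfig, classify_all
from .variant_selection import (
    VariantFilterConfig, filter_variants, ns_syn_ratio, read_variant_table,
)
from .noncoding_features import (
    FEATURES, FeatureAssignment, FeatureCriterionConfig, FeatureEvidence,
    classify_symbol, evaluate_features, feature_applicability,
    qualify_feature_by_nssyn,
)
from .peptide_support import PeptideConfig, gene_peptide_support, read_peptide_table


def percentage(numerator: int, denominator: int) -> float | None:
    """100 * numerator / denominator, half-up to one decimal; None when empty."""
    if denominator == 0:
        return None
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")


@dataclass
class RunConfig:
    """Input locations (or an in-memory fixture) plus all stage settings."""

    gencode_gtf: str | None = None
    refseq_tsv: str | None = None
    uniprot_tsv: str | None = None
    variants_tsv: str | None = None
    evidence_tsv: str | None = None
    peptides_tsv: str | None = None
    exclusions: tuple[str, ...] = ("scaffold_only",)
    match_policy: MatchPolicy = field(default_factory=MatchPolicy)
    classify: ClassificationConfig = field(default_factory=ClassificationConfig)
    variants: VariantFilterConfig = field(default_factory=VariantFilterConfig)
    features: FeatureCriterionConfig = field(default_factory=FeatureCriterionConfig)
    peptides: PeptideConfig = field(default_factory=PeptideConfig)
    #: gene subsets for which NS/Syn ratios are reported
    nssyn_subsets: tuple[str, ...] = ("refseq_outside", "peptide_supported")
    out_dir: str | None = None
    seed: int = 0


@dataclass
class SummaryTables:
    venn: VennCounts
    venn_post_exclusion: VennCounts
    exclusion_counts: dict[str, int]
    categories: pd.DataFrame
    category_counts: dict[str, int]
    features: pd.DataFrame
    flagged_per_source: dict[str, tuple[int, int]]
    subsets: pd.DataFrame
    nssyn: dict[str, dict]
    support_unflagged_gencode: tuple[int, int]
    manifest: dict

    def consistency_check(self) -> None:
        n_flagged = int(self.subsets.set_index("subset").loc["all", "flagged"])
        if (self.features["n_genes"] > n_flagged + self.features["n_genes"].max()).any():
            raise PipelineError("summarize", "feature counts exceed locus counts")
        bad = self.features[self.features["n_supported"] > self.features["n_genes"]]
        if len(bad):
            raise PipelineError(
                "summarize", f"supported > tagged for {list(bad['feature'])}")
        for _, row in self.subsets.iterrows():
            if row["flagged"] > row["total"]:
                raise PipelineError(
                    "summarize", f"subset {row['subset']}: numerator > denominator")


def locus_principal_gene(loc: MergedGene) -> str | None:
    """The member gene id on which variants are keyed (GENCODE, else RefSeq)."""
    for s in (GENCODE, REFSEQ):
        if s in loc.members:
            return loc.members[s]
    return None


def build_principal_map(loci: list[MergedGene]) -> dict[str, str]:
    out: dict[str, str] = {}
    for loc in loci:
        for s in (GENCODE, REFSEQ):
            rec = loc.records.get(s)
            if rec is not None and rec.principal_transcript_id:
                out[rec.gene_id] = rec.principal_transcript_id
    return out


def select_locus_subset(loci: list[MergedGene], selector: str,
                        supported: dict[str, bool] | None = None) -> list[MergedGene]:
    supported = supported or {}
    if selector == "all":
        picked = loci
    elif selector == "intersection":
        picked = [l for l in loci if l.venn_cell == "GRU"]
    elif selector == "outside":
        picked = [l for l in loci if l.venn_cell != "GRU"]
    elif selector == "refseq_outside":
        picked = [l for l in loci if l.venn_cell != "GRU" and REFSEQ in l.members]
    elif selector == "peptide_supported":
        picked = [l for l in loci if supported.get(l.locus_id, False)]
    elif selector.startswith("cell:"):
        picked = [l for l in loci if l.venn_cell == selector[5:]]
    else:
        raise PipelineError("nssyn", f"unknown subset selector {selector!r}")
    return picked


def parse_evidence_table(df: pd.DataFrame) -> dict[str, dict]:
    out = {}
    for row in df.itertuples(index=False):
        exons = []
        for part in str(row.phylocsf_exons).split(";"):
            if part and part != "nan":
                score, codons = part.split(":")
                exons.append((float(score), int(codons)))
        out[str(row.gene_id)] = {
            "phylocsf_exons": exons,
            "gene_age_depth": row.gene_age_depth or None,
            "booleans": (bool(int(row.has_functional_residues)),
                         bool(int(row.has_structure_homology)),
                         bool(int(row.has_domain)),
                         bool(int(row.has_conservation)),
                         bool(int(row.has_tm_helix))),
        }
    return out


def assemble_evidence(loc: MergedGene, tool_evidence: dict[str, dict],
                      cfg: FeatureCriterionConfig) -> FeatureEvidence:
    """Gather one locus's feature evidence from the tool table and its records."""
    ev = FeatureEvidence(gene_id=loc.locus_id)
    for s in (GENCODE, REFSEQ):
        gid = loc.members.get(s)
        if gid in tool_evidence:
            t = tool_evidence[gid]
            ev.phylocsf_exons = t["phylocsf_exons"]
            ev.gene_age_depth = t["gene_age_depth"]
            (ev.has_functional_residues, ev.has_structure_homology,
             ev.has_domain, ev.has_conservation, ev.has_tm_helix) = t["booleans"]
            break
    up = loc.records.get(UNIPROT)
    if up is not None:
        ev.uniprot_caution = set(up.caution_notes)
        ev.uniprot_evidence = up.evidence_code
    descriptions = [r.description for s in (UNIPROT, REFSEQ, GENCODE)
                    if (r := loc.records.get(s)) is not None and r.description]
    ev.description_text = descriptions[0] if descriptions else None
    ev.hgnc_name_class = (classify_symbol(loc.symbol, cfg.noncoding_name_patterns)
                          if loc.symbol else None)
    ev.readthrough = TAG_READTHROUGH in loc.tags
    return ev


def flag_all(loci: list[MergedGene], evidence_df: pd.DataFrame,
             cfg: FeatureCriterionConfig) -> dict[str, FeatureAssignment]:
    tool = parse_evidence_table(evidence_df)
    out = {}
    for loc in loci:
        applicable = feature_applicability(loc.sources, cfg)
        ev = assemble_evidence(loc, tool, cfg)
        out[loc.locus_id] = evaluate_features(ev, cfg, applicable)
    return out


def summarize(
    loci: list[MergedGene],
    venn: VennCounts,
    venn_post: VennCounts,
    exclusion_counts: dict[str, int],
    categories: pd.DataFrame,
    assignments: dict[str, FeatureAssignment],
    locus_supported: dict[str, bool],
    nssyn: dict[str, dict],
    manifest: dict,
) -> SummaryTables:
    locus_ids = {l.locus_id for l in loci}
    stray = set(assignments) - locus_ids
    if stray:
        raise PipelineError("summarize",
                            f"assignments for unknown loci: {sorted(stray)[:5]}")

    cat_counts: dict[str, int] = {}
    if len(categories):
        cat_counts = categories["category"].value_counts().to_dict()

    flagged = {lid for lid, a in assignments.items() if a.flagged}

    # Table-1 analogue: per-feature GENCODE gene counts and peptide support
    rows = []
    gencode_loci = [l for l in loci if GENCODE in l.members]
    for f in FEATURES:
        tagged = [l for l in gencode_loci
                  if f in assignments[l.locus_id].features]
        n_sup = sum(1 for l in tagged if locus_supported.get(l.locus_id, False))
        rows.append({"feature": f, "n_genes": len(tagged), "n_supported": n_sup})
    features_df = pd.DataFrame(rows, columns=["feature", "n_genes", "n_supported"])

    flagged_per_source = {}
    for s in SOURCES:
        members = [l for l in loci if s in l.members]
        flagged_per_source[s] = (sum(1 for l in members if l.locus_id in flagged),
                                 len(members))

    def subset_row(name, picked):
        n_flag = sum(1 for l in picked if l.locus_id in flagged)
        return {"subset": name, "flagged": n_flag, "total": len(picked),
                "pct": percentage(n_flag, len(picked))}

    inter = [l for l in loci if l.venn_cell == "GRU"]
    outside = [l for l in loci if l.venn_cell != "GRU"]
    sub_rows = [
        subset_row("all", loci),
        subset_row("intersection", inter),
        subset_row("outside_intersection", outside),
    ]
    for s, label in ((GENCODE, "gencode"), (REFSEQ, "refseq"), (UNIPROT, "uniprot")):
        sub_rows.append(subset_row(f"{label}_all", [l for l in loci if s in l.members]))
        sub_rows.append(subset_row(f"{label}_outside",
                                   [l for l in outside if s in l.members]))
    subsets_df = pd.DataFrame(sub_rows, columns=["subset", "flagged", "total", "pct"])

    unflagged_gencode = [l for l in gencode_loci if l.locus_id not in flagged]
    n_sup_unflagged = sum(1 for l in unflagged_gencode
                          if locus_supported.get(l.locus_id, False))

    tables = SummaryTables(
        venn=venn, venn_post_exclusion=venn_post,
        exclusion_counts=exclusion_counts,
        categories=categories, category_counts=cat_counts,
        features=features_df, flagged_per_source=flagged_per_source,
        subsets=subsets_df, nssyn=nssyn,
        support_unflagged_gencode=(n_sup_unflagged, len(unflagged_gencode)),
        manifest=manifest,
    )
    tables.consistency_check()
    return tables


@dataclass
class PipelineResult:
    tables: SummaryTables
    loci: list[MergedGene]
    assignments: dict[str, FeatureAssignment]
    locus_supported: dict[str, bool]
    retained_variants: list
    drop_counts: dict[str, int]
    ambiguities: list[str]


def run_pipeline(config: RunConfig, bundle=None) -> PipelineResult:
    """Execute all stages on a fixture bundle or on the configured input files."""
    manifest: dict = {"config": _manifest_config(config), "stages": {}}

    # ---- read -------------------------------------------------------------
    try:
        if bundle is not None:
            catalogues = bundle.catalogues
            variants_df = bundle.variants
            evidence_df = bundle.evidence
            peptides = bundle.peptides
        else:
            catalogues = {
                GENCODE: read_gencode_gtf(config.gencode_gtf),
                REFSEQ: read_refseq_table(config.refseq_tsv),
                UNIPROT: read_uniprot_table(config.uniprot_tsv),
            }
            variants_df = read_variant_table(config.variants_tsv)
            evidence_df = pd.read_csv(config.evidence_tsv, sep="\t",
                                      keep_default_na=False)
            peptides = read_peptide_table(config.peptides_tsv)
    except Exception as e:  # noqa: BLE001 - stage attribution
        raise PipelineError("read", str(e)) from e
    for s in SOURCES:
        manifest["stages"][f"read_{s.lower()}"] = len(catalogues[s].records)

    # ---- merge ------------------------------------------------------------
    result = match_catalogues(catalogues[GENCODE], catalogues[REFSEQ],
                              catalogues[UNIPROT], config.match_policy)
    loci, dedup_log = dedup_uniprot(result.loci, catalogues[UNIPROT])
    loci, exclusion_counts = apply_exclusions(loci, set(config.exclusions))
    venn = compute_venn(loci)
    manifest["stages"]["merged_loci"] = len(loci)
    manifest["stages"]["exclusions"] = exclusion_counts

    # a second exclusion view without readthrough genes / IG-TR fragments
    loci_strict, strict_counts = apply_exclusions(
        loci, {"readthrough", "ig_tr_fragment"})
    venn_post = compute_venn(loci_strict)

    # ---- classify ----------------------------------------------------------
    categories = classify_all(loci, catalogues, config.classify)
    manifest["stages"]["classified"] = len(categories)

    # ---- variants ----------------------------------------------------------
    principal_map = build_principal_map(loci)
    retained, drops = filter_variants(variants_df, config.variants, principal_map)
    manifest["stages"]["variants_retained"] = len(retained)
    manifest["stages"]["variant_drops"] = drops

    # ---- features ----------------------------------------------------------
    assignments = flag_all(loci, evidence_df, config.features)
    manifest["stages"]["flagged"] = sum(1 for a in assignments.values() if a.flagged)

    # ---- peptides ----------------------------------------------------------
    support = gene_peptide_support(peptides, config.peptides.support_threshold,
                                   config.peptides)
    supported_genes = {s.gene_id for s in support if s.supported}
    locus_supported = {
        l.locus_id: any(g in supported_genes for g in l.members.values())
        for l in loci}
    manifest["stages"]["supported_loci"] = sum(locus_supported.values())

    # ---- NS/Syn per subset --------------------------------------------------
    nssyn: dict[str, dict] = {}
    for selector in config.nssyn_subsets:
        picked = select_locus_subset(loci, selector, locus_supported)
        ids = {locus_principal_gene(l) for l in picked} - {None}
        counts = ns_syn_ratio(retained, ids, config.variants, selector)
        nssyn[selector] = {
            **counts.to_dict(),
            "qualifies": qualify_feature_by_nssyn(
                counts.rare_ratio, counts.common_ratio, config.features),
        }

    tables = summarize(loci, venn, venn_post, exclusion_counts, categories,
                       assignments, locus_supported, nssyn, manifest)
    out = PipelineResult(tables=tables, loci=loci, assignments=assignments,
                         locus_supported=locus_supported,
                         retained_variants=retained, drop_counts=drops,
                         ambiguities=result.ambiguities)
    if config.out_dir:
        write_outputs(out, Path(config.out_dir))
    return out


def _manifest_config(config: RunConfig) -> dict:
    d = asdict(config)
    d.pop("out_dir", None)  # a location, not a setting
    return d


def write_outputs(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    t = result.tables

    def dump_json(obj, name):
        with open(out_dir / name, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True, default=str)
            fh.write("\n")

    def dump_tsv(df: pd.DataFrame, name: str):
        with open(out_dir / name, "w", encoding="utf-8", newline="\n") as fh:
            df.to_csv(fh, sep="\t", index=False, lineterminator="\n")

    dump_json({"venn": t.venn.to_dict(),
               "venn_without_readthrough_igtr": t.venn_post_exclusion.to_dict(),
               "exclusions": t.exclusion_counts}, "venn.json")
    loci_rows = [{
        "locus_id": l.locus_id, "symbol": l.symbol or "",
        "venn_cell": l.venn_cell,
        "gencode_id": l.members.get(GENCODE, ""),
        "refseq_id": l.members.get(REFSEQ, ""),
        "uniprot_id": l.members.get(UNIPROT, ""),
        "chrom": l.chrom or "", "start": l.start or "", "end": l.end or "",
        "strand": l.strand or "", "tags": ";".join(sorted(l.tags)),
        "flagged": int(result.assignments[l.locus_id].flagged),
        "features": ";".join(sorted(result.assignments[l.locus_id].features)),
        "supported": int(result.locus_supported.get(l.locus_id, False)),
    } for l in result.loci]
    dump_tsv(pd.DataFrame(loci_rows), "loci.tsv")
    dump_tsv(t.categories, "categories.tsv")
    dump_tsv(t.features, "feature_counts.tsv")
    dump_tsv(t.subsets, "subset_percentages.tsv")
    dump_json(t.nssyn, "nssyn.json")
    dump_json({"variant_drops": result.drop_counts,
               "ambiguities": result.ambiguities}, "filter_log.json")
    dump_json(t.manifest, "manifest.json")
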