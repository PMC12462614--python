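"""Per-variant consequence filtering and NS/Syn ratios.

A VEP-style tab-separated variant table (columns ``variant_id``, ``gene_id``,
``transcript_id``, ``alt_allele``, ``consequence_terms`` — ``&``-joined,
``max_af``) is filtered down to single-base variants on each gene's principal
transcript whose consequence is one of the seven retained classes.
``splice_region_variant`` never counts on its own but rides along with an
accompanying retained class; frameshift variants and variants with a missing
or zero maximum allele frequency are removed.

Variants are then split at maxAF 0.005 into rare and common strata (rare
means below the threshold by default; the boundary value itself is common)
and NS/Syn ratios — missense over synonymous counts — are computed for
arbitrary gene subsets.  Subsets under purifying selection show a depressed
common-stratum ratio; subsets whose ratio stays high in both strata behave
like non-coding sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

VALID_ALLELES = frozenset("ACGT")

#: VEP consequence term -> effect class, for the retained classes
CONSEQUENCE_WHITELIST = {
    "start_lost": "start_lost",
    "synonymous_variant": "synonymous",
    "missense_variant": "missense",
    "stop_gained": "stop_gained",
    "stop_lost": "stop_lost",
    "splice_donor_variant": "splice_donor",
    "splice_acceptor_variant": "splice_acceptor",
}

#: most-severe-first order used when a row carries several retained terms
SEVERITY_ORDER = (
    "stop_gained", "stop_lost", "start_lost", "splice_donor",
    "splice_acceptor", "missense", "synonymous",
)

FRAMESHIFT_TERM = "frameshift_variant"
SPLICE_REGION_TERM = "splice_region_variant"

VARIANT_COLUMNS = ("variant_id", "gene_id", "transcript_id", "alt_allele",
                   "consequence_terms", "max_af")


@dataclass
class VariantRecord:
    variant_id: str
    gene_id: str
    transcript_id: str
    alt_allele: str
    consequence_terms: tuple[str, ...]
    max_af: float | None
    effect_class: str | None = None


@dataclass
class VariantFilterConfig:
    rare_common_threshold: float = 0.005
    valid_alleles: frozenset = VALID_ALLELES
    consequence_whitelist: Mapping[str, str] = field(
        default_factory=lambda: dict(CONSEQUENCE_WHITELIST))
    splice_region_rides_along: bool = True
    exclude_frameshift: bool = True
    #: 'below_threshold' (default): rare iff maxAF < threshold, boundary common.
    #: 'above_threshold': the literal reading — rare iff maxAF > threshold.
    rare_definition: str = "below_threshold"

    def __post_init__(self):
        if not (0.0 < self.rare_common_threshold < 1.0):
            raise ValueError("rare_common_threshold must be in (0, 1)")
        if self.rare_definition not in ("below_threshold", "above_threshold"):
            raise ValueError("rare_definition must be below_threshold or above_threshold")

    def is_rare(self, max_af: float) -> bool:
        if self.rare_definition == "below_threshold":
            return max_af < self.rare_common_threshold
        return max_af > self.rare_common_threshold


@dataclass
class NsSynCounts:
    """Missense (NS) and synonymous (Syn) tallies for one gene subset."""

    subset_label: str
    rare_ns: int = 0
    rare_syn: int = 0
    common_ns: int = 0
    common_syn: int = 0

    @property
    def rare_ratio(self) -> float | None:
        return self.rare_ns / self.rare_syn if self.rare_syn > 0 else None

    @property
    def common_ratio(self) -> float | None:
        return self.common_ns / self.common_syn if self.common_syn > 0 else None

    def to_dict(self) -> dict:
        return {
            "subset": self.subset_label,
            "rare_ns": self.rare_ns, "rare_syn": self.rare_syn,
            "common_ns": self.common_ns, "common_syn": self.common_syn,
            "rare_ratio": self.rare_ratio, "common_ratio": self.common_ratio,
        }


def resolve_effect_class(
    consequence_terms: Sequence[str],
    cfg: VariantFilterConfig | None = None,
) -> str | None:
    """Resolve a row's ordered VEP terms to one effect class, or None (excluded).

    A lone ``splice_region_variant`` is excluded; combined with a retained
    term it takes that term's class.  Several retained terms resolve to the
    most severe.
    """
    cfg = cfg or VariantFilterConfig()
    if not consequence_terms:
        raise ValueError("consequence_terms must be non-empty")
    classes = {cfg.consequence_whitelist[t] for t in consequence_terms
               if t in cfg.consequence_whitelist}
    if not classes:
        return None
    if SPLICE_REGION_TERM in consequence_terms and not cfg.splice_region_rides_along:
        return None
    for c in SEVERITY_ORDER:
        if c in classes:
            return c
    return None


# drop reasons, attributed in this fixed order (the retained set itself is
# the intersection of independent predicates, so it is order-independent)
DROP_REASONS = ("unknown_gene", "non_principal_transcript", "invalid_allele",
                "frameshift", "no_retained_consequence", "missing_max_af",
                "zero_max_af")


def filter_variants(
    rows: pd.DataFrame | Iterable[Mapping],
    cfg: VariantFilterConfig | None = None,
    principal_map: Mapping[str, str] | None = None,
) -> tuple[list[VariantRecord], dict[str, int]]:
    """Apply the variant filters; return retained records and per-reason drops."""
    cfg = cfg or VariantFilterConfig()
    principal_map = principal_map or {}
    if isinstance(rows, pd.DataFrame):
        rows = rows.to_dict("records")

    retained: list[VariantRecord] = []
    drops = {r: 0 for r in DROP_REASONS}
    for row in rows:
        gene = str(row["gene_id"])
        transcript = str(row["transcript_id"])
        terms = tuple(t for t in str(row["consequence_terms"]).split("&") if t)
        raw_af = row.get("max_af", None)
        max_af = None
        if raw_af is not None and str(raw_af) != "" and not pd.isna(raw_af):
            max_af = float(raw_af)

        if gene not in principal_map:
            drops["unknown_gene"] += 1
            continue
        if transcript != principal_map[gene]:
            drops["non_principal_transcript"] += 1
            continue
        allele = str(row["alt_allele"])
        if len(allele) != 1 or allele not in cfg.valid_alleles:
            drops["invalid_allele"] += 1
            continue
        if cfg.exclude_frameshift and FRAMESHIFT_TERM in terms:
            drops["frameshift"] += 1
            continue
        effect = resolve_effect_class(terms, cfg)
        if effect is None:
            drops["no_retained_consequence"] += 1
            continue
        if max_af is None:
            drops["missing_max_af"] += 1
            continue
        if max_af == 0.0:
            drops["zero_max_af"] += 1
            continue
        retained.append(VariantRecord(
            variant_id=str(row["variant_id"]), gene_id=gene,
            transcript_id=transcript, alt_allele=allele,
            consequence_terms=terms, max_af=max_af, effect_class=effect))
    return retained, drops


def split_rare_common(
    variants: Sequence[VariantRecord],
    cfg: VariantFilterConfig | None = None,
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Total partition of filtered variants into (rare, common) strata."""
    cfg = cfg or VariantFilterConfig()
    rare, common = [], []
    for v in variants:
        (rare if cfg.is_rare(v.max_af) else common).append(v)
    return rare, common


def ns_syn_ratio(
    variants: Sequence[VariantRecord],
    gene_subset: set[str] | frozenset[str],
    cfg: VariantFilterConfig | None = None,
    subset_label: str = "",
) -> NsSynCounts:
    """NS/Syn counts and ratios for a gene subset, per maxAF stratum.

    Only missense (NS) and synonymous (Syn) effect classes are counted.
    Ratios are undefined (None) when the synonymous count is zero.
    """
    cfg = cfg or VariantFilterConfig()
    out = NsSynCounts(subset_label=subset_label)
    for v in variants:
        if v.gene_id not in gene_subset:
            continue
        if v.effect_class == "missense":
            if cfg.is_rare(v.max_af):
                out.rare_ns += 1
            else:
                out.common_ns += 1
        elif v.effect_class == "synonymous":
            if cfg.is_rare(v.max_af):
                out.rare_syn += 1
            else:
                out.common_syn += 1
    return out


def read_variant_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "gene_id": str,
                                            "transcript_id": str,
                                            "alt_allele": str,
                                            "consequence_terms": str},
                     keep_default_na=False)
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        from .catalogue_io import SchemaError
        raise SchemaError(path, missing)
    df["max_af"] = pd.to_numeric(df["max_af"], errors="coerce")
    return df


def write_variant_table(df: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")
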