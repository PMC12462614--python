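"""Per-gene peptide support from a PeptideAtlas-style peptide table.

A peptide counts toward a gene only if it is fully tryptic (both termini
consistent with trypsin cleavage after K/R, or a protein terminus), has been
observed at least twice, and maps to exactly one gene.  A gene is supported
when at least two distinct qualifying peptide sequences map to it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
TERMINUS_MARKER = "-"

PEPTIDE_COLUMNS = ("sequence", "preceding_residue", "following_residue",
                   "n_observations", "mapped_genes")


@dataclass
class PeptideRecord:
    sequence: str
    preceding_residue: str   # single letter, or '-' for the protein N-terminus
    following_residue: str   # single letter, or '-' for the protein C-terminus
    n_observations: int
    mapped_genes: frozenset[str]

    def __post_init__(self):
        if not self.sequence or not set(self.sequence) <= AMINO_ACIDS:
            raise ValueError(f"invalid peptide sequence {self.sequence!r}")
        if self.n_observations < 0:
            raise ValueError("n_observations must be non-negative")
        self.mapped_genes = frozenset(self.mapped_genes)


@dataclass
class PeptideSupport:
    gene_id: str
    n_supporting_peptides: int
    supported: bool


@dataclass
class PeptideConfig:
    #: distinct qualifying peptides needed to call a gene supported
    support_threshold: int = 2
    #: observations needed for a peptide to qualify at all
    min_observations: int = 2
    #: strict mode adds the no-proline rule (trypsin does not cleave K/R-P)
    no_proline_rule: bool = False


def is_fully_tryptic(p: PeptideRecord, cfg: PeptideConfig | None = None) -> bool:
    """Both peptide termini consistent with tryptic cleavage or a protein end."""
    cfg = cfg or PeptideConfig()
    n_ok = p.preceding_residue in ("K", "R", TERMINUS_MARKER)
    c_ok = p.sequence[-1] in ("K", "R") or p.following_residue == TERMINUS_MARKER
    if cfg.no_proline_rule:
        if p.preceding_residue in ("K", "R") and p.sequence[0] == "P":
            n_ok = False
        if (p.sequence[-1] in ("K", "R") and p.following_residue == "P"):
            c_ok = False
    return n_ok and c_ok


def gene_peptide_support(
    peptides: Iterable[PeptideRecord],
    threshold: int = 2,
    cfg: PeptideConfig | None = None,
    genes: Sequence[str] | None = None,
) -> list[PeptideSupport]:
    """Distinct qualifying-peptide counts per gene.

    Peptides failing trypticity, observed fewer than twice, or mapping to
    more than one gene are discarded.  Duplicated rows of the same sequence
    for a gene count once.  ``genes`` optionally forces an entry (possibly
    zero-count) for every listed gene.
    """
    cfg = cfg or PeptideConfig()
    seqs_by_gene: dict[str, set[str]] = {g: set() for g in (genes or [])}
    for p in peptides:
        if p.n_observations < cfg.min_observations:
            continue
        if len(p.mapped_genes) != 1:
            continue
        if not is_fully_tryptic(p, cfg):
            continue
        (gene,) = p.mapped_genes
        seqs_by_gene.setdefault(gene, set()).add(p.sequence)
    return [
        PeptideSupport(gene_id=g, n_supporting_peptides=len(s),
                       supported=len(s) >= threshold)
        for g, s in sorted(seqs_by_gene.items())
    ]


def read_peptide_table(path: str | Path) -> list[PeptideRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in PEPTIDE_COLUMNS if c not in df.columns]
    if missing:
        from .catalogue_io import SchemaError
        raise SchemaError(path, missing)
    return [
        PeptideRecord(
            sequence=r.sequence,
            preceding_residue=r.preceding_residue,
            following_residue=r.following_residue,
            n_observations=int(r.n_observations),
            mapped_genes=frozenset(g for g in r.mapped_genes.split(";") if g),
        )
        for r in df.itertuples(index=False)
    ]


def write_peptide_table(peptides: Sequence[PeptideRecord], path: str | Path) -> None:
    rows = [{
        "sequence": p.sequence,
        "preceding_residue": p.preceding_residue,
        "following_residue": p.following_residue,
        "n_observations": p.n_observations,
        "mapped_genes": ";".join(sorted(p.mapped_genes)),
    } for p in peptides]
    df = pd.DataFrame(rows, columns=PEPTIDE_COLUMNS)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")
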