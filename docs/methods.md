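# Methods

## The reconciliation problem

Three groups curate the human protein-coding gene set: two
coordinate-based genome annotations (a GTF catalogue and a gene-table
catalogue, called the GENCODE and RefSeq roles here) and one protein-based
database of reviewed entries (the UniProtKB role).  Because the three
curate from different starting material, they disagree on the coding status
of a substantial minority of genes.  The pipeline merges the three sets
into loci, counts the seven cells of the membership Venn, explains each
disagreement, and asks — via population variation and proteomics evidence —
which of the disputed genes are plausibly not protein-coding at all.

## Merging and deduplication

Records are normalised to a common model (1-based inclusive coordinates
throughout; symbols trimmed but case-preserving; unknown biotypes passed
through verbatim).  The matching cascade is:

1. exact HGNC symbol;
2. cross-references, in either direction;
3. reciprocal coordinate overlap ≥ 50% of the shorter gene span, same
   chromosome and strand — but only for records that carry **no** symbol.
   A record whose symbol matched nothing is treated as evidence of a
   distinct gene; without this restriction, a small ORF annotated inside
   another gene's UTR would be silently merged into that gene.  The original
   analysis resolved such cases by manual curation; the cascade plus a
   reviewable ambiguity log is the deterministic replacement.

Leftover same-symbol records are collapsed across the remaining sources,
and anything still unmatched becomes a single-member locus.  When two
same-source records share a symbol (duplicated gene models at one locus),
the first joins and the second is kept as a separate locus and logged.

Protein entries are deduplicated per locus: the canonical entry has the
most cross-references, then the longest protein, then the smallest
accession (the protein-length column exists in the entry table for exactly
this tie-break).  One sequence-identical entry mapping to k loci stays
shared — each of the k loci counts as UniProt-annotated.  Entries placed
only on unplaced scaffolds are removed before Venn counting (the default
exclusion set); readthrough genes and IG/TR fragments can be excluded with
the same mechanism for the "strict" comparison view, which the pipeline
also reports.

## Discrepancy classification

Each locus outside the triple intersection is classified against the
annotation of the source(s) that do not call it coding, with precedence

    readthrough > ig_tr > pseudogene > retroviral > lncRNA > antisense >
    artefact_tec > utr_orf > intronic > intergenic > no_coordinates

— tag- and identity-based evidence beats overlap geometry, and specific
overlap beats positional defaults.  The geometric rules are strand-aware:

* pseudogene / artefact-TEC: any-strand overlap with such a feature's span;
* retroviral / lncRNA: same-strand exon overlap (structure-less side
  records count as single-exon spans);
* antisense: opposite strand of a coding gene, overlapping or within
  1 000 bp of its UTR (the distance is a configurable choice; no value is
  prescribed by the source analysis);
* UTR ORF: same-strand overlap with a coding gene's UTR;
* intronic: wholly contained in one intron.

Name-based fallbacks (pseudogene-suffixed symbols with a parent-gene stem
of ≥ 3 characters — so `TP53` is not misread — `-AS` suffixes, `LINC`
prefixes, `ERV`-style names) apply only when no geometric evidence exists.

The protein-entry catalogue has no genome annotation of its own, so when it
is among the non-annotating sources the classifier consults the coordinate
catalogues' coding-gene geometry (minus the locus's own members) for the
positional rules: whether an ORF sits in another gene's UTR or intron is a
property of the locus visible in any coordinate annotation.  This replaces
the per-record manual review of the original analysis and is switchable
(`ClassificationConfig.uniprot_neighbour_geometry`).

## NS/Syn purifying-selection screen

Variants are read from a VEP-style table and filtered to: the gene's
principal transcript only (rows on other transcripts are dropped, not
remapped); single-base alternate alleles A/C/G/T; consequence among
start_lost, synonymous, missense, stop_gained, stop_lost, splice_donor,
splice_acceptor (a lone splice_region variant is excluded; combined with a
retained term it counts as that term); frameshifts excluded; maxAF present
and non-zero.  Each retained variant counts once — variants, not carriers.

Strata: **rare = maxAF < 0.005**, boundary value common.  The source text
assigns "rare" to maxAF > 0.005, which contradicts standard usage and its
own control narrative (rare 1.96 vs common 0.9 only makes sense with rare
below the threshold); the literal reading remains available as
`rare_definition="above_threshold"`.

The NS/Syn ratio of a gene subset is missense/synonymous per stratum,
undefined when the synonymous count is zero (no division is attempted).  A
feature qualifies as potential non-coding when both stratum ratios are
strictly > 2.0 and their absolute difference is strictly < 0.3; an
undefined ratio makes the verdict undecidable (`None`), which is reported
rather than coerced.

## The eight features

| feature | evidence channel | rule |
|---|---|---|
| recent_gene_age | tools (GTF catalogue) | most distant homologue at or below catarrhini |
| no_protein_features | tools | all five protein-evidence flags false **and** PhyloCSFMax < 0 |
| readthrough_gene | GTF/gene-table annotation | all transcripts readthrough-tagged |
| phylocsf_max | tools | best exon (≥ 10 codons) score ≤ −14 |
| caution_note | protein entry | curator caution (dubious CDS / possible pseudogene) |
| uncertain_evidence | protein entry | protein-existence code 'uncertain' |
| described_pseudogene | any | case-insensitive token 'pseudogene(s)' in the description |
| non_coding_name | HGNC symbol | pseudogene / antisense / lncRNA-style symbol |

A feature is evaluated for a locus only when a member source provides its
evidence channel — a gene-table-only gene can carry exactly three
(readthrough, described pseudogene, non-coding name).  A gene is flagged
iff at least one applicable feature is present.  An undefined PhyloCSFMax
(no scorable exon of ≥ 10 codons) counts as negative for
no_protein_features by default: the absence of a scorable coding exon is
itself non-coding-like (configurable).  Two legacy evidence-code features
('homology' and 'predicted') fail the stratum-gap test and are computed and
reported but never flag a gene unless explicitly re-enabled.

## Peptide support

A peptide qualifies when it is fully tryptic (preceding residue K/R or the
protein N-terminus, and sequence ending K/R or at the protein C-terminus),
observed at least twice, and maps to exactly one gene.  Duplicate sequences
count once; a gene is supported by ≥ 2 distinct qualifying peptides.  The
default trypticity is flank-based with no proline rule (a strict mode adds
K/R-P suppression).  The peptide-level observation threshold and the
gene-level peptide threshold are independent settings.

## The synthetic fixtures

The study's inputs are living public releases; nothing re-downloadable is
deposited.  The generator therefore produces complete stand-ins whose
ground truth is known:

* **Venn structure** — a per-cell cardinality map.  The full-scale spec
  (`full_scale_spec`) uses the published cell totals; the split of the 170
  two-source loci between the GR and RU cells is not printed in the text,
  so the spec uses 100/70 (any split respecting the printed marginals gives
  identical reported quantities).
* **Categories as geometry** — an antisense case is emitted as a real
  opposite-strand gene overlapping a host gene's UTR, an intronic case
  really sits inside an intron, a pseudogene case overlaps a pseudogene
  side record in the right catalogue.  Loci are laid out in disjoint
  10 kb slots left-to-right along the chromosomes so the intended category
  is the only applicable one; hosted cases (antisense/UTR-ORF/intronic)
  are placed inside the slot of a designated intersection locus.
  Categories that cannot be realised geometrically for a cell (e.g.
  antisense where only the structure-less gene table fails to annotate) are
  realised through HGNC-style names; infeasible combinations are rejected
  before any file is written.
* **Feature blocks** — groups of (cell, feature-set, count, supported
  count) realised as actual evidence: ages, per-exon PhyloCSF scores,
  protein-evidence flags, caution notes, evidence codes, descriptions and
  symbols are all set so that evaluating the evidence reproduces the
  intended feature set exactly.
* **Variant tables** — per-subset regimes (true rare/common NS/Syn ratio,
  n, rare fraction).  By default the stratum sizes and class counts are
  exact (largest-remainder), matching the design that stratum membership
  is assigned first; a binomial sampling mode exists and is what the
  statistical recovery tests use.  maxAF values are log-uniform within
  each stratum (10⁻⁵–0.005 and 0.0051–0.5), avoiding the boundary.  Decoy
  rows (frameshift, lone splice_region, zero/missing maxAF, invalid
  alleles, non-principal transcripts) exercise every filter.
* **Peptide tables** — two distinct tryptic peptides per supported gene,
  plus decoys (shared mappings, single observations, non-tryptic flanks)
  and the one readthrough gene with a single — hence insufficient —
  peptide.
* **Merge quirks** — symbol-less records matched by cross-reference or by
  overlap, multi-entry genes, one shared entry spanning six loci,
  unreviewed rows and scaffold-only entries, exercising the cascade's later
  passes and the exclusion logic.

Everything is deterministic under the seed; the same spec and seed give
byte-identical files.  `shrink_fixture` scales a spec with
largest-remainder apportionment, preserving cell and category proportions
to ±1.

**What passing tests do and do not show.**  The fixtures realise each
discrepancy as clean, slot-isolated geometry; real annotations contain
overlapping gene clusters, ragged UTRs, and symbol drift between releases,
so real-data performance of the matching cascade and classifier will be
messier than the fixture recovery rates (the ambiguity log exists for
exactly that reason).  The variant model draws gene assignments uniformly and
ignores per-gene mutational target size and linkage; it validates the
counting and stratification arithmetic, not population-genetic realism.
Peptide decoys cover the rule set, not spectral false positives.

## Numerical and reporting choices

* Percentages: half-up rounding to one decimal, recomputed from the
  adjacent counts in the same table; undefined (not 0) on empty
  denominators.
* Locus order and ids are assigned after sorting by coordinates and member
  ids, so merge output is independent of input record order.
* Drop-reason attribution in the variant filter follows a fixed order; the
  retained set itself is the intersection of independent predicates and
  hence order-independent.
* All writers emit UTF-8, tab-separated, LF line endings; manifests omit
  timestamps and output locations so that identical configurations produce
  byte-identical outputs.
* Problem sizes in the test suite: the full-scale fixture (21 871 loci,
  2 × 20 000 variants) is exercised once per session; oracle-equivalence
  runs use 100 random fixtures of ≤ ~500 genes; statistical recovery uses
  20 000 variants per regime.

## Known limitations

* The merge cascade resolves ambiguities deterministically where the
  original analysis used manual curation; the ambiguity log is the audit
  trail, not a curator.
* Gene-family age and per-exon PhyloCSF scores are consumed as precomputed
  inputs; computing them (BLAST searches, whole-genome alignments) is out
  of scope, as is running VEP itself.
* The classifier's neighbour-geometry rule for the protein database is a
  modelling choice, not something the source analysis states; it is
  switchable and documented above.
* UniProt-role entries carry at most one genomic placement; multi-placement
  entries (beyond the scaffold flag) are not modelled.
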