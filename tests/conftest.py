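import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", max_examples=50, derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

from genecat import (  # noqa: E402
    RunConfig, generate_fixture, full_scale_spec, run_pipeline, shrink_fixture,
)
from genecat.synthetic_data import (  # noqa: E402
    FeatureBlock, FixtureSpec, MergeQuirkSpec, PeptideDecoySpec,
    VariantDecoySpec, VariantSubsetModel, _auto_realise,
)


@pytest.fixture(scope="session")
def full_scale_bundle():
    """The full study-scale fixture (21 871 loci)."""
    return generate_fixture(full_scale_spec(seed=11))


@pytest.fixture(scope="session")
def full_scale_run(full_scale_bundle):
    return run_pipeline(RunConfig(seed=11), bundle=full_scale_bundle)


@pytest.fixture(scope="session")
def small_bundle():
    """A 5% shrink of the study-scale fixture (~1 100 loci)."""
    return generate_fixture(shrink_fixture(full_scale_spec(seed=5), 0.05))


@pytest.fixture(scope="session")
def small_run(small_bundle):
    return run_pipeline(RunConfig(seed=5), bundle=small_bundle)


def random_spec(seed: int) -> FixtureSpec:
    """A feasible random fixture spec with <= ~500 genes, for oracle testing."""
    rng = np.random.default_rng(seed)
    cells = {"GRU": int(rng.integers(25, 70))}
    for c in ("G", "R", "U", "GR", "GU", "RU"):
        cells[c] = int(rng.integers(0, 16))

    host_budget = cells["GRU"]
    category_cells = {}
    for cell in ("G", "R", "U", "GR", "GU", "RU"):
        n = cells[cell]
        if n == 0:
            continue
        cats = {}
        for _ in range(n):
            options = []
            for cat in ("readthrough", "ig_tr", "pseudogene", "lncRNA",
                        "retroviral", "antisense", "utr_orf", "intronic",
                        "intergenic", "artefact_tec", "no_coordinates"):
                if cat == "no_coordinates" and cell != "U":
                    continue
                try:
                    mode = _auto_realise(cat, cell)
                except Exception:
                    continue
                if cat in ("antisense", "utr_orf", "intronic") \
                        and mode == "geometry" and host_budget <= 0:
                    continue
                options.append((cat, mode))
            cat, mode = options[int(rng.integers(len(options)))]
            if cat in ("antisense", "utr_orf", "intronic") and mode == "geometry":
                host_budget -= 1
            cats[cat] = cats.get(cat, 0) + 1
        category_cells[cell] = cats

    blocks = []
    gru_budget = cells["GRU"]
    for cell, cats in category_cells.items():
        n_rt = cats.get("readthrough", 0)
        if n_rt and set(cell) & {"G", "R"}:
            blocks.append(FeatureBlock(cell, ("readthrough_gene",), n_rt,
                                       category="readthrough"))
    feature_menu = {
        "G": [("recent_gene_age",), ("no_protein_features",),
              ("phylocsf_max",), ("recent_gene_age", "phylocsf_max"),
              ("described_pseudogene",)],
        "R": [("described_pseudogene",), ("non_coding_name",)],
        "U": [("caution_note",), ("uncertain_evidence",),
              ("described_pseudogene",), ("caution_note", "uncertain_evidence")],
    }
    for cell in cells:
        if cells[cell] == 0:
            continue
        menu = []
        for letter, opts in feature_menu.items():
            if letter in cell:
                menu += opts
        if not menu:
            continue
        free = cells[cell] - sum(b.count for b in blocks if b.cell == cell)
        if cell == "GRU":
            free = min(free, gru_budget - 10)  # leave room for support/quirks
        if free <= 0:
            continue
        n_blocks = int(rng.integers(0, 3))
        for _ in range(n_blocks):
            feats = menu[int(rng.integers(len(menu)))]
            count = int(rng.integers(1, max(free // 2, 2)))
            if count > free:
                break
            blocks.append(FeatureBlock(cell, feats, count,
                                       n_supported=int(rng.integers(0, count + 1))))
            free -= count

    used_gru = sum(b.count for b in blocks if b.cell == "GRU")
    spare = cells["GRU"] - used_gru - (cells["GRU"] - host_budget)
    quirks = MergeQuirkSpec()
    if spare > 8:
        quirks = MergeQuirkSpec(
            xref_matched=int(rng.integers(0, 3)),
            overlap_matched=int(rng.integers(0, 3)),
            multi_uniprot=int(rng.integers(0, 2)),
            unreviewed_entries=int(rng.integers(0, 3)),
            scaffold_entries=int(rng.integers(0, 3)))
        spare -= 10
    unflagged_supported = {"GRU": int(rng.integers(0, max(spare, 1)))} if spare > 0 else {}

    return FixtureSpec(
        seed=seed,
        venn_cells=cells,
        category_cells=category_cells,
        feature_blocks=blocks,
        unflagged_supported=unflagged_supported,
        variant_models=[VariantSubsetModel(
            "all", "all", rare_ratio=float(rng.uniform(0.5, 3.0)),
            common_ratio=float(rng.uniform(0.5, 3.0)),
            n_variants=int(rng.integers(200, 600)))],
        variant_decoys=VariantDecoySpec(
            frameshift=int(rng.integers(0, 10)),
            splice_region_only=int(rng.integers(0, 10)),
            zero_af=int(rng.integers(0, 10)),
            missing_af=int(rng.integers(0, 10)),
            bad_allele=int(rng.integers(0, 10)),
            non_principal=int(rng.integers(0, 10))),
        peptide_decoys=PeptideDecoySpec(
            multi_gene=int(rng.integers(0, 5)),
            single_observation=int(rng.integers(0, 5)),
            non_tryptic=int(rng.integers(0, 5))),
        quirks=quirks,
    )
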