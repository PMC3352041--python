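"""Deterministic generator of complete synthetic input bundles.

Emulates the five input dialects — miRNA and gene deregulation lists, a
scored miRNA-target interaction table, GMT categories, a miFam family file —
with planted statistical structure so that every stage of the analysis can
be exercised and its operating characteristics (type-I error, power,
enrichment recovery) measured without any external download.

What is emulated: realistic identifier dialects, a sparse random
interaction graph, a tunable dependence between miRNA and target
deregulation, decoy interaction rows above the score threshold, one
category enriched among deregulated genes and one miRNA family contained
in the deregulated miRNAs.  What is *not* emulated: expression values and
their preprocessing (the tool consumes discrete deregulation calls), seed-
sequence structure, and the heavy target-multiplicity of real prediction
tables (see the methods note).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io_formats import (
    GENE,
    MIRNA,
    CategoryDB,
    DeregulationSet,
    FamilyDB,
    InteractionTable,
    write_deregulation_file,
    write_gmt,
    write_interaction_table,
    write_mifam,
)

PLANTED_CATEGORY = "C_PLANTED"
PLANTED_FAMILY = "fam-planted"

#: seed of the fixed melanoma-shaped example bundle
MELANOMA_BUNDLE_SEED = 20120222


@dataclass(frozen=True)
class ScenarioSpec:
    """Study conditions for one synthetic dataset.

    Defaults describe a desk-scale study: 40 miRNAs regulating 800 genes
    through 1600 scored interactions (so a gene is targeted about twice on
    average, keeping the pair-level independence assumption of the
    chi-squared test reasonable), with a quarter of each entity class
    deregulated.  ``dependence_strength`` is the excess probability that a
    target of a deregulated miRNA is itself deregulated:
    P(deregulated | targeted) = p0 + rho * (1 - p0).
    """

    n_mirnas: int = 40
    n_genes: int = 800
    n_interactions: int = 1600
    frac_dereg_mirnas: float = 0.25
    frac_dereg_genes: float = 0.25
    dependence_strength: float = 0.0
    direction_bias: float = 0.5
    n_categories: int = 30
    planted_category_odds: float = 10.0
    n_families: int = 8
    plant_family: bool = True
    plant_category: bool = True
    score_threshold: float = 0.01
    decoy_fraction: float = 0.25
    organism_prefix: str = "hsa"
    mirna_split: tuple[int, int] | None = None  # exact (up, down) counts
    gene_split: tuple[int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_interactions > self.n_mirnas * self.n_genes:
            raise ValueError("more interactions requested than miRNA x gene pairs")
        for frac in (
            self.frac_dereg_mirnas,
            self.frac_dereg_genes,
            self.dependence_strength,
            self.direction_bias,
            self.decoy_fraction,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions and probabilities must lie in [0, 1]")
        if self.gene_split is not None and sum(self.gene_split) > self.n_genes:
            raise ValueError("gene_split exceeds n_genes")
        if self.mirna_split is not None and sum(self.mirna_split) > self.n_mirnas:
            raise ValueError("mirna_split exceeds n_mirnas")


@dataclass(frozen=True)
class ScenarioBundle:
    """In-memory scenario: the parsed-equivalent objects plus ground truth."""

    spec: ScenarioSpec
    mir_dereg: DeregulationSet
    gene_dereg: DeregulationSet
    interactions: InteractionTable
    categories: CategoryDB
    families: FamilyDB
    truth: dict


def _gumbel_top_k(rng: np.random.Generator, weights: np.ndarray, k: int) -> np.ndarray:
    """Indices of a weighted sample of size k without replacement
    (successive-draw / Plackett-Luce semantics via the Gumbel trick)."""
    if k == 0:
        return np.array([], dtype=int)
    keys = np.log(weights) + rng.gumbel(size=weights.size)
    return np.argpartition(-keys, k - 1)[:k]


def _sample_pairs(
    rng: np.random.Generator, n_mirnas: int, n_genes: int, n_pairs: int
) -> np.ndarray:
    """n_pairs distinct flat indices into the n_mirnas x n_genes grid."""
    total = n_mirnas * n_genes
    if n_pairs > total // 2:
        return rng.permutation(total)[:n_pairs]
    flat: np.ndarray = np.unique(rng.integers(0, total, size=int(n_pairs * 1.5) + 16))
    while flat.size < n_pairs:
        extra = rng.integers(0, total, size=n_pairs)
        flat = np.unique(np.concatenate([flat, extra]))
    return rng.permutation(flat)[:n_pairs]


def build_scenario(spec: ScenarioSpec) -> ScenarioBundle:
    """Draw one scenario from the given study conditions (pure, in-memory)."""
    rng = np.random.default_rng(spec.seed)
    mirna_ids = [f"{spec.organism_prefix}-miR-{i + 1}" for i in range(spec.n_mirnas)]
    gene_ids = [f"GENE{i + 1:05d}" for i in range(spec.n_genes)]

    # interaction graph
    flat = _sample_pairs(rng, spec.n_mirnas, spec.n_genes, spec.n_interactions)
    mir_idx, gene_idx = np.divmod(flat, spec.n_genes)

    # deregulated miRNAs: exact counts, random identities
    if spec.mirna_split is not None:
        n_up_m, n_down_m = spec.mirna_split
    else:
        total_m = round(spec.frac_dereg_mirnas * spec.n_mirnas)
        n_up_m, n_down_m = total_m - total_m // 2, total_m // 2
    dereg_m_idx = rng.choice(spec.n_mirnas, size=n_up_m + n_down_m, replace=False)
    mir_entries: dict[str, int] = {}
    for pos, idx in enumerate(dereg_m_idx):
        mir_entries[mirna_ids[idx]] = +1 if pos < n_up_m else -1
    mir_dereg = DeregulationSet(entity_class=MIRNA, entries=mir_entries)

    # which genes are targeted by a deregulated miRNA (and a regulator direction)
    dereg_m_mask = np.zeros(spec.n_mirnas, dtype=bool)
    dereg_m_mask[dereg_m_idx] = True
    targeted = np.zeros(spec.n_genes, dtype=bool)
    regulator_dir = np.zeros(spec.n_genes, dtype=np.int64)
    for mi, gi in zip(mir_idx, gene_idx):
        if dereg_m_mask[mi]:
            targeted[gi] = True
            regulator_dir[gi] = mir_entries[mirna_ids[mi]]

    p0 = spec.frac_dereg_genes
    rho = spec.dependence_strength
    p_target = p0 + rho * (1.0 - p0)
    if spec.gene_split is not None:
        # exact counts: weighted sampling without replacement, weights equal to
        # the odds ratio implied by rho
        n_up_g, n_down_g = spec.gene_split
        if p0 in (0.0, 1.0) or rho == 0.0:
            weights = np.ones(spec.n_genes)
        else:
            odds_ratio = (p_target / (1 - p_target)) / (p0 / (1 - p0))
            weights = np.where(targeted, odds_ratio, 1.0)
        dereg_g_idx = _gumbel_top_k(rng, weights, n_up_g + n_down_g)
        dereg_g_mask = np.zeros(spec.n_genes, dtype=bool)
        dereg_g_mask[dereg_g_idx] = True
        order = rng.permutation(dereg_g_idx)
        gene_dirs = {int(idx): (+1 if pos < n_up_g else -1) for pos, idx in enumerate(order)}
    else:
        # per-gene Bernoulli (matches the definition of rho directly)
        probs = np.where(targeted, p_target, p0)
        dereg_g_mask = rng.random(spec.n_genes) < probs
        gene_dirs = {}
        for gi in np.nonzero(dereg_g_mask)[0]:
            gi = int(gi)
            if targeted[gi] and regulator_dir[gi] != 0:
                same = rng.random() < spec.direction_bias
                gene_dirs[gi] = int(regulator_dir[gi]) if same else -int(regulator_dir[gi])
            else:
                gene_dirs[gi] = +1 if rng.random() < 0.5 else -1
    gene_entries = {gene_ids[gi]: d for gi, d in sorted(gene_dirs.items())}
    gene_dereg = DeregulationSet(entity_class=GENE, entries=gene_entries)

    # scored interactions: retained rows below the threshold, decoys above
    scores = rng.uniform(0.0, spec.score_threshold, size=flat.size)
    scores = np.clip(np.nextafter(scores, -1.0), 0.0, None)  # strictly below threshold
    pairs = tuple(
        (mirna_ids[int(mi)], gene_ids[int(gi)], float(s))
        for mi, gi, s in zip(mir_idx, gene_idx, scores)
    )
    interactions = InteractionTable(
        pairs=tuple(sorted(pairs)), organism_prefix=spec.organism_prefix
    )
    n_decoys = int(round(spec.decoy_fraction * flat.size))
    decoy_flat = rng.choice(spec.n_mirnas * spec.n_genes, size=n_decoys, replace=False)
    decoy_scores = rng.uniform(spec.score_threshold, 1.0, size=n_decoys)

    # categories: random gene sets plus one planted toward deregulated genes
    categories: dict[str, frozenset[str]] = {}
    n_random = spec.n_categories - (1 if spec.plant_category else 0)
    for c in range(n_random):
        size = int(rng.integers(10, 41))
        members = rng.choice(spec.n_genes, size=size, replace=False)
        categories[f"C{c:03d}"] = frozenset(gene_ids[int(g)] for g in members)
    if spec.plant_category:
        weights = np.where(dereg_g_mask, spec.planted_category_odds, 1.0)
        members = _gumbel_top_k(rng, weights, min(20, spec.n_genes))
        categories[PLANTED_CATEGORY] = frozenset(gene_ids[int(g)] for g in members)
    category_db = CategoryDB(categories=categories, source_label="synthetic")

    # families: disjoint miRNA groups; the planted one sits inside the
    # deregulated miRNAs
    families: dict[str, frozenset[str]] = {}
    pool = list(range(spec.n_mirnas))
    family_size = max(2, min(5, spec.n_mirnas // max(1, spec.n_families)))
    if spec.plant_family and len(dereg_m_idx) >= 2:
        planted_size = min(family_size, len(dereg_m_idx))
        chosen = rng.choice(dereg_m_idx, size=planted_size, replace=False)
        families[PLANTED_FAMILY] = frozenset(mirna_ids[int(i)] for i in chosen)
        pool = [i for i in pool if i not in set(int(c) for c in chosen)]
    n_other = spec.n_families - len(families)
    pool_arr = rng.permutation(pool)
    offset = 0
    for f in range(n_other):
        members = pool_arr[offset : offset + family_size]
        offset += family_size
        if len(members) < 2:
            break
        families[f"fam-{f:03d}"] = frozenset(mirna_ids[int(i)] for i in members)
    family_db = FamilyDB(families=families)

    truth = {
        "seed": spec.seed,
        "n_dereg_mirnas_up": int(mir_dereg.n_up),
        "n_dereg_mirnas_down": int(mir_dereg.n_down),
        "n_dereg_genes_up": int(gene_dereg.n_up),
        "n_dereg_genes_down": int(gene_dereg.n_down),
        "n_interactions_retained": int(flat.size),
        "n_interactions_decoy": int(n_decoys),
        "n_targeted_by_dereg_mirnas": int(targeted.sum()),
        "realized_p_dereg_given_targeted": (
            float(dereg_g_mask[targeted].mean()) if targeted.any() else float("nan")
        ),
        "dependence_strength": rho,
        "planted_category": PLANTED_CATEGORY if spec.plant_category else None,
        "planted_family": (
            PLANTED_FAMILY if spec.plant_family and PLANTED_FAMILY in families else None
        ),
        "decoy_rows": [
            (mirna_ids[int(mi)], gene_ids[int(gi)], float(s))
            for (mi, gi), s in zip(
                (divmod(int(f), spec.n_genes) for f in decoy_flat), decoy_scores
            )
        ],
    }
    return ScenarioBundle(
        spec=spec,
        mir_dereg=mir_dereg,
        gene_dereg=gene_dereg,
        interactions=interactions,
        categories=category_db,
        families=family_db,
        truth=truth,
    )


def generate_scenario(spec: ScenarioSpec, out_dir: str | Path) -> dict:
    """Materialise a scenario as the five input files plus a manifest.

    Returns the manifest: file paths, the ground-truth record, and the spec.
    The interaction file interleaves the retained rows with decoy rows whose
    scores sit at or above the threshold, so reading it back at the spec's
    threshold recovers exactly the retained pairs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = build_scenario(spec)
    paths = {
        "mirna_dereg": out_dir / "mirna_deregulation.tsv",
        "gene_dereg": out_dir / "gene_deregulation.tsv",
        "interactions": out_dir / "interactions.tsv",
        "categories": out_dir / "categories.gmt",
        "families": out_dir / "mifam.dat",
    }
    write_deregulation_file(bundle.mir_dereg, paths["mirna_dereg"])
    write_deregulation_file(bundle.gene_dereg, paths["gene_dereg"])
    all_rows = sorted(
        list(bundle.interactions.pairs) + list(bundle.truth["decoy_rows"])
    )
    with paths["interactions"].open("w") as handle:
        for mirna, gene, score in all_rows:
            handle.write(f"{mirna}\t{gene}\t{score!r}\n")
    write_gmt(bundle.categories, paths["categories"])
    write_mifam(bundle.families, paths["families"])

    manifest = {
        "spec": asdict(bundle.spec),
        "paths": {k: str(v) for k, v in paths.items()},
        "truth": {k: v for k, v in bundle.truth.items() if k != "decoy_rows"},
    }
    with (out_dir / "manifest.json").open("w") as handle:
        json.dump(manifest, handle, indent=1, sort_keys=True)
        handle.write("\n")
    return manifest


def melanoma_example_spec() -> ScenarioSpec:
    """Fixed-seed scenario with the shape of the published melanoma inputs.

    A synthetic stand-in, not the original data: 1000 miRNAs and 20000 genes
    joined by ~280,000 retained interactions, 16 up + 17 down deregulated
    miRNAs, 2550 up + 2218 down deregulated genes.
    """
    return ScenarioSpec(
        n_mirnas=1000,
        n_genes=20000,
        n_interactions=279_225,
        mirna_split=(16, 17),
        gene_split=(2550, 2218),
        dependence_strength=0.0,
        n_categories=30,
        n_families=20,
        decoy_fraction=0.05,
        seed=MELANOMA_BUNDLE_SEED,
    )


def melanoma_example_bundle(out_dir: str | Path) -> dict:
    """Write the melanoma-shaped synthetic bundle (fixed seed) to ``out_dir``."""
    return generate_scenario(melanoma_example_spec(), out_dir)
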