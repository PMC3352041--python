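"""Hypergeometric over-representation analysis (ORA), Venn overlap
statistics, Benjamini-Hochberg adjustment, the three-analysis overlap
coding, and miRNA-family enrichment.

Three coordinated gene-set analyses are run against the same category
database:

* **A** — targets of deregulated miRNAs,
* **B** — deregulated targets of deregulated miRNAs (B = A intersect C),
* **C** — deregulated genes.

Categories significant in at least two of the three receive an overlap
*code*, a bitmask over the pairwise overlaps reminiscent of Unix file
permissions: A&B contributes 1, B&C contributes 2, A&C contributes 4, so a
category significant in all three codes 7 and one significant in B and C
only codes 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .io_formats import CategoryDB, DeregulationSet, FamilyDB, InteractionTable

logger = logging.getLogger(__name__)

ENRICHED = "enriched"
DEPLETED = "depleted"

#: overlap-code bit values, keyed by the pairwise overlap they flag
CODE_BITS = {("A", "B"): 1, ("B", "C"): 2, ("A", "C"): 4}


# ---------------------------------------------------------------------------
# hypergeometric tail
# ---------------------------------------------------------------------------


def _log_hypergeom_pmf(population: int, successes: int, draws: int, k: np.ndarray) -> np.ndarray:
    return (
        gammaln(successes + 1)
        - gammaln(k + 1)
        - gammaln(successes - k + 1)
        + gammaln(population - successes + 1)
        - gammaln(draws - k + 1)
        - gammaln(population - successes - draws + k + 1)
        - (gammaln(population + 1) - gammaln(draws + 1) - gammaln(population - draws + 1))
    )


def hypergeom_tail(
    population: int, successes: int, draws: int, observed: int, side: str = "upper"
) -> float:
    """Exact hypergeometric tail probability, summed in log space.

    ``side="upper"`` gives P(X >= observed), ``side="lower"`` P(X <= observed)
    for X ~ Hypergeometric(population, successes, draws).
    """
    if not (0 <= successes <= population and 0 <= draws <= population):
        raise ValueError("need 0 <= successes, draws <= population")
    if not 0 <= observed <= min(draws, successes):
        raise ValueError(
            f"observed {observed} outside [0, min(draws, successes) = "
            f"{min(draws, successes)}]"
        )
    if side not in ("upper", "lower"):
        raise ValueError(f"side must be 'upper' or 'lower', got {side!r}")
    k_min = max(0, draws - (population - successes))
    k_max = min(draws, successes)
    if side == "upper":
        ks = np.arange(observed, k_max + 1)
    else:
        ks = np.arange(k_min, observed + 1)
    if ks.size == 0:
        return 1.0 if side == "upper" and observed <= k_min else 0.0
    total = logsumexp(_log_hypergeom_pmf(population, successes, draws, ks))
    return float(min(1.0, np.exp(total)))


def bh_adjust(p_values: list[float] | np.ndarray) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in adjusted]


# ---------------------------------------------------------------------------
# ORA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OraResult:
    """Per-category enrichment record for one analysis."""

    category: str
    test_hits: int
    test_size: int
    ref_hits: int
    ref_size: int
    expected: float
    direction: str
    p_raw: float
    p_adj: float
    preselected: bool = False

    def __post_init__(self) -> None:
        if self.test_hits > min(self.test_size, self.ref_hits):
            raise ValueError("test_hits exceeds min(test_size, ref_hits)")
        if self.p_adj + 1e-15 < self.p_raw:
            raise ValueError("adjusted p below raw p")


def ora(
    test_set: frozenset[str] | set[str],
    reference_set: frozenset[str] | set[str],
    categories: CategoryDB,
    alpha: float = 0.05,
) -> list[OraResult]:
    """Two-sided hypergeometric ORA of ``test_set`` against ``reference_set``.

    Per category (restricted to the reference), the direction is chosen by
    comparing observed hits to the expected count, the matching one-sided
    tail is doubled (capped at 1), and BH adjustment is applied across all
    categories of the analysis.  Results are sorted by adjusted p, then name.
    Categories with no members in the reference are skipped and logged.
    """
    test = frozenset(test_set)
    reference = frozenset(reference_set)
    if not reference:
        raise ValueError("reference set is empty")
    if not test <= reference:
        missing = sorted(test - reference)[:5]
        raise ValueError(f"test set not contained in reference (e.g. {missing})")
    rows: list[OraResult] = []
    for name in sorted(categories.categories):
        members = categories.categories[name] & reference
        if not members:
            logger.info("category %s has no members in the reference; skipped", name)
            continue
        ref_hits = len(members)
        test_hits = len(members & test)
        expected = len(test) * ref_hits / len(reference)
        if test_hits >= expected:
            direction = ENRICHED
            tail = hypergeom_tail(len(reference), ref_hits, len(test), test_hits, "upper")
        else:
            direction = DEPLETED
            tail = hypergeom_tail(len(reference), ref_hits, len(test), test_hits, "lower")
        rows.append(
            OraResult(
                category=name,
                test_hits=test_hits,
                test_size=len(test),
                ref_hits=ref_hits,
                ref_size=len(reference),
                expected=expected,
                direction=direction,
                p_raw=min(1.0, 2.0 * tail),
                p_adj=1.0,  # placeholder until BH below
            )
        )
    if not rows:
        return []
    adjusted = bh_adjust([r.p_raw for r in rows])
    rows = [
        replace(r, p_adj=p, preselected=p < alpha) for r, p in zip(rows, adjusted)
    ]
    rows.sort(key=lambda r: (r.p_adj, r.p_raw, r.category))
    return rows


# ---------------------------------------------------------------------------
# the three coordinated gene sets and the Venn overlap
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSets:
    """The three test sets of the coordinated analyses plus their reference."""

    targets_of_dereg_mirs: frozenset[str]  # A
    dereg_targets_of_dereg_mirs: frozenset[str]  # B = A & C
    dereg_genes: frozenset[str]  # C
    reference: frozenset[str]


def derive_gene_sets(
    mir_dereg: DeregulationSet,
    gene_dereg: DeregulationSet,
    interactions: InteractionTable,
) -> GeneSets:
    """Build sets A, B, C and the reference universe (table genes + uploads)."""
    dereg_mirs = mir_dereg.ids()
    targets: set[str] = set()
    for mirna, gene in interactions.pair_keys():
        if mirna in dereg_mirs:
            targets.add(gene)
    dereg_genes = gene_dereg.ids()
    reference = interactions.gene_ids | dereg_genes
    return GeneSets(
        targets_of_dereg_mirs=frozenset(targets),
        dereg_targets_of_dereg_mirs=frozenset(targets & dereg_genes),
        dereg_genes=frozenset(dereg_genes),
        reference=frozenset(reference),
    )


@dataclass(frozen=True)
class VennResult:
    """Two-set Venn of deregulated genes vs targets of deregulated miRNAs.

    ``left`` counts targets that are not deregulated, ``overlap`` deregulated
    targets, ``right`` deregulated genes that are not targeted.  The p-value
    is the upper hypergeometric tail of the overlap given the universe.
    """

    left: int
    overlap: int
    right: int
    universe_size: int
    p_value: float


def venn_overlap(
    dereg_genes: frozenset[str] | set[str],
    targets_of_dereg_mirs: frozenset[str] | set[str],
    universe: frozenset[str] | set[str],
) -> VennResult:
    dereg = frozenset(dereg_genes)
    targets = frozenset(targets_of_dereg_mirs)
    uni = frozenset(universe)
    if not dereg <= uni or not targets <= uni:
        raise ValueError("both sets must be contained in the universe")
    overlap = len(dereg & targets)
    p = hypergeom_tail(len(uni), len(dereg), len(targets), overlap, "upper")
    return VennResult(
        left=len(targets - dereg),
        overlap=overlap,
        right=len(dereg - targets),
        universe_size=len(uni),
        p_value=p,
    )


# ---------------------------------------------------------------------------
# overlap coding
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OverlapCodeTable:
    """Categories significant in >= 2 of the three analyses, with their code.

    ``rows`` maps category -> (membership letters as a sorted tuple from
    {"a", "b", "c"}, bitmask code in {1, 2, 4, 7}).
    """

    rows: dict[str, tuple[tuple[str, ...], int]]


def overlap_codes(
    results_a: list[OraResult],
    results_b: list[OraResult],
    results_c: list[OraResult],
    alpha: float = 0.05,
    use_raw: bool = False,
) -> OverlapCodeTable:
    """Assign the pairwise-overlap bitmask to multiply-significant categories.

    A category is "found" in an analysis when its adjusted p (raw p when
    ``use_raw``) is below ``alpha``.  Bits: A&B = 1, B&C = 2, A&C = 4.
    """
    by_analysis = {"A": results_a, "B": results_b, "C": results_c}
    universes = {
        label: frozenset(r.category for r in results)
        for label, results in by_analysis.items()
    }
    if not (universes["A"] == universes["B"] == universes["C"]):
        raise ValueError("the three ORA result lists cover different categories")
    found: dict[str, set[str]] = {}
    for label, results in by_analysis.items():
        for r in results:
            p = r.p_raw if use_raw else r.p_adj
            if p < alpha:
                found.setdefault(r.category, set()).add(label)
    rows: dict[str, tuple[tuple[str, ...], int]] = {}
    for category, labels in sorted(found.items()):
        if len(labels) < 2:
            continue
        code = 0
        for (x, y), bit in CODE_BITS.items():
            if x in labels and y in labels:
                code |= bit
        rows[category] = (tuple(sorted(label.lower() for label in labels)), code)
    return OverlapCodeTable(rows=rows)


# ---------------------------------------------------------------------------
# miRNA-family enrichment
# ---------------------------------------------------------------------------


def family_ora(
    mir_dereg: DeregulationSet,
    families: FamilyDB,
    mir_universe: frozenset[str] | set[str],
    alpha: float = 0.05,
) -> list[OraResult]:
    """ORA of the deregulated miRNAs over miRNA families.

    Identical statistic to :func:`ora` with miRNAs in place of genes; ids are
    matched case-insensitively.  Families with adjusted p below ``alpha``
    carry ``preselected=True`` (the default selection a user would start
    from).
    """
    universe = frozenset(m.lower() for m in mir_universe) | mir_dereg.ids()
    family_db = CategoryDB(
        categories={
            name: families.members_normalized(name) for name in families.families
        },
        source_label="miRNA families",
    )
    return ora(mir_dereg.ids(), universe, family_db, alpha=alpha)
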