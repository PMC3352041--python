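"""Contingency-table test of (in)dependence between miRNA and target
deregulation, with a label-randomization control.

Every (miRNA, target) interaction pair is classified by the deregulation
status of its two ends — up, down, or not deregulated — giving a 3x3 table.
Pearson's chi-squared statistic with (3-1)(3-1) = 4 degrees of freedom tests
whether miRNA status and target status are associated across the pairs.

Two caveats are built in.  First, when the uploaded gene list contains only
one direction of deregulation the analytic p-value is refused (the table is
still reported): a one-directional list makes the direction dimension
degenerate and the test uninterpretable as an up/down association.  The same
refusal applies when a row or column margin is zero, where expected counts
are undefined.  Second, interaction pairs are not independent draws — a
high-degree gene contributes many pairs with identical status — so a
randomization control is provided that resamples which identifiers carry the
observed deregulation pattern and recomputes the statistic, yielding an
empirical null that respects the pairing structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import GENE, MIRNA, DeregulationSet, InteractionTable

STATUS_LABELS = ("up", "down", "not")
_STATUS_INDEX = {+1: 0, -1: 1, None: 2}

DF = 4  # (3 - 1) * (3 - 1) for the 3x3 status table


class IndependenceRefusedError(RuntimeError):
    """The analytic p-value is not allowed for this input (see message)."""


@dataclass(frozen=True)
class ContingencyTable:
    """3x3 counts of interaction pairs by miRNA status x target status.

    Rows are miRNA status (up, down, not), columns target status.  The total
    always equals the number of interaction pairs considered.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (3, 3):
            raise ValueError("contingency table must be 3x3")
        if (counts < 0).any():
            raise ValueError("contingency counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def same_direction_count(self) -> int:
        """Pairs whose miRNA and target are deregulated in the same direction."""
        return int(self.counts[0, 0] + self.counts[1, 1])

    def to_text(self) -> str:
        header = "miRNA\\target\t" + "\t".join(STATUS_LABELS)
        rows = [
            STATUS_LABELS[i] + "\t" + "\t".join(str(int(c)) for c in self.counts[i])
            for i in range(3)
        ]
        return "\n".join([header] + rows)


@dataclass(frozen=True)
class IndependenceResult:
    table: ContingencyTable
    chi2: float
    df: int
    p_value: float | None
    p_allowed: bool
    same_direction_count: int
    refusal_reason: str | None = None

    def __post_init__(self) -> None:
        if self.p_allowed != (self.p_value is not None):
            raise ValueError("p_value must be present exactly when p_allowed")


def build_contingency(
    mir_dereg: DeregulationSet,
    gene_dereg: DeregulationSet,
    interactions: InteractionTable,
) -> ContingencyTable:
    """Classify every interaction pair into the 3x3 status table.

    Identifiers absent from the deregulation sets count as "not deregulated";
    each pair contributes to exactly one cell.
    """
    if mir_dereg.entity_class != MIRNA or gene_dereg.entity_class != GENE:
        raise TypeError("expected a miRNA deregulation set and a gene deregulation set")
    counts = np.zeros((3, 3), dtype=np.int64)
    # Build status lookups once; pair classification is then O(1) per pair.
    mir_status = {key: _STATUS_INDEX[mir_dereg.direction_of(key)] for key in mir_dereg.ids()}
    gene_status = {key: _STATUS_INDEX[gene_dereg.direction_of(key)] for key in gene_dereg.ids()}
    for mirna, gene in interactions.pair_keys():
        i = mir_status.get(mirna, 2)
        j = gene_status.get(gene, 2)
        counts[i, j] += 1
    return ContingencyTable(counts=counts)


def pearson_chi2(counts: np.ndarray) -> float:
    """Pearson statistic over all 9 cells; cells with zero expected count
    (zero margin) contribute nothing."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total == 0:
        return 0.0
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
    return float(terms.sum())


def chi_squared_independence(
    table: ContingencyTable, gene_dereg: DeregulationSet
) -> IndependenceResult:
    """Chi-squared test on the status table, honouring the refusal rules.

    The p-value comes from the upper tail of the chi-squared distribution
    with 4 degrees of freedom.  Refusal (p absent, table still returned)
    happens when the gene deregulation list is one-directional or a margin
    of the table is zero.
    """
    chi2 = pearson_chi2(table.counts)
    refusal: str | None = None
    if len(gene_dereg.directions_present) < 2:
        refusal = (
            "gene deregulation list contains a single direction; "
            "the chi-squared p-value is not computed"
        )
    elif (table.counts.sum(axis=1) == 0).any() or (table.counts.sum(axis=0) == 0).any():
        refusal = "a row or column margin of the contingency table is zero"
    p_value = None if refusal else float(stats.chi2.sf(chi2, DF))
    return IndependenceResult(
        table=table,
        chi2=chi2,
        df=DF,
        p_value=p_value,
        p_allowed=refusal is None,
        same_direction_count=table.same_direction_count,
        refusal_reason=refusal,
    )


def _universe(
    dereg: DeregulationSet, table_ids: frozenset[str]
) -> tuple[str, ...]:
    return tuple(sorted(table_ids | dereg.ids()))


def randomize_deregulation(
    mir_dereg: DeregulationSet,
    gene_dereg: DeregulationSet,
    interactions: InteractionTable,
    seed: int | np.random.Generator,
) -> tuple[DeregulationSet, DeregulationSet]:
    """Resample which identifiers carry the observed deregulation pattern.

    The up/down pattern (16 up + 17 down stays 16 up + 17 down) is preserved;
    identifiers are drawn uniformly without replacement from the universe of
    ids seen in the interaction table unioned with the uploaded ids.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out: list[DeregulationSet] = []
    for dereg, table_ids in (
        (mir_dereg, interactions.mirna_ids),
        (gene_dereg, interactions.gene_ids),
    ):
        universe = _universe(dereg, table_ids)
        if len(universe) < len(dereg):
            raise ValueError(
                f"universe of {len(universe)} {dereg.entity_class} ids is smaller "
                f"than the deregulation set of {len(dereg)}"
            )
        chosen = rng.choice(len(universe), size=len(dereg), replace=False)
        directions = [dereg.entries[k] for k in sorted(dereg.entries)]
        entries = {universe[idx]: d for idx, d in zip(chosen, directions)}
        out.append(DeregulationSet(entity_class=dereg.entity_class, entries=entries))
    return out[0], out[1]


def randomization_pvalue(
    mir_dereg: DeregulationSet,
    gene_dereg: DeregulationSet,
    interactions: InteractionTable,
    n_reps: int,
    seed: int,
) -> float:
    """Empirical p: fraction of randomized replicates with chi2 >= observed,
    with add-one smoothing (p = (1 + #exceed) / (n_reps + 1))."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    observed = chi_squared_independence(
        build_contingency(mir_dereg, gene_dereg, interactions), gene_dereg
    )
    if not observed.p_allowed:
        raise IndependenceRefusedError(observed.refusal_reason or "p-value refused")
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_reps):
        mir_r, gene_r = randomize_deregulation(mir_dereg, gene_dereg, interactions, rng)
        chi2_r = pearson_chi2(build_contingency(mir_r, gene_r, interactions).counts)
        if chi2_r >= observed.chi2:
            exceed += 1
    return (1 + exceed) / (n_reps + 1)
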