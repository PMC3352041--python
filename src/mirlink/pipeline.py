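"""End-to-end orchestration of the joint miRNA/mRNA deregulation analysis.

A run reads the five inputs and emits, in order: the input summary, the
contingency table with its chi-squared result (or refusal note), the Venn
overlap, the three coordinated ORAs, the overlap-code table, the
miRNA-family ORA, the ranked miRNA list, the selected regulatory subnetwork
(GraphML + SIF + gene list), a focused ORA on the selection, and PubMed
query strings when a disease label is given.  All tables are written as TSV,
assembled into a Markdown report, and every parameter and seed is recorded
in a run log.  Output is fully deterministic for a fixed config and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import enrichment, independence, network
from .io_formats import (
    GENE,
    MIRNA,
    DeregulationSet,
    FamilyDB,
    read_deregulation_file,
    read_gmt,
    read_interaction_table,
    read_mifam,
    write_graphml,
    write_sif,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message is prefixed with the stage name."""


@dataclass(frozen=True)
class SelectionSpec:
    """How to choose the miRNAs of the subnetwork analysis.

    Exactly one of the four criteria should be set: explicit ids, family
    names, the top N miRNAs by deregulated-target count, or all miRNAs with
    at least ``min_dereg_targets`` deregulated targets.  When none is set,
    every miRNA vertex is selected.
    """

    mirna_ids: tuple[str, ...] = ()
    family_names: tuple[str, ...] = ()
    top_n: int | None = None
    min_dereg_targets: int | None = None


@dataclass(frozen=True)
class AnalysisConfig:
    mirna_dereg_path: str
    gene_dereg_path: str
    interactions_path: str
    categories_path: str
    families_path: str | None = None
    disease: str | None = None
    score_threshold: float = 0.01
    alpha: float = 0.05
    adjustment: str = "bh"  # "bh" or "raw"
    selection: SelectionSpec = field(default_factory=SelectionSpec)
    degree_constraint: int = 1
    randomize_reps: int = 0
    seed: int = 0
    out_dir: str = "mirlink_results"

    def __post_init__(self) -> None:
        if not 0.0 < self.score_threshold <= 1.0:
            raise ValueError("score_threshold must lie in (0, 1]")
        if self.degree_constraint < 1:
            raise ValueError("degree_constraint must be >= 1")
        if self.adjustment not in ("bh", "raw"):
            raise ValueError("adjustment must be 'bh' or 'raw'")


def config_from_file(path: str | Path) -> AnalysisConfig:
    """Parse a flat ``key = value`` config file (one pair per line, ``#``
    comments allowed; list values comma-separated)."""
    raw: dict[str, str] = {}
    with Path(path).open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            key, _, value = line.partition("=")
            raw[key.strip()] = value.strip()
    selection = SelectionSpec(
        mirna_ids=tuple(
            s.strip() for s in raw.pop("select_mirnas", "").split(",") if s.strip()
        ),
        family_names=tuple(
            s.strip() for s in raw.pop("select_families", "").split(",") if s.strip()
        ),
        top_n=int(raw.pop("select_top_n")) if "select_top_n" in raw else None,
        min_dereg_targets=(
            int(raw.pop("select_min_dereg_targets"))
            if "select_min_dereg_targets" in raw
            else None
        ),
    )
    kwargs: dict = {"selection": selection}
    strings = {
        "mirna_dereg_path",
        "gene_dereg_path",
        "interactions_path",
        "categories_path",
        "families_path",
        "disease",
        "adjustment",
        "out_dir",
    }
    for key, value in raw.items():
        if key in strings:
            kwargs[key] = value
        elif key in ("score_threshold", "alpha"):
            kwargs[key] = float(value)
        elif key in ("degree_constraint", "randomize_reps", "seed"):
            kwargs[key] = int(value)
        else:
            raise ValueError(f"unknown config key {key!r}")
    return AnalysisConfig(**kwargs)


@dataclass
class ResultsBundle:
    config: AnalysisConfig
    summary: pd.DataFrame
    independence: independence.IndependenceResult
    randomization_p: float | None
    gene_sets: enrichment.GeneSets
    venn: enrichment.VennResult
    ora_a: list[enrichment.OraResult]
    ora_b: list[enrichment.OraResult]
    ora_c: list[enrichment.OraResult]
    overlap: enrichment.OverlapCodeTable
    family: list[enrichment.OraResult]
    ranking: list[tuple[str, int]]
    selection: network.SubnetworkSelection
    focused_ora: list[enrichment.OraResult]
    pubmed: dict[str, str]
    paths: dict[str, str]


def summarize_inputs(
    mir_dereg: DeregulationSet, gene_dereg: DeregulationSet
) -> pd.DataFrame:
    """Up/down/total counts per entity class (the run's input summary)."""
    rows = []
    for dereg in (gene_dereg, mir_dereg):
        label = "genes" if dereg.entity_class == GENE else "miRNAs"
        rows.append(
            {
                "entity": label,
                "up": dereg.n_up,
                "down": dereg.n_down,
                "sum": dereg.n_up + dereg.n_down,
            }
        )
    return pd.DataFrame(rows, columns=["entity", "up", "down", "sum"])


def _ora_frame(results: list[enrichment.OraResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "category": r.category,
                "test_hits": r.test_hits,
                "test_size": r.test_size,
                "ref_hits": r.ref_hits,
                "ref_size": r.ref_size,
                "expected": round(r.expected, 6),
                "direction": r.direction,
                "p_raw": f"{r.p_raw:.6g}",
                "p_adj": f"{r.p_adj:.6g}",
                "preselected": r.preselected,
            }
            for r in results
        ],
        columns=[
            "category",
            "test_hits",
            "test_size",
            "ref_hits",
            "ref_size",
            "expected",
            "direction",
            "p_raw",
            "p_adj",
            "preselected",
        ],
    )


def _resolve_selection(
    spec: SelectionSpec,
    graph,
    families: FamilyDB | None,
    ranking: list[tuple[str, int]],
) -> frozenset[str]:
    mirna_vertices = network.mirna_nodes(graph)
    if spec.mirna_ids:
        return frozenset(m.lower() for m in spec.mirna_ids)
    if spec.family_names:
        if families is None:
            raise ValueError("family selection requested but no family file given")
        chosen: set[str] = set()
        for name in spec.family_names:
            if name not in families.families:
                raise KeyError(f"unknown family {name!r}")
            chosen |= set(families.members_normalized(name))
        return frozenset(chosen & mirna_vertices)
    if spec.top_n is not None:
        return frozenset(m for m, _ in ranking[: spec.top_n])
    if spec.min_dereg_targets is not None:
        return frozenset(m for m, c in ranking if c >= spec.min_dereg_targets)
    return frozenset(mirna_vertices)


def _stage(name: str):
    """Decorator-free stage guard: returns a context manager flagging failures."""
    class _Guard:
        def __init__(self, out_dir: Path | None):
            self.out_dir = out_dir

        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                if self.out_dir is not None:
                    (self.out_dir / "FAILED").write_text(
                        f"stage {name!r} failed: {exc}\n"
                    )
                raise PipelineError(f"[{name}] {exc}") from exc
    return _Guard


def run_full_analysis(config: AnalysisConfig) -> ResultsBundle:
    """Execute every stage in order and write the results bundle to disk."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    log_lines = [f"{k}\t{v}" for k, v in sorted(asdict(config).items())]

    with _stage("parse-inputs")(out_dir):
        mir_dereg = read_deregulation_file(config.mirna_dereg_path, MIRNA)
        gene_dereg = read_deregulation_file(config.gene_dereg_path, GENE)
        interactions = read_interaction_table(
            config.interactions_path, config.score_threshold
        )
        categories = read_gmt(config.categories_path)
        families = (
            read_mifam(config.families_path) if config.families_path else None
        )

    with _stage("input-summary")(out_dir):
        summary = summarize_inputs(mir_dereg, gene_dereg)
        paths["summary"] = str(out_dir / "input_summary.tsv")
        summary.to_csv(paths["summary"], sep="\t", index=False)

    with _stage("independence")(out_dir):
        table = independence.build_contingency(mir_dereg, gene_dereg, interactions)
        indep = independence.chi_squared_independence(table, gene_dereg)
        paths["contingency"] = str(out_dir / "contingency.tsv")
        Path(paths["contingency"]).write_text(table.to_text() + "\n")
        randomization_p = None
        if config.randomize_reps > 0 and indep.p_allowed:
            randomization_p = independence.randomization_pvalue(
                mir_dereg,
                gene_dereg,
                interactions,
                config.randomize_reps,
                config.seed,
            )

    with _stage("venn")(out_dir):
        gene_sets = enrichment.derive_gene_sets(mir_dereg, gene_dereg, interactions)
        venn = enrichment.venn_overlap(
            gene_sets.dereg_genes,
            gene_sets.targets_of_dereg_mirs,
            gene_sets.reference,
        )

    use_raw = config.adjustment == "raw"
    with _stage("ora")(out_dir):
        ora_a = enrichment.ora(
            gene_sets.targets_of_dereg_mirs, gene_sets.reference, categories,
            alpha=config.alpha,
        )
        ora_b = enrichment.ora(
            gene_sets.dereg_targets_of_dereg_mirs, gene_sets.reference, categories,
            alpha=config.alpha,
        )
        ora_c = enrichment.ora(
            gene_sets.dereg_genes, gene_sets.reference, categories,
            alpha=config.alpha,
        )
        for label, results in (("A", ora_a), ("B", ora_b), ("C", ora_c)):
            key = f"ora_{label.lower()}"
            paths[key] = str(out_dir / f"{key}.tsv")
            _ora_frame(results).to_csv(paths[key], sep="\t", index=False)

    with _stage("overlap-codes")(out_dir):
        overlap = enrichment.overlap_codes(
            ora_a, ora_b, ora_c, alpha=config.alpha, use_raw=use_raw
        )
        paths["overlap_codes"] = str(out_dir / "overlap_codes.tsv")
        frame = pd.DataFrame(
            [
                {
                    "category": name,
                    "related_sets": ", ".join(membership),
                    "code": code,
                }
                for name, (membership, code) in sorted(overlap.rows.items())
            ],
            columns=["category", "related_sets", "code"],
        )
        frame.to_csv(paths["overlap_codes"], sep="\t", index=False)

    with _stage("family-ora")(out_dir):
        family = []
        if families is not None:
            family = enrichment.family_ora(
                mir_dereg,
                families,
                interactions.mirna_ids,
                alpha=config.alpha,
            )
        paths["family_ora"] = str(out_dir / "family_ora.tsv")
        _ora_frame(family).to_csv(paths["family_ora"], sep="\t", index=False)

    with _stage("network")(out_dir):
        graph = network.build_graph(
            mir_dereg, gene_dereg, interactions, disease=config.disease
        )
        ranking = network.rank_mirnas_by_dereg_targets(graph)
        paths["mirna_ranking"] = str(out_dir / "mirna_ranking.tsv")
        pd.DataFrame(ranking, columns=["mirna", "dereg_targets"]).to_csv(
            paths["mirna_ranking"], sep="\t", index=False
        )
        chosen = _resolve_selection(config.selection, graph, families, ranking)
        selection = network.select_subnetwork(
            graph, chosen, k=config.degree_constraint
        )
        paths["graphml"] = str(out_dir / "subnetwork.graphml")
        paths["sif"] = str(out_dir / "subnetwork.sif")
        paths["gene_list"] = str(out_dir / "subnetwork_genes.txt")
        write_graphml(selection.graph, paths["graphml"])
        write_sif(selection.graph, paths["sif"])
        genes = network.subnetwork_gene_list(selection)
        network.write_gene_list(genes, paths["gene_list"])

    with _stage("focused-ora")(out_dir):
        focused = enrichment.ora(
            frozenset(genes), gene_sets.reference, categories, alpha=config.alpha
        ) if genes else []
        paths["focused_ora"] = str(out_dir / "focused_ora.tsv")
        _ora_frame(focused).to_csv(paths["focused_ora"], sep="\t", index=False)

    with _stage("pubmed")(out_dir):
        pubmed: dict[str, str] = {}
        if config.disease:
            entities = sorted(selection.retained_mirnas) + genes
            if entities:
                for mode in ("inclusive", "exclusive"):
                    pubmed[mode] = network.pubmed_query(
                        entities[:20], config.disease, mode
                    )
            paths["pubmed"] = str(out_dir / "pubmed_queries.txt")
            with open(paths["pubmed"], "w") as handle:
                for mode in sorted(pubmed):
                    handle.write(f"{mode}\t{pubmed[mode]}\n")

    bundle = ResultsBundle(
        config=config,
        summary=summary,
        independence=indep,
        randomization_p=randomization_p,
        gene_sets=gene_sets,
        venn=venn,
        ora_a=ora_a,
        ora_b=ora_b,
        ora_c=ora_c,
        overlap=overlap,
        family=family,
        ranking=ranking,
        selection=selection,
        focused_ora=focused,
        pubmed=pubmed,
        paths=paths,
    )

    with _stage("report")(out_dir):
        paths["report"] = str(out_dir / "report.md")
        Path(paths["report"]).write_text(render_report(bundle))
        paths["run_log"] = str(out_dir / "run.log")
        Path(paths["run_log"]).write_text("\n".join(log_lines) + "\n")
    return bundle


def render_report(bundle: ResultsBundle) -> str:
    """Assemble the Markdown report from the per-stage results (no
    re-computation: every number is read off the bundle)."""
    lines: list[str] = ["# Joint miRNA/mRNA deregulation analysis", ""]

    lines += ["## Input summary", ""]
    lines += [bundle.summary.to_csv(sep="\t", index=False).rstrip(), ""]

    indep = bundle.independence
    lines += ["## Independence of miRNA and target deregulation", ""]
    lines += [indep.table.to_text(), ""]
    lines.append(f"chi-squared statistic: {indep.chi2:.6g} (df = {indep.df})")
    if indep.p_allowed:
        lines.append(f"p-value: {indep.p_value:.6g}")
    else:
        lines.append(f"p-value not computed: {indep.refusal_reason}")
    lines.append(f"same-direction interaction pairs: {indep.same_direction_count}")
    if bundle.randomization_p is not None:
        lines.append(f"randomization p-value: {bundle.randomization_p:.6g}")
    lines.append("")

    venn = bundle.venn
    lines += ["## Overlap of deregulated genes and targets of deregulated miRNAs", ""]
    lines.append(
        f"targets only: {venn.left}\toverlap: {venn.overlap}\t"
        f"deregulated only: {venn.right}\tuniverse: {venn.universe_size}"
    )
    lines.append(f"hypergeometric p-value: {venn.p_value:.6g}")
    lines.append("")

    for label, results, title in (
        ("a", bundle.ora_a, "targets of deregulated miRNAs"),
        ("b", bundle.ora_b, "deregulated targets of deregulated miRNAs"),
        ("c", bundle.ora_c, "deregulated genes"),
    ):
        lines += [f"## ORA ({label}): {title}", ""]
        sig = [r for r in results if r.p_adj < bundle.config.alpha]
        lines.append(f"categories tested: {len(results)}; significant: {len(sig)}")
        for r in sig:
            lines.append(
                f"- {r.category}: {r.test_hits}/{r.test_size} vs expected "
                f"{r.expected:.2f} ({r.direction}), p_adj = {r.p_adj:.3g}"
            )
        lines.append("")

    lines += ["## Categories significant in at least two analyses", ""]
    if bundle.overlap.rows:
        lines.append("category\trelated_sets\tcode")
        for name, (membership, code) in sorted(bundle.overlap.rows.items()):
            lines.append(f"{name}\t{', '.join(membership)}\t{code}")
    else:
        lines.append("(none)")
    lines.append("")

    lines += ["## miRNA-family enrichment", ""]
    pre = [r for r in bundle.family if r.preselected]
    lines.append(f"families tested: {len(bundle.family)}; preselected: {len(pre)}")
    for r in pre:
        lines.append(f"- {r.category}: p_adj = {r.p_adj:.3g}")
    lines.append("")

    lines += ["## miRNAs ranked by deregulated targets", ""]
    for mirna, count in bundle.ranking:
        lines.append(f"{mirna}\t{count}")
    lines.append("")

    sel = bundle.selection
    lines += ["## Subnetwork selection", ""]
    lines.append(
        f"chosen miRNAs: {len(sel.chosen_mirnas)}; retained: "
        f"{len(sel.retained_mirnas)}; degree constraint k = {sel.degree_constraint}; "
        f"genes retained: {len(sel.genes)}"
    )
    lines.append("")

    lines += ["## Focused ORA on the selected genes", ""]
    sig = [r for r in bundle.focused_ora if r.p_adj < bundle.config.alpha]
    lines.append(
        f"categories tested: {len(bundle.focused_ora)}; significant: {len(sig)}"
    )
    for r in sig:
        lines.append(f"- {r.category}: p_adj = {r.p_adj:.3g} ({r.direction})")
    lines.append("")

    if bundle.pubmed:
        lines += ["## PubMed queries", ""]
        for mode in sorted(bundle.pubmed):
            lines.append(f"{mode}\t{bundle.pubmed[mode]}")
        lines.append("")

    return "\n".join(lines)
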