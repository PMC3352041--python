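# mirlink

Joint statistical analysis of deregulated microRNAs and deregulated mRNAs
connected by a miRNA → target interaction table.

MicroRNAs (miRNAs) are short non-coding RNAs that repress target mRNAs by
complementary binding; when a disease shifts the expression of both layers,
the interesting biology often sits in their *joint* pattern — deregulated
miRNAs whose predicted targets are themselves deregulated. `mirlink` takes
two discrete deregulation calls (a list of miRNAs and a list of genes, each
marked up-regulated `1` or down-regulated `-1`), a scored target-prediction
table, gene-set categories (GMT) and miRNA families (miFam), and runs a
coordinated battery of analyses for systems-biology users who have already
done their differential-expression step elsewhere.

## What it computes

**Independence of deregulation.** Every interaction pair (miRNA *m*, target
gene *g*) is classified by the status of its two ends — up, down, or not
deregulated — into a 3×3 contingency table *N*. Pearson's statistic

χ² = Σᵢⱼ (Nᵢⱼ − Eᵢⱼ)² / Eᵢⱼ,  Eᵢⱼ = Nᵢ₊ N₊ⱼ / N₊₊

is referred to the χ² distribution with (3−1)(3−1) = 4 degrees of freedom.
When the gene list is one-directional (or a table margin is zero) the
p-value is refused and the table alone is reported. Because interaction
pairs are not independent draws (a high-degree gene repeats its status
across many pairs), a label-randomization control re-draws *which*
identifiers carry the observed up/down pattern and recomputes χ², giving an
empirical null that respects the pairing structure.

**Set overlap and enrichment.** Three coordinated over-representation
analyses (ORA) are run against the same categories with the hypergeometric
test: for a category with *K* members in a reference of size *N* and a test
set of size *n* with *k* hits, the one-sided tail P(X ≥ k) (or P(X ≤ k) for
depletion) is doubled and Benjamini–Hochberg-adjusted within the analysis.
The three test sets are **a** targets of deregulated miRNAs, **b**
deregulated targets of deregulated miRNAs (= a ∩ c), and **c** deregulated
genes; a Venn overlap of a and c with its own hypergeometric p-value comes
first. Categories significant in ≥ 2 analyses receive a file-permission
style *code* over the pairwise overlaps (a∩b = 1, b∩c = 2, a∩c = 4, all
three = 7). miRNA families (miFam) get the same ORA with miRNAs in place of
genes; significant families are preselected for the network step.

**Regulatory network.** A multipartite graph over miRNA, gene and optional
disease vertex classes admits only deregulated miRNAs with at least one
deregulated target (and those targets). From a chosen miRNA set, the
degree constraint *k* keeps genes targeted by at least *k* of the chosen
miRNAs; the selection exports to GraphML/SIF, yields a gene list for a
focused ORA, and can be turned into PubMed query URLs.

**Synthetic scenarios.** `mirlink.simulate` generates complete five-file
input bundles with tunable miRNA→target deregulation dependence and a
planted enriched category and family, so calibration, power and recovery
are all measurable offline.

## Worked example

```
mirlink simulate --seed 3 --out demo
mirlink independence --mirnas demo/mirna_deregulation.tsv \
    --genes demo/gene_deregulation.tsv --interactions demo/interactions.tsv
```

prints (the demo scenario plants no dependence, so a non-significant
p-value is the expected outcome):

```
miRNA\target	up	down	not
up	15	31	163
down	31	25	155
not	145	137	898
chi2	7.25755
df	4
p	0.122888
same_direction_pairs	40
```

Of the 1600 retained interaction pairs, 40 join a miRNA and a target
deregulated in the same direction, and the 3×3 table shows no evidence of
association between miRNA and target status (χ² = 7.26, df = 4, p = 0.12 —
consistent with the scenario's independent deregulation). The full
workflow, `mirlink run --config run.cfg`, writes every table plus a
Markdown report; `mirlink enrich` and `mirlink network` run the enrichment
and network stages separately.

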