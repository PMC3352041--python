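# Methods

This note documents the statistical model behind `mirlink`, the choices
made where the design was genuinely open, and what the synthetic scenarios
do and do not establish about real data.

## Inputs and identifier handling

The tool consumes discrete deregulation calls, not expression values: two
two-column lists (identifier, `1`/`-1`), a tab-delimited miRNA→gene table
with an optional prediction p-value, categories in GMT, families in the
miFam dialect. Gene symbols are compared upper-cased; miRNA identifiers
keep their case for display but compare case-insensitively (community
usage mixes `hsa-miR-17` and `hsa-mir-17` freely). Both the ASCII hyphen
and the Unicode minus are accepted in the down-regulation token, since
lists copied out of spreadsheets and PDFs contain either. Conflicting
directions for one identifier are an error rather than last-wins: a silent
overwrite would hide a real problem in the upstream differential-expression
step. Duplicate interaction rows collapse to the smallest prediction
p-value. The organism is inferred from the miRNA id prefix (`hsa`, `mmu`,
`dre`, …) and must be uniform across the table.

Prediction filtering keeps rows with score strictly below the threshold
(default 0.01, the conventional level for microCosm-style tables); rows
without a score — e.g. experimentally validated pairs — are always kept.

## Independence of miRNA and target deregulation

Each retained interaction pair is classified by the status of both ends
into a 3×3 table (up/down/not × up/down/not). We use the plain Pearson
statistic with df = (3−1)(3−1) = 4 and no continuity correction; with the
pair counts this test is normally applied to, small-sample corrections are
immaterial, and the plain statistic is the one whose null distribution the
randomization control reproduces.

Two refusal rules replace exceptions: the p-value is withheld (the table is
still reported) when (i) the uploaded gene list contains a single direction
— the direction dimension is then degenerate and a small p would be an
artefact of the marginal imbalance rather than evidence of coupling — or
(ii) a row/column margin is zero, where expected counts are undefined. In
the Pearson sum, cells with zero expected count contribute zero; this
matters only for the randomization replicates, where a margin can
occasionally empty.

**Caveat: pairs are not independent draws.** A gene targeted by d miRNAs
contributes d pairs that share its status, and symmetrically for miRNAs.
The χ²₄ reference distribution ignores this clustering, so with heavy
target multiplicity (real prediction tables average ~14 predicted
regulators per gene) the analytic p-value is anti-conservative. This is
precisely why the randomization control exists: it keeps the up/down
pattern fixed, resamples which identifiers carry it (uniformly without
replacement from the ids in the interaction table united with the uploaded
ids — both miRNA and gene sides), and recomputes χ², yielding an empirical
p with add-one smoothing, (1 + #{χ²_rand ≥ χ²_obs}) / (n + 1). For real
analyses the randomization p is the one to trust; the analytic p is a fast
first look.

## Over-representation analyses

All set statistics are exact hypergeometric tails, summed in log space
(log-gamma terms combined with log-sum-exp) so that extreme tails do not
underflow. Two-sidedness: the observed hit count is compared to its
expectation n·K/N; the matching one-sided tail is doubled and capped at 1.
Doubling is the standard conservative two-sided convention for discrete
tests and reports enrichment and depletion symmetrically.

Multiple testing uses Benjamini–Hochberg within each analysis (each ORA
table is one family of hypotheses). A `raw` mode flags significance on
unadjusted p-values instead, for comparison with tools that report raw
ORA p-values at α = 0.05.

The reference universe is the union of the genes in the interaction table
and the uploaded deregulated genes; nothing else about the experiment is
known to the tool, and this is the population from which both the test
sets and the categories are restricted. The Venn p-value is the upper
hypergeometric tail of the overlap between deregulated genes and targets
of deregulated miRNAs within this universe.

**Overlap codes.** A category significant in at least two of the three
analyses gets a bitmask over the pairwise overlaps: a∩b = 1, b∩c = 2,
a∩c = 4; membership in all three yields 7, so the achievable codes are
exactly {1, 2, 4, 7}. (A verbal description of this scheme that circulates
alongside it suggests a code of "3" for a two-overlap pattern; no pure
bitmask produces 3 from two analyses, and we implement the code table
consistently with the worked examples — b,c → 2 and a,b,c → 7.)

Family enrichment is the identical statistic over miRNA ids, with the
miRNA universe = table ids ∪ uploaded ids; families with adjusted p < 0.05
are marked preselected, the natural starting selection for the network
step. Since b = a ∩ c by construction, the three analyses are positively
dependent; BH is applied within each analysis, and the overlap code is a
descriptive summary, not a joint test.

## Regulatory network

The graph is r-partite over {miRNA, gene, disease} with edges only between
classes. Admission rule: deregulated miRNAs with ≥ 1 deregulated predicted
target, and exactly those targets. The disease class holds at most one
vertex — the user's label — connected to every other vertex; it exists so
that exports and PubMed queries carry the disease context, not because any
data populates it.

The degree constraint k keeps genes adjacent to at least k of the *chosen*
miRNAs (not of all miRNAs — choosing 8 miRNAs and k = 3 can retain fewer
than 8, because a chosen miRNA none of whose targets survives is dropped
from the drawing). Monotonicity holds by construction: genes(k+1) ⊆
genes(k). Exports carry `node_class`, `regulation` (+1/−1/0) and `degree`
(miRNA–gene edges in the current graph) so external viewers can reproduce
the usual conventions (shape by class, colour by direction, size by
degree); gene nodes in a selection additionally carry `selection_degree`,
the count restricted to the chosen miRNAs, since either sizing convention
is defensible.

PubMed queries: `inclusive` ORs the entity terms, `exclusive` ANDs them,
and either clause is ANDed with the disease; the string is URL-encoded and
no network call is made. These two semantics are this package's reading of
the otherwise undefined terms.

## Synthetic scenarios

`ScenarioSpec` defaults define the desk-scale study conditions used
throughout the tests: 40 miRNAs, 800 genes, 1600 scored interactions, 25%
of each entity class deregulated (≥ 200 deregulated entities), 30
categories with one planted at odds ratio 10 toward deregulated genes, 8
disjoint families with one planted inside the deregulated miRNA set, and
25% decoy interaction rows at or above the score threshold. The average
target multiplicity is deliberately low (~2 pairs per gene) so that the
pair-level independence assumption of the analytic χ² approximately holds
and its calibration can be measured meaningfully; scaling multiplicity up
to prediction-table levels re-introduces the clustering discussed above,
which is a property of real data the calibration result does *not* cover.

Dependence is planted per gene: a target of ≥ 1 deregulated miRNA is
deregulated with probability p = p₀ + ρ(1−p₀) (ρ = `dependence_strength`),
others with p₀; directions are symmetric by default, with a
`direction_bias` knob to couple a target's direction to its regulator's.
When exact up/down counts are requested (to reproduce a published input
summary, e.g. 2550/2218 genes and 16/17 miRNAs), deregulated identities
are instead drawn by weighted sampling without replacement (Gumbel-top-k)
with weights equal to the odds ratio implied by ρ — exact counts and
per-gene Bernoulli draws are mutually exclusive, so the weighted draw is
the count-preserving analogue. The planted family is *contained* in the
deregulated miRNAs rather than sampled with an odds knob: at these family
sizes (5 of 40) an odds-based plant leaves the realized enrichment too
variable to serve as ground truth.

The fixed-seed "melanoma-shaped" bundle reproduces only the *shape* of the
published melanoma inputs (1000 miRNAs, 20000 genes, 279,225 retained
interactions, the Table-style 16/17 and 2550/2218 splits) with ρ = 0; it
is a synthetic stand-in for exercising the full pipeline deterministically,
not a reconstruction of the original data, and its p-values carry no
biological meaning.

What passing tests show: the implementation's correctness against
enumeration oracles, the calibration and power of the independence test
under the stated conditions, and recovery of planted structure. What they
do not show: behaviour under real identifier noise (aliases, retired
miRBase names), real category-size distributions, or the clustered
multiplicity of genuine prediction tables.

## Numerical and procedural details

- Hypergeometric tails: exact log-space summation; agreement with
  exhaustive enumeration to 1e−12 for populations ≤ 12 is asserted in the
  test suite, and against scipy's distribution functions elsewhere.
- BH adjustment delegates to statsmodels (`fdr_bh`); inputs outside (0, 1]
  are rejected.
- Ties in the miRNA ranking break lexicographically, making all outputs
  order-deterministic; every writer sorts its rows, so regenerating any
  file from the same seed is byte-identical.
- Empty objects are legal wherever they can arise (empty graph, empty
  selection, empty family file); an empty interaction table *after score
  filtering* is an error, since every downstream statistic is defined over
  it.
- The pipeline aborts on the first failing stage with a stage-named error
  and leaves a `FAILED` marker file in the output directory.
- Problem sizes in the test suite (hundreds of scenario replicates at the
  default scenario shape; one full-pipeline determinism check at the
  melanoma shape) were chosen so the whole battery reflects the operating
  characteristics above while remaining a desk-scale run.
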