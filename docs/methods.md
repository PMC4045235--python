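# Methods

## The procedure

The pipeline integrates two independent evidence layers around a disease
protein complex.  The proteomic layer starts from per-bait IP/MS hit tables
(bait, prey, matched-peptide count).  Preys with fewer than `min_peptides`
(default 2) matched peptides are discarded; any prey observed in a
no-antibody control pulldown — at *any* peptide count, the most stringent
reading of background subtraction — is removed; the per-bait survivors are
intersected, so a prey must be recovered with every bait to enter the common
interactor set.  The stage order (filter → subtract → intersect) is fixed.
Bait proteins recovered as preys are kept by default (`exclude_self_hits`
toggles this), since self- and cross-recovery of complex members is genuine
signal.

The transcriptomic layer selects probes by fold change alone:
FC = mean(case)/mean(control) on the linear scale (log2 input is anti-logged
first), a probe passes at FC ≥ t or FC ≤ 1/t with t > 1 (default 2,
boundaries inclusive; the rule is invariant under swapping case and control
up to FC → 1/FC), and probes collapse to genes by union — a gene is selected
if any of its probes passes.  Probes with a zero control mean are flagged
undefined and excluded; no variance filter or significance test is applied.

Both layers are projected onto a reference interaction database (undirected,
classes physical/genetic/both; self-loops dropped, duplicate pairs merged
with class conflict resolved to "both").  The common interactor set builds an
*induced* network (edges with both endpoints in the set); the
differentially expressed genes build a *first-neighbour* network (edges with
at least one endpoint in the gene list, plus the partners they pull in).
The first-neighbour rule is this package's explicit, testable definition of
an "inferred" network; plugin-specific expansion rules in legacy network
tools are undocumented, which is why originally reported node/edge counts of
such networks are not treated as reproducible targets.  Node counts are
reported both as totals (isolated seeds retained) and as non-isolated
counts; the conventional "network of N proteins" phrasing corresponds to the
latter.

The two layers are intersected: k = |common set ∩ transcriptomic-network
nodes|, scored by the hypergeometric upper tail P(X ≥ k) with n = |query|,
K = |reference|, N = |universe|.  The universe is configurable
(`annotation_union`: all genes in the probe annotation; `interaction_db_nodes`;
or an explicit integer) because overlap p-values are meaningless without a
stated background; the choice is surfaced in the report.  The induced
subgraph on the overlap set is the final disease interactome; its
non-isolated nodes are the query for pathway enrichment and the input to
module detection.

## Hypergeometric tail and multiple testing

The tail Σᵢ₌ₖ^min(n,K) C(K,i)·C(N−K,n−i)/C(N,n) is accumulated from
log-pmf terms with log-sum-exp, and both p and log₁₀ p are returned: observed
overlaps can sit so deep in the tail that p underflows double precision, in
which case p is stored as 0.0 and log₁₀ p carries the value.  k = 0 returns
exactly 1.  The implementation is checked in the tests against exhaustive
subset enumeration in exact rational arithmetic for every (k, K, n, N) with
N ≤ 10, and for monotonicity in k and the n↔K symmetry.

Enrichment conditions on the union of collection members by default (the
annotation-universe convention of pathway services); gene sets and the query
are clipped to the universe.  "Adjusted probability" is Benjamini–Hochberg
across all sets in the collection (`bonferroni` and `none` selectable);
the adjustment is delegated to statsmodels and cross-checked in the tests
against a direct step-up implementation.  Rows sort by unadjusted p with
ties broken by set name.

## Module landscape

Community centrality is defined as truncated influence,
c(i) = Σ_{d(i,j)≤r} (r+1−d(i,j))·w(j), with r ≥ 1 (default 2) and node
weights w = degree (default) or 1; the self term is included.  Each node
ascends to the neighbour with the maximal (score, lexicographically smaller
identifier) key when that key strictly exceeds its own, else it is a module
centre.  The key order is strict and total, so ascent cannot cycle, plateaus
drain deterministically toward the smallest identifier, and the whole
assignment is reproducible bit-for-bit.  A consequence of the tie-break worth
knowing: two *adjacent* equal-score local maxima merge into one centre (the
smaller identifier wins), so two equal cliques joined by a direct bridge edge
yield one centre, whereas the same cliques joined through an intermediate
bridge node yield two.  Centres are verified in the tests against brute-force
local-maxima enumeration on every labelled graph with ≤ 5 nodes and on random
6–7-node graphs.

This landscape is a deliberately simple, fully specified replacement for
plugin-based module detection whose variant and parameters are typically
unrecorded; module *counts* from such tools are therefore not comparison
targets.

## Synthetic study design

The generator emulates the study conditions the analysis assumes, with
defaults fixed at: 2000 genes; preferential-attachment reference graph
(2 edges per new node, ~70/20/10% physical/genetic/both edge classes); a
planted connected disease module of 60 genes densified with internal edge
probability 0.15; 3 baits and 3 no-antibody controls; true-interactor and
contaminant peptide counts Poisson(mean 4) floored at 2; a 150-protein
contaminant pool sampled into each bait at rate 0.6 and into each control at
rate 0.5; 100 bait-specific noise preys per bait, 60% at a single peptide;
4 case and 3 control expression samples, 2 probes per gene plus 20
unannotated probes, log-normal baselines, multiplicative log-normal noise
(σ = 0.25) and a planted ±2.5-fold effect on the module plus 40 distractor
genes with random sign; 50 gene sets of 10–40 members with one planted set
whose module fraction is enrichment_factor × module_size / n_genes
(default factor 8, i.e. roughly a quarter of its members from the module —
of the order seen in real pathway tables, where mapped counts run an order
of magnitude above chance expectation).

Each noise channel exists to make one published filtering rule consequential:
single-peptide preys die at the peptide filter, pool contaminants at
background subtraction, bait-specific preys at the intersection, and flat
genes at the fold-change cut.  In the noise-free limit every stage is exact
(common set = planted module, selected genes = planted genes, final network
= the module's induced subgraph), and this is asserted in the tests.  All
generators are pure functions of (config, seed) via per-stage RNG streams,
so outputs are byte-identical across runs.

What the generator does *not* emulate: peptide-count dependence on protein
abundance or length, correlated probe noise and batch effects, degree bias
of literature-curated interaction databases, overlapping pathway hierarchies,
and symbol-mapping loss between omics layers.  Passing recovery tests on
synthetic data therefore demonstrates correctness of the pipeline's logic
under its stated model, not performance on real IP/MS or microarray data.

## Numerical and design choices

* Identifiers are trimmed, upper-cased, and passed through an optional
  alias→canonical synonym table whose chains are collapsed at construction
  (cycles rejected), making normalization idempotent.
* Duplicate (bait, prey) rows merge by maximum peptide count — the best
  evidence for the pair is retained.
* Probe selection at the threshold boundary is inclusive on both sides;
  fold changes are ratios of means, not means of ratios.
* The overlap p-value is reported with its log10; `OverlapTestResult` only
  stores p = 0.0 when the exact value underflows doubles, and the log10
  carries the magnitude.
* The pipeline report contains config echo and seed but no wall-clock
  provenance, so identical inputs give byte-identical reports.
* Problem sizes used by the recovery benchmarks (20 replicates of the
  default 2000-gene design; 1000 null draws for calibration) were chosen to
  estimate the reported rates to within a few percent while keeping the
  whole suite fast on a laptop.

## Known limitations

* Universe choice dominates overlap/enrichment p-values; published
  probabilities computed against unstated service-side universes cannot be
  reproduced and are not asserted.
* Fold-change-only selection with n = 4 vs 3 samples has no error control;
  it is faithful to the emulated protocol, not a recommendation.
* The landscape's degree weighting favours hubs; on hub-dominated graphs
  module centres track degree more than community structure.
* GraphML is the only export that preserves isolated nodes; SIF writes them
  as bare node lines and edge-TSV round-trips node sets only through edge
  endpoints.
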