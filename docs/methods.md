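# Methods

This note records the model, the numerical choices, and the places where
the design was genuinely open, so results can be interpreted and the
defaults revisited deliberately.

## Model and assumptions

`netconcord` treats a trait × cell-type analysis as a search for connected
gene sets on a fixed interaction network whose nodes carry two calibrated
weights: a genetic weight v_g derived from gene-level GWAS p-values and an
expression weight v_s derived from the cell type's pseudo-bulk profile.
The underlying assumptions:

- Gene-level GWAS scores are available upstream (e.g. MAGMA); SNP-level
  modelling, LD and gene-based testing are out of scope.
- Cell types are defined upstream (clustering/annotation is out of
  scope); a cell type is summarized by the per-gene mean of per-cell
  log(CPM+1). No cross-cell-type specificity contrast is computed: the
  test asks whether GWAS signal and *this* cell type's expression are
  concordant, independently of other cell types.
- The network is any undirected gene–gene relation; results are
  interpreted relative to that choice. Gene identifiers must be
  pre-harmonized across inputs (exact string match; no alias service).

## Weight calibration

Raw `-log10 p` and mean `log(CPM+1)` are both right-skewed with heavy
upper tails (extreme GWAS loci, highly expressed genes). Summing raw
weights would let one system's tail dominate every module. Calibration:

1. **Box-Cox** with λ from the grid −2.00, −1.95, …, 2.00, maximizing a
   Shapiro–Wilk W computed on a stride-thinned subsample of ≤ 5000 points
   (deterministic; W is the conventional omnibus normality statistic —
   the selection criterion was an open design point). If the argmax is
   exactly 0 the second-best λ is taken, so the transform is always a
   genuine power. The output is shifted to restore the input median.
2. **INT anchor + quantile normalization.** An inverse-normal reference
   vector (Blom offset c = 3/8 — another unstated constant; Blom is the
   standard choice) joins the two Box-Cox vectors in an N × 3 matrix;
   standard quantile normalization (each rank replaced by the
   across-column mean of that rank's order statistics, average ranks for
   ties) yields v_g and v_s. Both vectors then share one distribution and
   keep their within-system rank order exactly; tied inputs receive
   identical outputs, so results do not depend on input row order.

Numerical details: ε = 1e-6 is added before Box-Cox so exact zeros
(p = 1 genes; silent genes) stay in the domain; the offset is rank-neutral.
Mean-based quantile normalization is *not* exactly idempotent (its fixed
point under iteration is the INT reference itself); re-running calibration
preserves ranks and the common distribution but shifts values slightly.
This is inherent to the standard algorithm and harmless — calibration runs
exactly once per pair.

Note the calibrated scale inherits its location from the raw medians
(GWAS median ≈ 0.3, expression median is several log-CPM units), so
calibrated weights are mostly positive; module scores therefore grow with
size, which is exactly why the null is size-stratified (below).

## Module score and search

m = m_g + m_s − |m_g − m_s|/√2 with m_g = Σv_g/√|v|, m_s = Σv_s/√|v|.
The penalty is the Euclidean deviation of (m_g, m_s) from its common mean
and makes a one-sided module pay for its imbalance.

The search from each seed alternates expansion and trimming:

- **Expansion**: among neighbours of the current module, add the one
  maximizing the new score iff new_m > m·(1 + r1). Ties break to the
  lexicographically smaller gene (determinism).
- **Trim** (after every successful expansion): leaves — nodes with degree
  ≤ 1 in the module-induced subgraph, whose removal cannot disconnect the
  rest — are examined in increasing v_g + v_s; the first one whose removal
  keeps the score above m·(1 − r2) is removed, and the pass repeats until
  no leaf qualifies.
- **Non-positive scores**: the multiplicative tests are ill-behaved at
  m ≤ 0, so there any strict improvement is accepted (expansion) or
  required (trim).
- **Termination**: when no neighbour qualifies. Because
  (1 + r1)(1 − r2) can be < 1, an add/remove oscillation is possible in
  principle; a visited-state set stops the loop on the first repeat.

Modules from different seeds frequently coincide; each distinct gene set
is reported once with its seed multiplicity `n_seeds`, and the seed itself
may be absent from its own final module.

**r1/r2 defaults.** The thresholds govern how aggressively modules grow
and how concise they stay. Following the method's own calibration recipe
— examine random modules from the permutation search — a grid over
r1, r2 ∈ {0.05, 0.1, 0.2} on permuted fixture networks showed r2 = 0.05
leaves random modules large (median 4 genes, p90 ≈ 7), r2 = 0.2 collapses
nearly everything to singletons, and (r1, r2) = (0.1, 0.1) yields concise
but non-degenerate modules (median 2, p90 ≈ 6). (0.1, 0.1) is the
default; both are configurable.

## Permutation null and module significance

v_g and v_s are permuted over nodes independently (the graph is
untouched), and the full every-seed search re-runs per round; rounds stop
when every module size observed in the real data has at least
`min_random_per_size` (default 1000) random modules, or at
`max_virtual_rounds`. The pool is seed-level (one outcome per seed per
round, rounds pooled without deduplication). Per size stratum the mean
and sample standard deviation (n − 1) of m, m_g, m_s normalize real
module scores into z_m, z_g, z_s; empirical p-values are the fraction of
the pooled (likewise normalized) random scores strictly above the
module's — p = 0 is attainable, matching the plain empirical estimator.

Deficient strata (sizes the random search cannot fill before the round
cap) borrow the nearest populated size, larger on ties, and affected
modules are flagged — real modules are never silently dropped. A stratum
with zero variance is a hard error (it signals a degenerate search, e.g.
a graph small enough that every round rediscovers the same module).

## Association: the concordance proportional test

Cutoffs Q95(z_g) and Q95(z_s) are the 95th percentiles (linear, type-7
interpolation) of the *normalized* random pool. Concordant = both
exceeded. Raw-score cutoffs were considered and rejected: m_g and m_s
both scale with √size, so raw cutoffs are dominated by large random
modules, and a one-sided signal that merely inflates module size drags
the second raw score over its cutoff too — in simulation this produced
strong false associations for plantings with an effect in only one weight
system. Size-normalized cutoffs restore that control.

Counting is seed-level on both sides (A = seeds searched, B = seeds ×
rounds): the test compares how often *a search* lands on a concordant
module in real versus permuted data, which is also what makes a single
strong module detectable — many seeds converge on it. The pooled
two-proportion z with cutoff 5 (≈ Bonferroni for a 40 × 437 grid via
Φ⁻¹(0.05/17,480)) declares association. Degenerate pools (p̂ ∈ {0, 1})
report z = 0 with a flag rather than NaN.

Reported subnetwork per associated pair: union of modules that are both
significant (p_m, p_g, p_s < 0.05) and concordant, at least 2 genes,
with network-induced edges; GSEA NES (weight exponent 1, gene-label
permutations, sign-matched normalization, default 1000 permutations)
summarizes it against each weight system and the combined NES is their
mean. Trait similarity is the mean Jaccard of module genes over cell
types where both traits have genes; pairs with no shared cell type are
missing, not zero.

## Working-network filters

In order, each edge attributed to the first filter that removes it:
excluded interaction types (`in-complex-with` by default — complex
members are co-expressed by construction) and self-loops at read time;
then the exclusion list (housekeeping/ribosomal genes, user-supplied);
then same-chromosome pairs whose gene-body gap is ≤ 50 kb (the SNP
flank window — such pairs share proximal SNPs and would double-count
signal; overlapping genes have gap 0 and are dropped; the anchor choice
gene-body-gap vs TSS was open, gene bodies chosen to match the flank's
purpose); then edges touching the MHC (chr6:26–34 Mb, hg19, any overlap,
half-open) whose LD structure inflates gene scores. Genes without
coordinates pass the location filters with a logged count.

Expression filters: cell types under 30 cells are dropped first, then
genes with zero counts in strictly more than 95% of the remaining cells
(denominator = all retained cells of the panel, an interpretation
choice). CPM is computed per cell (sum 1e6), log is natural by default
(base 2 configurable), profiles are means over cells of a type.

## Synthetic data generator

The generator emulates all five inputs with controllable ground truth:

- GWAS p ~ Uniform(0,1); planted genes get −log10 p shifted by the
  module's GWAS effect (+2 by default study conditions, which lands
  planted genes around +2 SD of the calibrated scale, interleaved with
  the null tail as real signals are).
- Counts ~ negative binomial (dispersion 2) with log-normal gene means
  (meanlog 1.5, sdlog 1.0) — the right-skewed, zero-inflated shape the
  calibration expects; planted genes' means are multiplied by
  exp(expression effect) in one designated cell type. 3 cell types × 60
  cells by default: enough cells for stable profiles while keeping runs
  fast.
- Network: Barabási–Albert preferential attachment (m = 2), planted
  modules wired as connected subgraphs (random spanning tree plus a few
  internal edges) at *random* node indices — early BA indices are hubs,
  and pinning special genes there would make the fixture an artifact of
  index order.
- Coordinates place genes 1 Mb apart except deliberate 40-kb pairs and a
  fake chr6 MHC block; those genes, and the exclusion-list genes, are
  never planted, so filters are exercised without silently removing the
  signal.

What the generator does **not** emulate: LD between genes, eQTL
structure, batch effects, cell-type hierarchies, or realistic network
topology beyond the degree distribution. Passing tests therefore show
the machinery is correct and calibrated under idealized noise, not that
real-data power matches these numbers.

## Known limitations

- Greedy search absorbs occasional "rider" genes (bridges on the path a
  search took, or chance jointly-high neighbours); the leaf-only trim
  cannot remove them once they are internal nodes. Reported subnetworks
  are therefore modest supersets of the core signal.
- At small gene universes (a few hundred genes) the seed-level
  proportional test is powerful enough to detect *chance* correlation
  between the two weight systems (sampling correlation ~ 1/√N), so
  occasional z > 5 calls on unplanted data are expected at that scale;
  the effect vanishes for genome-scale universes.
- Problem sizes in the test suite and acceptance script (300–500 gene
  universes, 200 random modules per size stratum, 8–12 permutation
  rounds, 20 replicate seeds) are the package's desk-scale study
  conditions; genome-scale runs use the 1000-per-stratum default.
- Empirical p-values use the plain strictly-greater estimator with no
  pseudocount, so p = 0 occurs; treat reported zeros as "< 1/B".
- The virtual null depends on the calibrated weights and is recomputed
  per (trait, cell type); its cost dominates the runtime.
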