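# Methods

`ginpipe` implements a comparative genetic-interaction-network (GIN)
analysis for arrayed yeast screens: several genetic backgrounds are probed
with drugs (chemical-genetic screens) and with SGA query genes
(double-mutant screens), and the resulting interaction profiles are compared
by hit-set algebra, hierarchical clustering, network community structure,
topological centrality, and functional enrichment. This note records the
models, the parameters that matter, and the design decisions taken where
the procedure was genuinely open.

## Screen model and interaction scoring

A screen compares a treated plate set to its paired control. Colony sizes
are modeled as multiplicative-lognormal:

    size = mu * exp(sigma * Z),   sigma^2 = ln(1 + CV^2)

with `mu` the condition median. Treatment scales `mu` by `(1 - inhibition)`
globally (default 0.4 — drug doses are chosen to inhibit growth by roughly
40%) and by `(1 - effect_size)` additionally for hypersensitive deletions
(default effect 0.5). The default colony-noise CV is 0.10 and the baseline
median 500 size units (strictly positive and right-skewed, like measured
colony areas). Border positions (outermost row/column) receive a fixed 1.25x
growth advantage on both plates: it cancels in ratios but would bias a naive
plate median, which is why normalization and Z-spread estimation exclude
borders while border genes are still scored.

Scoring: each plate is divided by its interior median; per-gene ratios
`r = treated/control` (replicate positions collapsed by median) are
log2-transformed and converted to Z-scores with the sign convention that
growth defects are positive:

    z(g) = (center - log2 r(g)) / spread,  p = 1 - Phi(z)

Hits require `Z > 2.0` and `P < 0.05` jointly; since the one-sided p at
Z = 2 is about 0.023, the conjunction is Z-driven. `center`/`spread` default
to mean/SD over non-border scorable genes. A robust mode
(median / 1.4826 MAD) exists but is not the default: with a few percent of
genuine strong hits in the tail, the plain SD is slightly inflated by the
hits themselves, which suppresses false positives at Z > 2; the MAD is blind
to that contamination and delivers the fully calibrated ~2.3% one-sided
false-positive rate. Under the default conditions (1536 genes, 50 planted
hits, effect 0.5, CV 0.10) the expected operating point is ~0.97 sensitivity
and ~0.998 specificity, which the acceptance suite verifies by simulation.

Genes within ±25 kb of an SGA query locus on its chromosome are marked
`linkage`-excluded and removed from hit lists (meiotic linkage, not
epistasis, suppresses those double mutants). No window size is canonical;
25 kb is configurable (`linkage_window_bp`).

## Augmented networks

Primary hits seed an augmented GIN: every gene within hop distance <= 2 of a
seed in the stringently filtered global network (|score| >= 0.12 inclusive,
p < 0.05 strict) joins the node set, and the induced subgraph is kept. The
"two levels of distance (path length 3)" phrasing is read as <= 2 hops
(three nodes on the path); `hop_bound` is configurable against the
alternative reading. Node strength uses |weight| throughout — negative
interaction scores are evidence of connection, not of distance.

Seed-centrality validation: the Mann-Whitney rank test compares seed genes'
centralities to a pooled null of 1000 equally sized uniform random gene
sets. The inclusion flag (p < 0.05) is recorded in the manifest but does not
gate the synthetic pipeline: planted hits are drawn uniformly, so by
construction they are topologically unexceptional and nearly every
synthetic network would be excluded. On real screens the flag should be
enforced by the analyst.

## Communities

Modularity of a partition, on absolute weights with `2m = sum_ij |A_ij|`:

    M = (1/2m) sum_ij [ A_ij - k_i k_j / 2m ] delta(c_i, c_j)

The Louvain heuristic maximizes M in two phases (seeded, shuffled local
moves; community aggregation) until no move improves M. The incremental
gain of a single move is maintained algebraically and is contract-bound to
equal the direct before/after recomputation of M to 1e-10 — the published
rendering of the increment formula is typographically ambiguous, and the
identity, not the typography, defines the implementation. Because the sweep
order matters, `louvain_partition` runs 4 deterministic restarts and keeps
the best partition; with a fixed seed the output is reproducible. Community
ids are renumbered 0..k-1 by descending size. Resolution is fixed at 1.0 by
default and exposed.

Greedy Louvain is a local-move heuristic: on small graphs with weak or
near-zero modularity structure it can settle on single-move-optimal
partitions measurably below the exhaustive-partition optimum (reference
implementations return the same partitions on such graphs). Wherever the
optimum is substantial (>= 0.3 on <= 8-node test graphs) the implementation
matches it; tests bound the absolute gap by 0.05 elsewhere.

Community function is summarized by GO coverage — for a term,
`100 * overlap / term_total_in_dataset`, with a one-sided hypergeometric p
given (community size, term total, dataset size) — and by motif searches
(`find_comembership`) that report whether a gene set (e.g. the UPR sensors)
shares one community per network, and if not, whether the stragglers sit in
an adjacent (edge-sharing) community.

## Centralities and bottlenecks

Betweenness is pair-normalized Brandes betweenness on unweighted hops;
closeness is Wasserman-Faust component-scaled; eigenvector centrality is
the unit-norm leading eigenvector of |A| on the largest component (power
iteration on |A| + I, tolerance 1e-12; the shift guarantees convergence on
bipartite components), zero elsewhere. Hops rather than 1/|w| distances are
the default because interaction scores are not metric lengths; a weighted
mode exists. Shortest-path machinery runs through igraph for speed at the
2000-node scale, with all normalization done explicitly; the test suite
checks all three centralities against literal path-enumeration /
dense-eigensolver oracles.

Genes are clustered in standardized (BC, CC, EC) space. The cluster-count
scan fits k-means and Ward agglomerative clusterings for k = 2..10 and
reports silhouette and Calinski-Harabasz scores (optimum = silhouette
argmax, ties to smaller k). The operational labeling runs k-means at k = 4
(n_init = 50, seeded) and orders clusters alpha..delta by ascending mean
betweenness, so delta is always the bottleneck-rich cluster; top-n (default
5) genes per centrality are reported with lexicographic tie-breaks.

## Enrichment, FDR, semantics, SAFE

Over-representation uses the one-sided hypergeometric tail with
dataset-restricted term totals; terms without study overlap are skipped.
Correction is the two-stage Benjamini-Krieger-Yekutieli FDR: stage-1 BH at
q' = alpha/(1+alpha) estimates m0 as the non-rejections, stage-2 BH at
q'·m/m0 sets the flags. The rejection set, not a monotone adjusted p,
defines the procedure (the adjusted values reported can drop below raw p).
Note the two-stage set is a superset of BH at q' — not necessarily of BH at
alpha.

Lin similarity between terms is `2·IC(MICA)/(IC(t1)+IC(t2))` with IC
estimated from the analysis dataset's own annotation corpus (the uniqueness
values of interest come from the result lists themselves, not genome-wide
GO; the corpus is configurable). Uniqueness of a term in a result set is one
minus its mean Lin similarity to the other terms; singletons score 1.

SAFE-style enrichment scores map neighborhoods instead of communities: edge
lengths are Euclidean distances in a 2D embedding, a node's neighborhood is
everything within map-weighted shortest-path radius 7.5 (embedding units —
the radius is meaningful only relative to the map scale), and each
(node, attribute) pair gets a hypergeometric p plus the normalized score
`min(-log10 p, 16)/16`. When no embedding is supplied the pipeline uses a
seeded Fruchterman-Reingold layout rescaled so the median edge length is
4 map units, making the 7.5 radius a local neighborhood of roughly 5-15% of
nodes; with a user-supplied embedding results are deterministic. Region
semantics (e.g. an 18-region functional map) enter as a user-supplied
attribute file, not code.

## Profile clustering

Profiles are stacked into a screens x genes matrix of per-gene min-max
normalized Z-scores (constant columns to 0; the normalization is
idempotent). Genes unscored in a profile are masked and imputed with the
column median for distance computation only — dropping every gene missing
anywhere would discard most of the genome across 20 screens. Rows are
clustered agglomeratively (Euclidean, average linkage by default; Ward and
correlation distance available) and cut into 3 clades by default. Focused
panels re-normalize a column subset and cluster both profiles and genes;
"contiguous genes" around a focal gene means nearest dendrogram neighbors,
not chromosomal neighbors. Dendrograms export as Newick.

## Synthetic data: what it emulates, and what it does not

The generator provides the full study's inputs with known truth: 1536- (or
384-) density plates with border flags; lognormal colony noise; a
planted-partition (SBM) global network of 2000 genes in 10 blocks
(p_in = 0.06, p_out = 0.002, mean filtered degree ~10) with weights
|N(0.25, 0.1)|, 10% negated, straddling the 0.12 cutoff, and edge p-values
~ Beta(0.5, 10); and a rooted GO-like DAG (120 terms, depth 4, leaf
annotation rate 1%) whose leaf terms preferentially annotate one network
block (bias 0.5), planting function-module correlation. Sixteen synthetic
chromosomes with uniform 12-kb gene spacing make linkage windows exercisable.

The default study design plants the published tallies as ground truth: five
probes (two statins, three sterol-pathway query genes) by four backgrounds;
per-probe hit unions of 288/283/339/181/425 split into cores common to all
four backgrounds (4/3/0/1/5), pair-shared genes, one atorvastatin gene
shared only by the three non-reference backgrounds, and unique hits — 1660
planted screen hits in total. The 10-block global network was chosen so that
augmented GINs land at the ~2000-node scale with community counts in the
7-14-per-network band (~200 over 20 panels). What the generator does *not*
emulate: spatial plate artifacts beyond the border effect, batch effects,
linkage beyond a hard window, hub-dominated degree distributions of real
GINs, and realistic GO DAG shape. Passing tests therefore demonstrate
correctness of the computations and recoverability under the stated noise
model — not performance on real screens.

## Numerical conventions and degenerate inputs

- Plate normalization requires >= 50% occupancy and a positive interior
  median; constant ratio vectors raise a degenerate-distribution error.
- Zero-control colonies yield `missing`, never infinite ratios.
- Edge filter boundaries: |weight| >= cutoff inclusive, p < cutoff strict.
- Modularity is undefined (error) on edgeless graphs; self-loops are
  outside the network contract and ignored.
- Eigenvector centrality of a singleton largest component is 1.
- Ties: silhouette optimum -> smaller k; community renumbering -> smaller
  lexicographic member; top-gene ranking -> gene name.
- All stochastic stages take integer seeds; per-cell seeds are derived from
  the study seed, and rerunning a study byte-reproduces every artifact hash
  in the manifest.

## Problem sizes

Default test and acceptance runs use 1536-gene screens, a 2000-node global
network, 20 study cells, 1000-draw bootstraps, 500-move gain-identity
checks, 200 small-graph centrality oracles and 20-seed recovery
simulations; the full study completes in a few minutes on one CPU. These
sizes are the package's standard verification conditions.
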