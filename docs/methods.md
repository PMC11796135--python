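# Methods

This note documents the statistical procedures, the default parameters and
why they were chosen, the synthetic-data model behind all planted-truth
tests, and the package's numerical conventions and limitations.

## Network model and neighborhoods

A gene network is a simple directed graph over gene identifiers
(regulator → target).  Identifiers are compared case-sensitively after
trimming surrounding whitespace; no symbol-alias resolution is attempted.
Self-loops and duplicate edges are dropped at construction with a logged
count, so invariants hold for every `GeneNetwork` instance.

The n-layer neighborhood of a seed set is the seeds plus every node
reachable within ≤ n edge traversals, by breadth-first search following
out-edges (`downstream`), in-edges (`upstream`) or both (`undirected`).
Seeds absent from the network are retained in the result but not expanded,
so the layer-0 "Gene" cell of the overlap grid reproduces the raw list
overlap even when some signature genes are not in the network.  The result
is monotone in the layer count, and the undirected neighborhood contains
both directed ones.

"Connected subnetwork" means the largest **weakly** connected component of
the induced subgraph — edge direction is ignored for connectivity, the
standard convention when displaying causal-network neighborhoods, which
mix regulator and target edges.  Size ties are broken deterministically by
the component containing the lexicographically smallest gene.

## Layered Fisher-exact overlap

For two gene sets A, B in a universe of U genes with overlap k, the cell
records the cross-product odds ratio

    OR = k (U − |A| − |B| + k) / ((|A| − k)(|B| − k))

(0 when k = 0, +∞ when k > 0 meets a zero denominator) and the one-sided
enrichment p-value P(X ≥ k) for X hypergeometric — enrichment is the
question the heatmap answers, so the upper tail is the default.  Reported
−log10 p is capped at 300 to keep TSV outputs finite.

**Universe choice.** For the "Gene" cell the universe is the network node
set united with both signatures; for expansion layers it is the network
node set (expanded sets are intersected with it).  For stand-alone list
comparisons the universe is caller-supplied; the worked example uses a
whole-transcriptome-scale universe of 24,700 genes, under which two lists
of 359 and 223 genes sharing 9 give OR = 2.899 and p = 0.0055.  The odds
ratio is insensitive to the universe only at fixed margins — callers
comparing lists from different platforms should supply the measured-gene
universe explicitly.

The "2c" layer applies the largest-connected-component reduction to each
signature's two-layer neighborhood *separately* and then overlaps the two
components.  The alternative reading (component of the overlap) gives a
subset of the same information; the per-component form was chosen because
it also yields the two objects whose intersection is the bridge
subnetwork, which is reported with per-node signature-membership
annotations.

## Key-driver and bridging analysis

For each node with at least `min_neighborhood` (default 5) genes in its
h-layer neighborhood (node itself excluded; h = 2 by default, downstream —
drivers regulate, they are not regulated by their signature), the overlap
of neighborhood and signature is scored against the hypergeometric null on
the universe of all other nodes.  Benjamini–Hochberg adjustment runs per
signature across tested nodes.  Ranking is by p ascending, then
neighborhood size descending (bigger regulons win ties), then gene id.

The bridge score is max(p_A, p_B): an intersection–union test that is
small only when the node is enriched for **both** signatures.  A node is
flagged as a bridging driver when both adjusted values pass α = 0.05.  The
minimum-size filter, h, and α are declared package defaults in the spirit
of common key-driver practice, not estimates of any published
parameterization; all are configurable.

## Driver-associated signature

Pearson r between every gene and the driver across samples, with the exact
two-sided p from t = r√((n−2)/(1−r²)) on n−2 degrees of freedom.  Missing
entries are removed pairwise with a per-gene minimum of 20 complete pairs;
zero-variance genes are skipped with a logged count.  BH adjustment is
joint over all tested genes (not per sign), then genes partition into a
positive set (r ≥ r_min, q ≤ q_max) and a negative set (r ≤ −r_min,
q ≤ q_max).  Defaults r_min = 0.3, q_max = 0.05, min 20 samples — a
conventional moderate-effect screen; the counts such a screen returns
depend entirely on the panel, so they are outputs, never targets.
Negating the driver row swaps the two sets exactly, and both sets shrink
monotonically as thresholds tighten; both properties are tested.

## Scoring and stratification

Sample score = mean of row-z-scored positive genes − mean of row-z-scored
negative genes; z-scores use the population (n) denominator (irrelevant to
ordering, fixed for bit-reproducibility).  Stratification into k = 2
(low/high) or k = 3 (low/mid/high) groups:

- `kmeans-1d` — exact 1-dimensional k-means by dynamic programming over
  the sorted scores (O(k n²) with prefix sums), groups labeled by
  ascending center.  Default for k = 2 because it permits the unequal
  group sizes real cohorts show.
- `quantile` — rank-based cut at 1/k quantiles (stable argsort, contiguous
  rank blocks), so ties resolve by sample order and sizes are as equal as
  possible.  Default for k = 3 (tertiles).

Both assignments are monotone in score.  The DP optimum is verified
against exhaustive partition search for n ≤ 12.

## Survival

Kaplan–Meier product-limit estimator over distinct event times; censored
records leave the risk set after their time point, and events precede
censorings at tied times (the standard convention).  Median survival is
the first time with S(t) ≤ 0.5, undefined when never reached.  The
two-group log-rank test accumulates, at each distinct event time with d
events and n at risk (n_A in group A), observed minus expected events
o − d·n_A/n and the hypergeometric variance d(n_A/n)(1−n_A/n)(n−d)/(n−1);
(Σ(o−e))²/Σv is referred to χ²₁.  Zero total variance raises a degenerate-
test error rather than returning a silent NaN.  Only two-group tests are
provided — the comparisons this pipeline makes are all pairwise (treated
vs untreated, per stratum) — and there is no covariate stratification or
Cox modeling.  The implementation is cross-checked against `lifelines` in
the test suite and calibrated by simulation (type-I error 0.03–0.07 at
α = 0.05 with n = 100 per arm; power > 0.9 at hazard ratio 2 with ~30%
censoring).

## Synthetic data with planted truth

The generator emulates the statistical structure the analysis assumes,
at a scale where a full pipeline replicate runs in well under a second.

**Network** (defaults n = 2,000 genes, attach = 2, driver_out = 40,
depth = 2): nodes are index-ordered and edges only run from earlier to
later indices, so the graph is a DAG by construction, like the Bayesian
networks it stands in for.  Node 0 is the planted driver with 40 direct
targets, each rooting a depth-2 chain.  Every other node receives 2
backbone in-edges from earlier nodes sampled with probability ∝ (backbone
out-degree + 5).  The additive smoothing and the exclusion of planted
edges from the attachment weights are deliberate: pure linear preferential
attachment lets early hubs' two-layer cones blanket most of a graph this
size, which both destroys the locality the analysis exploits and makes
"downstream of the driver" a near-universal property.  With smoothing, the
driver's realized two-layer cone covers ~500–650 nodes (a quarter to a
third of the graph) — large enough to host the signature draws, small
enough to stay specific.

**Signatures** (defaults 359 and 223 genes, matching the published list
sizes; frac_in_cone = 0.5): each signature draws half its genes from the
driver's two-layer cone — disjointly between the two signatures where the
cone allows, so the *raw* overlap stays small (≈10–20 genes) — and the
rest uniformly from non-cone genes.  This is the planted-bridge geometry:
weak direct overlap, strong two-layer convergence.  With frac_in_cone = 0
the construction is a negative control and the driver is no longer
reliably top-ranked.

**Expression** (defaults 500 samples, β = 0.6, unit noise, 249 positive /
124 negative effect genes — the published associated-gene counts used as
generator defaults): driver row standard normal; effect rows ±β·driver
plus noise; everything else pure noise.  An optional `group_delta` plants
a two-population cohort (driver mean ±Δ/2; fraction high = 1/3, the
published 45/90 proportion).  Stratification checks use Δ = 4: the
composite score concentrates around the driver value, so the expected
assignment error is ≈ Φ(−Δ/2) ≈ 2.3%, comfortably inside the 95%-agreement
requirement while still leaving genuine misclassifications to detect.

**Survival**: exponential event times with per-(group, arm) hazards in
events/month, independent exponential censoring (default rate
0.02/month) plus administrative censoring at 60 months.  The default
hazard table gives the untreated arms 0.10/month everywhere and halves the
hazard under treatment only in the low group — the qualitative pattern the
stratification is meant to expose (treatment benefit confined to
driver-low patients).

What the generator does **not** emulate: count-based RNA-seq noise
(negative binomial, library-size effects), batch structure, correlated
co-regulation beyond the single driver, cyclic feedback, or non-
proportional hazards.  Passing tests demonstrate that the pipeline's
machinery recovers planted structure of the assumed form; they say nothing
about robustness to those real-data complications.

## Numerical conventions

- Hypergeometric tails come from `scipy.stats.hypergeom.sf`; the test
  suite verifies them against exact integer-arithmetic summation to 1e-10
  exhaustively for universes ≤ 30 and on 2,000 seeded tables with
  universes up to 500 (the full table space at U ≤ 500 is ~10⁹ cases;
  the sweep is exhaustive where enumeration is cheap and dense elsewhere).
- All generators and the pipeline are bit-reproducible from (parameters,
  seed); result tables are written with sorted rows and fixed float
  formatting, and the determinism test compares output bytes.
- Problem sizes in the acceptance checks (50 network replicates, 3
  association replicates, 25 stratification cohorts, 1,000 + 500 log-rank
  simulations) are the package's declared study conditions; each completes
  in seconds at the default scale.

## Known limitations

- Edge-list TSV cannot represent isolated nodes; GraphML round-trips the
  full node set.
- The odds ratio is the unconditional cross-product ratio, not the
  conditional maximum-likelihood estimate some Fisher-test implementations
  report; p-values agree either way.
- Key-driver results depend on the chosen h, direction and minimum
  neighborhood size; no attempt is made to infer a published
  parameterization.
- The quantile method's equal-size groups are a design choice, not an
  inference; use k-means when group sizes should follow the score
  distribution.
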