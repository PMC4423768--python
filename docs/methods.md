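# Methods

## The question the package answers

Given an undirected protein–protein interaction (PPI) network and one or
more named gene groups (for example, sets of genes whose expression a
treatment significantly enriched), `netdisrupt` asks whether the groups
occupy *important* positions in the network — more connected, more
central, more of a bottleneck — compared with each other and with the
rest of the network. "Importance" is operationalized as ten per-node
topology indices, and the comparisons use statistics chosen for the
heavy right skew and outliers that centrality indices always show.

## Network construction

The analysis network is either read directly from a SIF/TSV edge list or
built by expanding a seed gene list to all nodes within graph distance
two (primary neighbors and neighbors-of-neighbors) of any seed. The
expansion keeps the *induced* subgraph — every edge of the parent
network between two retained nodes — because interaction evidence
between two secondary neighbors is still interaction evidence; a
`induced=False` mode retains only edges linking consecutive BFS shells
for users who want the sparser convention. Identifier matching is
case-sensitive after whitespace trimming, with a case-insensitive option
because gene-symbol files vary in capitalization. Self-loops and
duplicate edges are dropped on read (public PPI exports contain both);
edge direction is ignored.

When gene groups overlap (one gene enriched by two treatments), the
shared genes are removed from *every* group before testing, so the
groups entering any comparison are pairwise disjoint; the non-enriched
background is the set of network nodes belonging to no treatment group.

## The ten indices

degree; closeness centrality (1/mean shortest-path distance);
betweenness centrality (Brandes accumulation; normalized per connected
component by (Nc−1)(Nc−2)/2); stress (raw count of shortest paths
through a node — never normalized, following NetworkAnalyzer);
eccentricity; radiality ((diam + 1 − asp)/diam per component); average
shortest path length; clustering coefficient; neighborhood connectivity
(mean neighbor degree); topological coefficient (mean normalized
neighbor-sharing J(v,m)/k(v) over nodes m sharing ≥ 1 neighbor with v,
J counting shared neighbors plus 1 when v–m is itself an edge).

All distance-based indices are computed within each node's connected
component; unreachable pairs contribute nothing. The alternative —
treating unreachable distances as N — was rejected because it
manufactures signal out of component sizes. Isolated nodes get 0 for
every distance index (rather than missing values) so the statistics
layer never sees holes; a `drop_isolated` flag removes them instead.
Betweenness and stress come from a single Brandes-style sweep with two
dependency accumulations (the fractional one for betweenness, a
path-count one for stress), vectorized over BFS frontiers; the full
ten-index table on a 2000-node, 10⁴-edge network takes a couple of
seconds, and the O(nm) scaling keeps 10⁴-node networks in the minutes
range on one CPU.

## Univariate statistics

**Location.** The Hodges–Lehmann pseudomedian: the median of all
n(n+1)/2 Walsh averages (xᵢ+xⱼ)/2, i ≤ j. It is exact here: small
samples materialize the averages; large samples (above n = 2000) run a
value-space binary search over the implicit pairwise-mean matrix with an
O(n log n) two-pointer count per step, collecting only the candidate
window — so a 7000-node index column (~26M Walsh averages) needs no
quadratic memory. Uncertainty is a bootstrap standard error (default
B = 1000 resamples, seeded).

**Group vs background.** Each group's index values are tested against
the *whole-network* pseudomedian with an upper-tailed one-sample
Wilcoxon signed-rank test (the one-sample Wilcoxon of the applied
literature; identical to R's one-sample `wilcox.test`). Zero
differences are dropped (Wilcoxon's rule, R's default); tied absolute
differences get mid-ranks; the null is exact for small tie-free samples
and a tie- and continuity-corrected normal approximation otherwise.

**Group vs group.** The Brunner–Dette–Munk (BDM) ANOVA-type rank
statistic, which tolerates both non-normality and unequal variances
(Kruskal–Wallis does not): mid-ranks of the pooled sample give relative
effects p̂ᵢ = (R̄ᵢ − ½)/N, contrasted by F* = N/tr(MV)·p̂ᵀMp̂ with
M = I − J/a and V the diagonal rank-variance matrix, referred either to
an F distribution with Box-approximation df (tr(MV)²/tr(MVMV) and
tr(MV)²/Σ(MV)ᵢᵢ²/(nᵢ−1)) or, by default, to a label-permutation null
(n_perm = 10,000, matching the multivariate layer, with the add-one
convention p = (1+hits)/(1+n_perm) so p is never 0). Internally groups
are re-ordered by a canonical key before the statistic and the
permutation stream are computed, so results are bit-identical no matter
how the caller orders the groups. Pairwise BDM tests are *protected*:
run only when the omnibus p ≤ α, then Holm-adjusted.

## Multivariate statistics

Cases are nodes, variables are the ten indices on their raw
non-negative scales (no standardization by default; a range-[0,1]
column-scaling flag exists because the raw stress/betweenness scales
otherwise dominate the resemblance). Resemblance is Steinhaus
(Bray–Curtis) dissimilarity Dᵢⱼ = Σ|xᵢᵥ−xⱼᵥ|/Σ(xᵢᵥ+xⱼᵥ) ∈ [0,1]; a pair
of all-zero rows is defined as distance 0.

**PERMANOVA.** SS_total = Σ_{i<j}D²ᵢⱼ/N partitioned into within-group
and among-group parts; pseudo-F = (SS_among/(a−1))/(SS_within/(N−a));
p from 10,000 seeded permutations of the label vector (add-one
convention). Permutations are evaluated in batches against stacked
one-hot indicator matrices (one BLAS product per batch), which keeps
10,000 permutations on ~2000 cases around half a minute. In the
Euclidean univariate limit the pseudo-F equals the classical one-way
ANOVA F (a test asserts this to 1e−9). Pairwise PERMANOVAs are plain
two-group runs on the subset, protected by the omnibus at α and
Holm-adjusted (the family-wise method is Holm for consistency with the
univariate layer).

**NMDS.** Non-metric multidimensional scaling by SMACOF with isotonic
(PAVA, ties averaged) regression of configuration distances on
dissimilarity ranks, minimizing Kruskal stress-1; defaults k = 2,
20 random starts, max_iter = 500, tol = 1e−7. The lowest-stress
solution is returned, centered and rotated to principal axes. Each
index is then regressed (with intercept) on the axis scores; the R² of
that fit scales the variable's arrow and the normalized coefficient
vector gives its direction.

**Backgrounds.** Two distinct backgrounds exist deliberately: the
Wilcoxon reference is the whole-network pseudomedian, while the
multivariate contrast includes the non-enriched nodes as an explicit
factor level; the pipeline exposes both (plus an explicit node-list
file) because they answer different questions and the background subset
entering a multivariate analysis is an analysis choice, not something
derivable from the network. The univariate BDM omnibus compares
treatment groups only, using the background solely as the Wilcoxon
reference.

## Synthetic studies

The generator emulates what the analysis assumes about real inputs:
sparse scale-free networks (Barabási–Albert preferential attachment,
default m = 5, so mean degree ≈ 10 with median well below the mean —
the right-skewed regime of PPI neighborhood expansions; Erdős–Rényi is
retained as a null-shape control) and groups sampled without
replacement with weight (index+1)^b, so b = 0 is uniform and larger b
concentrates groups on high-centrality nodes while zero-index nodes
stay sampleable. The `fish` template draws three disjoint treatment
groups of sizes (36, 89, 14) with biases (b, b, 0); the `human`
template draws two groups of ~130 sharing about half their members
before overlap exclusion. Everything is bit-reproducible from the seed.

What the generator does *not* emulate: the correlated modular structure
of real interactomes (complexes, pathways), annotation bias in curated
databases, or biologically meaningful group membership — so passing
calibration on synthetic studies demonstrates that the statistics are
correct and the effects recoverable, not that any particular biological
claim holds.

**Calibration.** Power and type-I error of the group-vs-network Wilcoxon
are estimated by replicate sampling. Each replicate redraws the network
by default: integer degrees put a point mass of Walsh averages exactly
at the network pseudomedian, and the sign balance around that atom is a
per-network accident, so the rejection rate *conditional on one
network* can wander by several percentage points; redrawing estimates
the procedure's marginal error rate under the generator's conditions.
At the default conditions (BA 2000/m=5, groups of 50) degree-biased
groups with b = 2 are detected essentially always, and unbiased groups
reject at close to the nominal 5%.

## Numerical choices and degenerate inputs

- Permutation p-values always use (1+hits)/(1+n_perm).
- PERMANOVA with SS_within = 0 reports +inf pseudo-F with the
  permutation p still defined.
- BDM with zero rank variance everywhere (all values tied) returns
  F* = 0, p = 1.
- Wilcoxon with every value equal to the reference warns and returns
  p = 1.
- Pseudomedian selection falls back to the window midpoint when massive
  ties shrink the search interval below ~1e−12 relative width.
- Index tables are written with %.17g and re-read with round-trip float
  parsing, so TSV round-trips are bit-exact.
- All RNG use goes through `numpy.random.default_rng` with sub-seeds
  derived from the run seed by CRC-tagged `SeedSequence`s, making whole
  pipeline runs byte-identical across reruns.

## Problem sizes used in the shipped checks

The test suite and the acceptance script size their simulations for a
single CPU: brute-force oracle comparisons use graphs of ≤ 25 nodes;
calibration uses 200 replicates of groups of 50 on 2000-node networks;
the full synthetic study runs 10,000-permutation tests on ~1940 cases
and NMDS (20 starts) on ~440 cases. These sizes reproduce the study
shapes at workstation scale; all are free parameters.

## Known limitations

- Exact reproduction of any published analysis requires that study's
  actual network and group files; degrees-of-freedom layouts can be
  checked without them, index values cannot.
- The one-sample signed-rank test is only asymptotically calibrated for
  asymmetric, heavily tied index distributions (see Calibration above);
  its nominal level is approximate on strongly discrete indices.
- NMDS stress minima are heuristic (SMACOF restarts); with few cases
  and near-degenerate dissimilarities different starts can tie at
  different local minima.
- No edge-level indices, directed variants, PERMDISP/beta-dispersion,
  or db-RDA.
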