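# Methods

## Measurement model and preprocessing

A measurement is one multiplex RT-PCR reaction estimating the relative
abundance of 35 mRNAs in one RNA sample. The design takes, per cell and
time point, two biological samples (distant sites of the same
plasmodium) and two technical replicates per sample, giving four values
per gene and cell-timepoint. All values are strictly positive relative
abundances in arbitrary units.

Normalization is applied in a fixed order:

1. **Per-measurement median.** Every measurement's values are divided
   by their median over the gene panel, removing differences in RNA
   input and reaction efficiency. Even gene counts use the
   mean-of-central-pair median (the convention of R's `median`, which
   the original pipelines in this field use); the choice matters only
   for even panel subsets and is therefore documented rather than
   configurable.
2. **Per-gene geometric mean.** Every gene's values are divided by the
   gene's geometric mean over all retained values, computed in log
   space. Values at or below a detection floor are rejected by default;
   an optional floor mode clamps instead, for data sets where
   sub-detection values are expected.

Replicate QC works on the x-fold deviation `r = x / mean(group)` with
group either the technical pair (2 members) or the cell-timepoint quad
(4 members). For a pair, `r₁ + r₂ = 2` holds exactly, so the deviation
distribution mirrors about 1 on the fold scale (`q_p + q_{1−p} = 2`)
and is right-bounded at 2 — its log2 is accordingly left-skewed, which
is the expected shape, not an artifact. Quantile tables report
probability, log2 quantile and fold quantile (`fold = 2^log2` exactly,
by monotonicity of the transform).

Two filters follow:

- **Two-fold pair rule.** A gene's replicate pair in which either value
  deviates more than two-fold from the pair mean is removed entirely; a
  discordant pair identifies neither member as the trustworthy one, so
  removing only one value would bias the survivor.
- **Plasmodium exclusion.** For each sample, the per-gene ratio of its
  profile (replicate means) to the median profile of its *sibling*
  samples — other samples of the same cell and time point, leaving the
  tested sample out — is summarized by its median over genes; if that
  score exceeds the fold limit in either direction for any sample, the
  whole plasmodium is excluded. Leave-one-out siblings are essential:
  with two samples, comparing a sample to a median that includes itself
  can never exceed a factor of two. The criterion is stated only
  verbally in the source literature; this operationalization is the
  package's own.

Aggregation takes the arithmetic mean of the surviving replicate values
per gene and cell-timepoint and records how many values contributed.
When QC removes all four values of a gene (possible when the failed-
reaction model is on), the end-to-end pipeline refills the hole with
the gene's geometric mean — a neutral value on the normalized scale —
so the downstream design stays complete; the hole count is logged.

## SIMPROF discretization

Expression vectors are clustered hierarchically (SciPy linkage;
average, complete or single) on Euclidean distances of log10 values —
log10 matching the scale on which profiles are displayed. The
dendrogram is cut top-down by the similarity-profile permutation test:
for a candidate group, the statistic is

    π = Σ_k | d_(k) − E_perm[d_(k)] |

over the ordered pairwise dissimilarities, with the expectation
estimated from permutations that shuffle each gene independently across
rows (the exchangeable "no multivariate structure" null); the p-value
is the add-one fraction of a second permutation set whose π reaches the
observed one. Nodes with p ≤ α are split; others become terminal
clusters. Defaults: α = 0.05, 999 expected + 999 simulated permutations
(the convention of the algorithm's original description); all exposed
as parameters because none is canonical for this assay. Permuted
distance profiles are computed batched (einsum Gram matrices) for
speed.

Determinism and reproducibility choices:

- Each node's permutation stream is seeded from the run seed plus the
  node's leaf set, so p-values do not depend on traversal history; with
  a fixed dendrogram and seed, the partition refines monotonically as
  α grows (the cluster count is non-decreasing in α).
- Cluster IDs number terminal clusters by the dendrogram leaf order of
  their first leaf — reproducible run to run; IDs are labels, never
  matched numerically to any published numbering.
- Identical rows give π = 0 and p = 1 by convention: for two rows,
  per-gene swaps negate coordinate differences without changing the
  Euclidean distance, so pair nodes are inherently untestable and are
  never split.

Known statistical property: the top-down recursion tests every
homogeneous subtree at roughly nominal level, so with k true clusters
the probability that *no* cluster is over-split is about (1−α)^k. At
α = 0.05 and three planted clusters, exact recovery of the cluster
count therefore saturates near 0.86 even with perfect separation, while
each individual planted cluster is recovered intact in ≈ 95% of cases
and clusters spanning two planted groups essentially never occur. Tests
of recovery are scored per planted cluster for this reason.

Cluster profiles are per-gene geometric means over member
cell-timepoints (log10 view available for heatmaps).

## State-machine Petri nets

Construction from a trajectory table: one place per distinct state; one
transition per distinct ordered pair of consecutive *differing* states,
with the observed multiplicity stored as `count` and the set of
(experiment, condition) origins as `provenance`; one immediate
transition C0 → s per distinct initial state, weighted by the number of
cells starting in s. Self-transits create no transition — they feed
residence times instead; any other convention would change the
transition count of the packaged net. All structural invariants (one
pre-place, one post-place, arc weights 1, immediates only from C0, no
self-loops) are enforced by `StateNet.validate()`.

- **Frequency**: a place's `relative_frequency` is its share of all
  cell-timepoints; shares sum to 1.
- **Stability**: a state's mean residence-run length in sampling
  intervals, normalized by the maximum over states to (0, 1]. Runs
  truncated by the start or end of a series count at their observed
  length (no censoring correction — at 11 time points any correction
  would be guesswork).
- **Graph analysis** is computed on the ordinary-transition graph with
  C0 excluded: sources (no incoming ordinary transition), sinks
  (terminal states), weak and strong components.
- **Minimal T-invariants**: in a state machine these are exactly the
  elementary directed cycles of the place graph; they are enumerated by
  Johnson's algorithm (via networkx, SCC-restricted), canonically
  rotated to start at the smallest place, sorted by (length, places),
  and capped (default 10⁶) because cycle counts explode on small gene
  subsets. The enumerator is validated against an exhaustive
  brute-force search on all nets with ≤ 12 places. The enumerated count
  for the packaged table is reported rather than asserted against an
  external figure, since hand transcription or differing tool
  conventions could shift it.
- **Summary metrics** exclude C0 and immediate transitions from place
  and transition counts; ratios are reported unrounded and at the
  printed precisions of the field's summary-table layout (P/Gene 1 dp,
  T/Gene 1 dp, T/P 2 dp, per-design ratios 3 dp).
- **Token game**: a run fires one immediate transition (uniform, or
  proportional to initial-state multiplicities) and then one enabled
  post-transition per step (uniform, or proportional to transit counts)
  until a sink or the step limit; exactly one token exists at every
  step, and every emitted sequence is accepted by `accepts()`.
- **Reachability**: `reachability_graph()` builds the reachable-marking
  graph explicitly; for a single-token state machine it coincides with
  the place/transit graph reachable from C0 (the Markov chain of
  states), and the test suite asserts this by construction on fixtures.

Export: ANDL (the plain-text net description of the Snoopy tool family;
the dialect written here covers single-token state machines — places
with initial marking, transitions with one pre-arc `[P - 1]`, one
post-arc `[P + 1]` and a firing weight, immediate and stochastic
sections — and round-trips through the package's own reader, with the
grammar documented in the module) and GraphViz DOT (places as circles,
transitions as boxes, annotations as node attributes, replacing
interactive color editing).

## Ordination and kinetics

Classical (Torgerson) MDS: eigendecomposition of the double-centered
squared Euclidean distance matrix; coordinates are eigenvectors scaled
by √eigenvalue for the k largest positive eigenvalues; percent variance
is eigenvalue over the sum of positive eigenvalues (negative
eigenvalues from non-Euclidean inputs are dropped from the denominator,
the `cmdscale` convention); each coordinate's sign is fixed by making
its largest-magnitude loading positive. With all positive eigenvalues
retained, embedding distances reproduce the input to 1e-9. Distances
default to log10-transformed values for consistency with the clustering
and heatmap scale; linear mode is exposed.

Kinetics curves: per cell and gene,
`log10(profile_{s(t)}(g)) − log10(profile_{s(0)}(g))` — exactly 0 at
t = 0 and stepwise constant within residence runs, so curves depend on
a trajectory only through its cluster profiles.

## Synthetic data generator

The generator defines the conditions every statistical test runs under:

- **TruthChain**: states 1..n along a backbone 1→2→…→n (guaranteeing
  reachability from state 1), extra forward edges raising mean
  out-degree toward `branching` (default 1.6), and a `cycle_fraction`
  (default 0.15) share of states with one back edge; `cycle_fraction=0`
  is acyclic by construction. Per-state self-stay probability 0.4
  (mean residence runs of ~1.7 intervals, matching the mixture of
  quick transits and multi-hour residences in the observed table);
  successor probabilities Dirichlet-distributed; initial distribution
  spread over the first third of states (observed experiments started
  from many different states).
- **Panel**: 10 up-regulated, 10 down-regulated, 4 condition-
  independent "pcnA-group" and 11 reference genes (35 total).
  Regulation spans a fold factor drawn log-uniformly from 10–100.
  Up/down genes drift monotonically along the backbone in far-red
  chains; in dark-control chains, and always for the pcnA-group, log2
  expression performs a random walk (step sd 0.5) — condition-
  independent wandering. Reference genes stay at baseline.
- **Noise**: measurement = profile × 2^N(0, σ_bio) per biological
  sample × 2^N(0, σ_tech) per technical replicate. σ_tech = 0.43 log2
  units is calibrated so the analytic 95% quantile of the pair x-fold
  deviation, r_q = 2/(1 + 2^(−z_q·σ√2)), equals 1.333; the implied 5%
  quantile ≈ 0.667 sits within the 0.663–0.681 range technical
  replicates actually show. σ_bio = 0.1 keeps within-plasmodium
  variation well inside technical noise, as observed. A `failed_rate`
  (default 0.01) models failed RT-PCR reactions at 0.1× the expected
  value, reproducing the low-value tail of real deviation histograms;
  calibration paths set it to 0.
- All randomness flows from explicit seeds through named
  `numpy.random.Generator` instances; no global state.

What the generator does *not* emulate: per-gene kinetic parameters (not
published), amplification-efficiency differences between genes
(corrected upstream by the instrument), batch effects between
experiments, and any history dependence of transits (states evolve as a
first-order Markov chain by construction). Passing tests on synthetic
data therefore demonstrate the correctness of the computations and
calibration of the noise model — not that real plasmodial gene
regulation satisfies the Markov assumption.

## Numerical and scale choices

- Geometric means are computed in log space throughout.
- Quantiles use NumPy's default (linear interpolation) estimator.
- The trajectory TSV dialect is tab-separated UTF-8 with `#` comments
  and an implicit 1 h grid encoded by column order.
- Test problem sizes (tens of cells, hundreds of permutation-test
  runs at 199+199 permutations, 500-cell recovery simulations,
  ~115,000 replicate pairs for calibration) were chosen so the full
  suite exercises every statistical claim at Monte-Carlo errors well
  below the asserted tolerances while remaining a desk-scale
  computation.

## Known limitations

- SIMPROF cannot split two-row groups under Euclidean distance (see
  above); states represented by a single cell-timepoint each can
  therefore be merged pairwise irrecoverably.
- The plasmodium-exclusion rule with only two samples per time point
  reduces to a pairwise two-fold check between sample profiles.
- The ANDL dialect covers the single-token state-machine class only —
  no arc weights > 1, multiple tokens, or colored extensions.
- Gene-subset nets can have cycle counts in the thousands; the
  enumeration cap exists to fail loudly rather than hang if a subset
  net is pathologically cyclic.
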