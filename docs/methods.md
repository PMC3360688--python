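# Methods

`cytoemd` classifies multi-tube flow cytometry samples (normal vs AML) from
the full shape of their cellular composition rather than from hand-gated
subpopulations. The pipeline has three parts: a SPADE cluster tree that
gives all samples a common coordinate system; an earth mover's distance
(EMD) on that tree that compares whole cell distributions; and a Relief
nearest-neighbor score, summed over staining tubes, whose sign gives the
predicted class.

## Data model and preprocessing

Each biological sample is split into eight staining tubes. A tube's data is
a cells × 7 matrix: forward scatter (FSC), side scatter (SSC), and five
fluorescence channels, already compensated and transformed upstream (FSC on
a linear scale, the rest logarithmic). Tubes measure mostly disjoint marker
panels; only FSC, SSC and a CD45-type marker recur, so tubes are analyzed
as independent prediction problems and fused only at the score level.

Because linear-scale FSC has a spread orders of magnitude larger than the
log channels, it would dominate every L1 distance downstream. The only
normalization applied is therefore a per-file affine rescale of the FSC
column to mean 0 and standard deviation 0.1 (sample sd, n−1 denominator),
bringing it onto the same footing as the log channels. SSC and the markers
are left untouched; per-channel histogram curves across the cohort are
produced as an advisory QC view only (no automatic sample exclusion).

## SPADE tree construction

For one tube, all samples are mapped onto a single cluster tree built in
four steps.

**Density-dependent downsampling** (per sample). The local density `LD_i`
of cell *i* is the number of cells within an L1 ball of radius 5× the
median nearest-neighbor L1 distance (median over a random subsample of at
most 1000 cells — the subsample only stabilizes the radius estimate; the
counts themselves are exact). Cells with `LD_i` below the outlier density
`OD` (1st percentile of all local densities) are discarded. Cells between
`OD` and the target density `TD` are kept; cells above `TD` are kept with
probability `TD/LD_i`, which flattens the density landscape so rare
subpopulations survive. `TD` is solved exactly: the expected retention
`Σ min(1, TD/LD_i)` over eligible cells is continuous, piecewise-linear and
increasing in `TD`, so the equation "expected retention = 2000" has a
closed-form solution. The actual draw is systematic sampling on a seeded
random permutation with inclusion probabilities `min(1, TD/LD_i)`: because
those probabilities sum to exactly 2000, every draw returns exactly 2000
distinct cells and each cell's inclusion probability equals its keep
probability exactly. Fixing the retained count means every sample
contributes equally to the pooled cloud regardless of its original size.

**Pooling.** The per-sample subsets are concatenated (provenance retained)
and, if larger, uniformly subsampled to 50000 cells.

**Size-balanced agglomerative clustering.** Clusters start as single cells
and merge in rounds; in each round every *mutual-nearest* pair of clusters
(L1 distance between current medians) merges, and all other clusters sit
the round out. At most one merge per cluster per round keeps sizes balanced
— unlike single linkage, no cluster can chain through the data — and
requiring reciprocity means no cluster is forced into a long-range merge
just because its natural partners were taken, so well-separated
subpopulations are never mixed. When fewer than twice the target count
remain, merging switches to one globally cheapest merge at a time, landing
on exactly 150 clusters. The procedure is deterministic given its input.

**Minimum spanning tree.** Each cluster is summarized by its channel-wise
median; the tree links the 150 medians with minimum total L1 edge length.
Any minimal spanning tree satisfies the contract; ties are broken by node
index for determinism. (Implementation note: the sparse-graph MST routine
treats zero-weight entries as absent edges, so a constant +1 is added to
every candidate edge before the call — all spanning trees have K−1 edges,
so a constant offset cannot change the minimizer — and true lengths are
restored afterwards.)

**Upsampling.** Every cell of every original file (not just the downsampled
subset) is assigned the cluster of its L1-nearest pooled reference cell
(exact ties go to the lowest-index reference). Counting assignments per
node and normalizing by the file's cell count yields each sample's
distribution over the 150 tree nodes — the feature used everywhere
downstream.

## Earth mover's distance on the tree

Two samples are compared by the minimum total effort needed to morph one
node distribution into the other, where moving one unit of mass across one
tree edge costs one unit (`hops` mode, the default) or the edge's L1 length
(`edge_length` mode, provided as an option). Distributions are normalized
relative frequencies (sum 1), not raw counts, since file sizes differ; any
global scale factor would cancel in the Relief score anyway.

The definitional computation is the transportation linear program
`min Σ f_ij d_ij` subject to `f_ij ≥ 0`, row sums `P` and column sums `Q`,
with `d_ij` the shortest-path cost between nodes — solved with HiGHS via
`scipy.optimize.linprog`. On a tree metric the optimum also has a closed
form: each edge is a cut, the net mass that must cross it is the subtree
imbalance `|Σ_{v∈subtree}(P_v − Q_v)|`, and the EMD is the cost-weighted
sum over edges. The production pairwise-matrix path uses the closed form
(O(K) per pair after rooting the tree once); the LP is kept as an
independent cross-check — the test suite verifies their agreement to 1e-6
on random trees — and for arbitrary non-tree cost matrices.

## Relief scoring and tube fusion

The Relief score of a held-out sample is

    score = min_j d(test, normal_j) − min_j d(test, AML_j)

over training samples, with `d` the tube's EMD. Negative scores indicate
the sample sits nearer the normal cloud; positive scores nearer the AML
cloud. Class = AML iff score > 0; an exact 0 predicts normal (a documented
tie-break — in practice the score distribution shows a gap around 0).
Per-tube scores are summed with equal weight (tube inclusion is
configurable, e.g. dropping the isotype/unstained control tubes 1 and 8);
|summed score| serves as a confidence proxy, and scores below 10% of the
cohort's median |score| are flagged as low-confidence calls (advisory
only). When a training sample is scored for diagnostics, its self-distance
is excluded. A scikit-learn facade (`ReliefClassifier`, precomputed-distance
convention) exposes the same rule as fit/predict/decision_function.

## Synthetic cohorts

The generator exists so every stage — and the end-to-end classifier — is
testable without external data. Cells are drawn from diagonal-covariance
Gaussian mixtures over 8 subpopulations on the transformed-intensity scale;
no instrument effects (compensation, spillover, doublets, acquisition
drift) are simulated, so passing tests demonstrate correctness of the
algorithms under the stated mixture model, not robustness to raw-instrument
artifacts.

Fixed generation conditions (chosen once, with rationale):

- **Staining patterns.** Per tube, each population's four tube-specific
  markers are "negative" (mean 0.5) or "positive" (mean 3.5), sd 0.2, with
  the on/off patterns drawn from 4-bit even-parity codes (pairwise Hamming
  distance ≥ 2). This guarantees pairwise L1 separation of population means
  of at least 4× the mean total spread in every informative tube without
  rejection-sampling pathologies; a verification loop still checks the
  property and retries (then errors) if jitter breaks it.
- **Shared channels.** SSC and the CD45-like marker take distinct values on
  an even-parity 4×4 grid (levels 0.4–4.0) shared across tubes; population
  FSC means span ±0.15 on the analysis scale with sd 0.05, emitted raw as
  `500 + 2000×latent` so the FSC rescaling step is genuinely exercised.
- **Controls.** With ≥4 tubes, tube 1 is an isotype analog (marker slots
  are non-specific noise; FSC/SSC/CD45 informative) and the last tube an
  unstained analog (all five fluorescence slots noise). The unstained tube
  is deliberately weakly informative and exempt from the separation
  guarantee — this is what makes equal-weight fusion worth testing.
- **Class effect.** One blast-like population has baseline abundance 0.04;
  in AML samples its abundance is multiplied by `exp(effect_size)` and the
  mixture renormalized. `effect_size = 0` is an exact null (the two classes
  are identically distributed). The default 1.5 multiplies the blast
  abundance ≈ 4.5-fold (0.04 → ≈ 0.16), a textbook-scale blast expansion.
- **Within-class variability.** Samples of a class share one set of mixture
  weights; they differ through their multinomial cell draws and their cell
  counts. An optional logistic-normal abundance jitter (off by default),
  drawn once per sample and shared by all of its tubes — aliquots of one
  specimen — makes cohorts deliberately harder: at sd 0.2 the within-class
  EMD spread reaches the order of the class signal and Relief, facing only
  4 AML training neighbors against 16 normal ones, starts missing AML
  samples. The standard bench cohort keeps jitter off, matching the
  template model from which the package's accuracy guarantees are stated;
  the jittered regime is for robustness exploration.
- **Cohort.** 40 samples (32 normal, 8 AML ≈ the 9:1 flavor of a screening
  cohort), 3000–6000 cells per file, stratified half train / half test.

## Problem sizes used by the test suite and acceptance script

The acceptance script runs the standard 40-sample, 8-tube cohort through
the pipeline at the published defaults (2000 retained cells/sample,
50000-cell pool cap, 150 clusters). Multi-seed statistical checks keep the
same cohort but scale the pipeline to desk size (retain 150–200 cells,
pool cap 4800–6400, 40–50 clusters) — the contracts being exercised (exact retention, flattening,
metric structure, score behavior) are scale-free, and the parameter
contracts at the published values are verified separately. Invariant sweeps
(accuracy monotone in effect size, between- vs within-class EMD) use
further reduced cohorts (16 samples, 2 tubes, ~1000 cells/file) with common
random numbers across effect sizes, which couples the accuracy curves and
makes the monotonicity check sharp instead of noise-dominated.

## Numerical choices and degenerate inputs

- Target-density solve: exact piecewise-linear inversion, no iteration; an
  error is raised if fewer eligible cells than the retention target exist.
- FSC rescale: n−1 standard deviation; zero FSC variance or a single cell
  is a degenerate-input error; post-conditions hold to 1e-9.
- Node distributions sum to 1 within 1e-12; EMD matrices are symmetric to
  1e-8 and satisfy the triangle inequality to the same slack.
- Ties: upsampling resolves exact nearest-neighbor ties to the lowest
  reference index; a summed Relief score of exactly 0 predicts normal;
  MST ties are broken by node index.
- Single-node trees, single-cluster assignments (k=1) and k=n are all
  legal limits and covered by tests.
- All stochastic stages draw from `numpy.random.Generator` streams derived
  from one master seed via `SeedSequence` (per tube, then per sample, in
  sorted sample-id order), so a rerun with the same configuration
  reproduces every artifact byte for byte.

## The no-signal control

At effect 0 the classifier must find nothing. Relief trained on a 4:1
normal:AML split predicts "normal" for most null samples (the minimum over
16 normal distances is stochastically smaller than over 4 AML distances),
but not for all of them, so null accuracy settles near — typically a few
points below — the majority-class rate rather than exactly on it. The
control therefore tests what "no signal" actually means: predictions are
statistically independent of the true labels (Fisher exact test on the
pooled prediction × truth table, p > 0.01), and nowhere near the perfect
separation seen with a planted effect.

## Known limitations

- The tube panels, channel count (7) and control-tube layout are fixed to
  the standard 8-tube screening design; other panel layouts would need a
  new template.
- The generator's Gaussian mixture cannot express continuous developmental
  trajectories, so the tree's ability to capture *progressions* (as opposed
  to discrete subpopulations) is not exercised by the synthetic tests.
- Equal-weight tube fusion is implemented as specified; learning tube
  weights is explicitly out of scope.
- Tree layout/visualization is out of scope; trees are exported as JSON
  (nodes, edges, lengths) for external plotting.
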