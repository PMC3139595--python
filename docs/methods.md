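# Methods

This note documents the models, conventions and numerical choices behind
`trtnet`, in the order the pipeline runs.

## From time series to connectivity

A subject-scan enters as a T×N matrix of ROI time courses. Preprocessing
is deliberately minimal and fully caller-controlled:

- **Nuisance regression** removes caller-supplied regressors (head-motion
  profiles, global signal, …) plus an implicit intercept by ordinary least
  squares; residuals are exactly orthogonal to the design and the
  operation is idempotent. The package never derives regressors from
  images — inputs start at ROI time series.
- **Band-pass filtering** uses a 2nd-order Butterworth design applied
  forward–backward (`sosfiltfilt`), giving zero phase shift. Only the
  band (default 0.01–0.1 Hz, the standard window for spontaneous BOLD
  fluctuations) is a scientific commitment; the filter family is a
  convention, chosen for stability at these narrow normalised bands.
- **Connectivity** is the Pearson correlation of every ROI pair. The
  diagonal is fixed at 1 and excluded from every downstream statistic;
  "all connections" always means the strict upper triangle, N(N−1)/2
  entries.

Averaging of repeat scans (used to build the long-term condition, scan 1
versus the average of scans 2–3) is done entrywise in Fisher-z space and
transformed back. The z-transform stabilises the variance of correlation
estimates, which makes averaging well-behaved near |r| → 1; plain r-space
averaging is available as an option since the choice is a convention, not
a theorem.

## Network construction

Sparsity S = E / (N(N−1)/2) is the fraction of possible edges retained.
Thresholding at fixed S rather than fixed correlation equalises edge count
across subjects and scans, so group statistics compare topology, not
density. Conventions:

- **Edge count**: E = round-half-up(S · E_max). The rounding rule is
  arbitrary but must be deterministic and monotone in S; half-up is both.
- **Ranking**: connections are ranked by salience — |r| under
  absolute-value membership, r (negatives zeroed) under positive-only
  membership — and the top E are kept. Ties at the cut break by
  lexicographic (i, j); combined with ranking once per matrix this makes
  edge sets exactly nested along the sparsity grid.
- **Weights**: weighted networks carry the salience (so absolute-value
  membership yields |r| weights); binarized networks carry 1.
- **Attainable range**: under positive-only membership S cannot exceed
  the fraction of positive connections; study-level code truncates the
  grid at the minimum attainable S over exactly the two scan conditions
  being compared.
- **Default grid**: 0.01 to the attainable maximum in steps of 0.01 for
  full-resolution studies; the bundled experiments use coarser grids
  (stated below) since every grid point multiplies runtime. Conclusions
  asserted by the tests are grid-density-independent (nesting, exactness,
  trends).

## Graph metrics

Twelve global and six nodal measures, for binarized and weighted
undirected networks. Binarized definitions are the standard ones; the
weighted generalisations are field conventions and are documented as such:

- **Paths** use edge length 1/weight, mapping connection strength to
  proximity. Distances come from Dijkstra (hop counts for binarized).
- **Lp** is the mean shortest path length over pairs when the graph is
  connected. Because thresholding over a full sparsity range unavoidably
  produces disconnected graphs, the disconnected case reports the
  harmonic mean N(N−1)/Σ 1/d (unreachable pairs drop out), which stays
  finite and degrades gracefully. Efficiency-based measures (Eglob = mean
  of 1/d, nodal efficiency, Eloc over neighbour subgraphs) handle
  unreachable pairs natively as zero contributions.
- **Clustering** (weighted) is the Onnela geometric-mean triangle
  intensity with weights normalised by the network maximum; it is bounded
  in [0, 1] and — a consequence of the max normalisation — invariant to
  rescaling all weights, which the test suite documents per metric.
- **Betweenness** is fractional shortest-path betweenness with endpoints
  excluded (Brandes, via networkx).
- **γ, λ, σ**: Cp and Lp normalised by their means over degree-preserving
  surrogates, σ = γ/λ. Surrogates come from double-edge swaps (default
  10 swaps per edge, ensemble of 100, both config-exposed); weighted
  networks are rewired topologically and the original weight multiset is
  randomly permuted onto the new edges. A complete graph admits no swap;
  the surrogate falls back to the input with a warning.
- **Assortativity** is the Pearson correlation of endpoint degrees
  (strengths) over edges, both orientations counted.
- **Hierarchy** is b in the power-law scaling c ~ k^(−b), estimated as
  minus the least-squares slope of log c on log k over nodes with degree
  ≥ 2 and positive clustering.
- **Synchronizability** is λ₂/λ_max of the graph Laplacian L = D − A;
  0 for disconnected graphs (λ₂ = 0).
- **Modularity** uses deterministic greedy agglomeration
  (Clauset–Newman–Moore): reliability comparisons must not inject
  algorithmic randomness, so a stochastic optimiser (e.g. Louvain with
  restarts) is deliberately avoided even though it can find slightly
  higher Q.
- **Participation** PC_i = 1 − Σ_m (k_im/k_i)²; its normalised form
  divides by the maximum attainable value at M modules, 1 − 1/M, so a
  node spread evenly over the modules scores 1 regardless of M.

**Undefined values are NaN, never zero.** Assortativity on regular
graphs, hierarchy with fewer than 3 eligible nodes, normalised
participation under a single-module partition, and γ/λ/σ when the
surrogate ensemble is triangle-free all return flagged NaN; downstream
reliability excludes them pairwise. Silent zeros would masquerade as
perfectly reliable measurements and bias every ICC they enter.

## Reliability

The statistic is the one-way random-effects, single-measurement ICC.
For n subjects with k repeated observations, a one-way ANOVA with random
subject effects gives MS_b (between subjects, df n−1) and MS_w (residual,
df n(k−1)), and

    ICC = (MS_b − MS_w) / (MS_b + (k−1)·MS_w),  F = MS_b / MS_w,
    equivalently ICC = (F − 1) / (F + k − 1).

Conventions: negative estimates are reported as computed (not truncated)
and graded "poor"; grade bands (poor < 0.25 ≤ low < 0.4 ≤ fair < 0.6 ≤
good < 0.75 ≤ excellent) are lower-inclusive; subjects with flagged
values are excluded listwise per measure, since the balanced one-way
ANOVA needs complete rows. Two-way ICC variants (which separate rater /
occasion effects) are out of scope — the one-way form treats scan-to-scan
differences wholly as error, which is the conservative choice for
test–retest designs.

Edgewise reliability transforms connection values to Fisher z before the
ANOVA (consistent with z-space averaging; the affine invariance of ICC
makes this immaterial for any one edge's monotone rescaling but it
equalises variance across edges of different strength).

Threshold dependence is summarised by the trapezoidal area under each
metric-versus-sparsity curve (AUC), computed per subject after pruning
flagged grid points; the ICC of the AUC values is the
threshold-independent reliability scalar. No multiple-testing correction
is applied to edgewise ICC maps.

## Noise-robustness experiment

For each subject, metrics from the clean correlation matrix are the
reference. Independent zero-mean Gaussian noise with variance equal to a
fraction f of that subject's own connectivity variance (variance of the
strict upper triangle — the diagonal is constant and would dilute it) is
added per unordered pair, mirrored, and clipped to [−1, 1]; noise is
added in r-space because the perturbation models measurement error on the
correlations themselves. Default design: f = 8.3%, 16.7%, 25%, 33.3%,
41.7%, 50% (six equal steps to one half), 5 repetitions per level.

Reliability per metric and level pairs reference versus noisy values as
k = 2 observations. Global metrics use the subject's AUC scalar; nodal
metrics compute an ICC per node (on per-node AUCs) and report the mean
over nodes — averaging the metric over nodes first would be degenerate
for degree, whose node-mean is fixed by the sparsity threshold. The
reported per-level value is the mean over the 5 repetitions, which is the
experiment's defined output; single repetitions are exposed in the raw
table. Inside this experiment the surrogate ensemble for γ/λ/σ defaults
to 5 (config-exposed) because the ensemble multiplies the cost of
re-running all twelve global metrics for every of the
n_subjects × n_levels × n_reps simulated matrices.

A note on the vanishing-noise limit: as f → 0 every ICC tends to 1, but
rank thresholding is discontinuous — two connections whose saliences
differ by less than the noise scale can swap across the cut, and
discrete or small-sample metrics (module count, the hierarchy slope over
few eligible nodes) amplify a single edge flip. At 10-ROI scale this
makes individual repetitions occasionally dip below the limit even at
f = 10⁻⁶; the repetition-averaged value is stable.

## Synthetic cohorts

The generator exists so that every downstream stage has a known ground
truth. Per connection (i, j), subject s, scan t:

    z_ijst = μ_ij + b_ijs + w_ijst,  b ~ N(0, σ_b²), w ~ N(0, σ_w²),
    r_ijst = tanh(z_ijst)

Working in Fisher-z space keeps correlations inside (−1, 1) and makes the
variance decomposition — hence the edgewise ICC σ_b²/(σ_b²+σ_w²) — exact
and analytic. Defaults (25 subjects, 3 scans, μ = 0.3, σ_b = 0.25,
σ_w = 0.2, i.e. true edgewise ICC ≈ 0.61) are chosen for testability: a
moderate positive mean connectivity so positive-only thresholding has
headroom, and variance components large enough that ICC estimates at
cohort sizes of tens of subjects are informative. They are not fitted to
any empirical dataset.

Matrix mode returns the tanh-transformed draws directly (symmetric, unit
diagonal; positive semidefiniteness is not required of a matrix that is
only ever thresholded). Time-series mode additionally projects each
matrix to the nearest correlation matrix (eigenvalue clipping at 1e−8
with re-normalisation to unit diagonal, iterated) and draws the requested
number of multivariate-Gaussian samples; the Pearson sampling noise of
finite series inflates the within-subject component, so analytic
ICC-recovery claims are asserted in matrix mode only.

Randomness: one seed per cohort, split per (subject, scan) by counter
through numpy `SeedSequence`s, so generation is independent of iteration
order and bitwise reproducible.

**What the generator does not emulate**: hemodynamic response shape,
autocorrelated or spatially structured physiological noise, head motion,
scanner drift, or any anatomically realistic mean connectivity pattern
(μ is flat by default). Passing tests therefore demonstrate correctness
of the estimators and the qualitative mechanics of reliability — not that
any particular empirical dataset attains a given reliability level.

## Problem sizes in the bundled experiments

The test suite and acceptance script choose sizes that make Monte-Carlo
assertions stable: 200-subject cohorts for edgewise ICC recovery
(tolerance ±0.05), 25-subject cohorts for the variance-ratio sweep
(monotonicity, Spearman ≥ 0.9), 10-subject 10-ROI cohorts with a
0.05-step grid for noise-experiment trend checks (majority over 5 seeds),
and the exhaustive ≤7-node connected-graph battery plus 100 random
weighted ≤8-node graphs for metric-versus-oracle equivalence at 1e−9.

## Known limitations

- Weighted-metric formulas (Onnela clustering, 1/w path lengths, strength
  degrees, weight-permuting rewiring) are conventions of the field, not
  uniquely determined; alternatives (e.g. Barrat clustering) would give
  numerically different, similarly valid results.
- The hierarchy coefficient is estimated from few points on small sparse
  graphs and is the least stable metric in the battery; its flagging
  rules (≥3 eligible nodes, nonzero degree spread) are necessary but not
  sufficient for a well-conditioned fit.
- Greedy modularity can merge the odd node differently from exhaustive
  Q-maximisation on near-degenerate partitions; Q values are exact for
  the returned partition but the partition itself is a heuristic optimum.
- The factorial repeated-measures ANOVA over condition factors reported
  in full studies is out of scope; the TSV outputs are designed to feed
  any external stats package.
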