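# Methods

`dfcstates` implements a dynamic functional-connectivity (dFC) state
analysis for region-of-interest (ROI) time series of the kind extracted
from resting-state fMRI, together with a synthetic cohort generator that
provides ground truth for validating every stage. This note records the
models, the parameters that matter, and the design choices made where the
methodology left a genuine decision open.

## Pipeline model

Given per-subject T x N ROI time series, the analysis proceeds:

1. **Sliding-window connectivity.** Rectangular (boxcar) windows of width
   `w` TR advance in steps of `s` TR (defaults w = 30, s = 1, matching the
   common protocol for ~230-volume resting-state runs and giving
   `floor((T - w)/s) + 1 = 201` windows at T = 230). Each window yields an
   N x N Pearson correlation matrix; a zero-variance column within a window
   is assigned zero correlations (logged) rather than NaN. Windows are
   0-based and half-open. A tapered window is deliberately not applied: the
   protocol this package follows specifies only width and step.
2. **Fisher z.** Off-diagonal r values are clipped to |r| <= 1 - 1e-7 and
   arctanh-transformed; diagonals are zeroed. The z-scale stabilizes the
   variance of r and is the scale on which all later stages operate
   (correlate -> z -> cluster, in that order).
3. **dFC variability.** The entrywise sample SD (ddof = 1) of z across
   windows summarizes each subject's connectivity fluctuation.
4. **State clustering.** All subjects' windows are pooled; each window is
   the row-major strict upper triangle of its z-matrix (N(N-1)/2 features,
   held in float32 — z values are O(1) and the L1 objective sums ~1e3
   absolute differences, far above single-precision granularity). K-means
   under the Manhattan (L1) distance partitions the rows; the centroid
   update is the coordinate-wise *median* of assigned rows, the L1-optimal
   center, so each iteration provably does not increase the cost (a
   mean-update with L1 assignment would not descend). Each fit is the best
   of `n_init = 20` k-means++-style restarts run to exact label
   convergence (`max_iter = 300` cap); empty clusters are reseeded from
   (and claim) the point farthest from its assigned centroid. K is chosen
   by the elbow criterion, read as the interior K maximizing the discrete
   second difference `cost(K-1) - 2 cost(K) + cost(K+1)` over K = 2..8,
   ties to the lowest K. This is a reproducible, parameter-free reading of
   "elbow"; a distortion-ratio rule would be an alternative but introduces
   a threshold. States are renumbered by descending mean |centroid| so
   state 1 is always the strongest-connected state. A partition is valid
   only if every state holds at least 10 pooled windows; the pipeline
   aborts otherwise.
5. **Temporal metrics.** Per subject: fractional windows (FW, per-state
   share of windows), mean dwell time (MDT, mean maximal-run length in
   window units, boundary-truncated runs included; a state never visited
   contributes MDT = 0 rather than being excluded — this is what makes
   near-zero group means with large SDs possible when most subjects skip a
   state), and the transition count. MDT is reported in windows with an
   optional TR-seconds column; window units are the primary convention.
6. **Graph metrics.** A subject's network in a state is the entrywise mean
   z-matrix over that subject's windows in the state (absent states yield
   a sentinel and drop the subject from that state's group tests). Each
   weighted network is binarized over a sparsity sweep (0.10-0.40, step
   0.01) by keeping the `floor(sparsity * N(N-1)/2)` largest *signed*
   weights (negative edges are effectively excluded at these sparsities;
   absolute-value ranking would be the alternative convention). Exact ties
   at the cutoff break by row-major edge index, deterministically, and are
   logged. Metrics: global efficiency (mean 1/d over ordered pairs, 1/inf
   = 0), local efficiency (mean over nodes of the neighbor-subgraph
   efficiency), clustering coefficient, degree, unnormalized betweenness
   (each unordered pair counted once), and small-worldness sigma =
   (C/C_rand)/(L/L_rand) against degree-preserving Maslov-Sneppen rewired
   nulls (10 x |E| swaps each; a graph that cannot be rewired falls back
   to a density-matched random null, logged). The characteristic path
   length is the mean finite distance on the largest connected component
   (coverage reported) — this avoids infinities at sparse thresholds.
   Sweep-level metrics are aggregated by the trapezoidal area under the
   metric-vs-sparsity curve (AUC; a constant metric of 1 integrates to
   0.30 over the sweep) before group testing. Whether metrics should be
   computed per window, per state-mean network or per subject-mean network
   is genuinely ambiguous in sliding-window work; the state-mean network
   is the primary object here because it is the state-resolved analogue of
   the conventional static analysis.
7. **Group statistics.** Pairwise group contrasts use a Freedman-Lane-style
   permutation test: the outcome is residualized on intercept + age +
   gender, the statistic is the group-mean difference of residuals, and
   the null permutes the group-contrast weights over subjects (5,000
   permutations by default; two-sided add-one p =
   (1 + #{|null| >= |obs|})/(n_perm + 1)). Covariate columns constant
   within a contrast are dropped with a log message. FDR families:
   FW across all states x contrasts, MDT likewise, transitions across
   contrasts, and nodal metrics across nodes within each (metric, state,
   contrast) — family definitions are a reporting choice and are recorded
   in the output tables. Edge-wise contrasts of state networks use the
   network-based statistic: a primary two-sided pooled-t edge screen at
   alpha = 0.001 on covariate-adjusted values, connected components of the
   surviving edges, and a familywise component p from the permutation
   distribution of the maximal component edge count (1,000 iterations,
   shared permutation schedule across edges, add-one corrected). The
   primary edge screen is parametric by design: a permutation edge p with
   n_iter iterations is bounded below by 1/(n_iter + 1) and cannot cross
   an 0.001 threshold unless n_iter >= 1000, which would couple the edge
   screen's resolution to the component null's budget. Spearman partial
   correlation (rank x and y, residualize both on the covariates,
   correlate the residuals; t-based p on n - 2 - k df) links metrics to
   clinical scores; correlation analyses are exploratory and reported
   uncorrected. Kruskal-Wallis / chi-square / Mann-Whitney utilities cover
   cohort description.

All randomness flows from one master seed through
`numpy.random.SeedSequence.spawn`, with a fixed per-stage spawn order
(simulate, cluster, graphs, stats), so a full run is bit-reproducible.

## Synthetic cohort model

No generative model is implied by the analysis itself, so the generator's
model is an explicit choice: a **Markov-switching multivariate normal**.
A latent state sequence evolves at the *time-point* level under a
first-order Markov chain; each time point is drawn from a zero-mean
multivariate normal with the covariance of the active state. Because
switching happens at time-point resolution, windows near a state boundary
mix states — exactly the nuisance a window-based clustering pipeline must
tolerate — and the ground-truth label of a window is its majority state
(ties to the lower label).

Defaults (a "desk-scale" cohort: 3 groups x 4 subjects, T = 230, N = 30):

* **States.** Three correlation structures with strong / sparse /
  intermediate mean absolute connectivity: state 1, three blocks of N/3
  ROIs at r = 0.65 (mean |off-diagonal| 0.20); state 2, two blocks of N/2
  at r = 0.10 (mean 0.05); state 3, three blocks at r = 0.55 offset by
  half a block from state 1's partition (mean 0.16). Two design
  constraints drove this shape. First, each state spreads its connectivity
  over several *independent* block factors: a single global factor (e.g.
  one full-matrix block) makes 30-sample windowed correlations fluctuate
  coherently along a global-strength axis, and K-means then splits that
  state by sampled strength instead of isolating the planted states.
  Second, the intermediate pattern is offset from the strong pattern so it
  does not lie on the strong-sparse mixing line traced by boundary
  windows, which would otherwise be absorbed into it. Indefinite
  user-specified structures are repaired by diagonal loading in 0.01
  steps up to 0.5 (shrinking off-diagonals), and error out beyond that.
* **Dynamics.** Transition matrices are built from a target stationary
  distribution and per-state mean dwell times by solving detailed balance
  for the pairwise flows (`x_ij = (F_i + F_j - F_k)/2`, `F_i = pi_i /
  dwell_i`), so the stationary occupancies are exact. The base chain uses
  occupancies 36.52 / 57.24 / 6.24 % — the strong state less frequent than
  the sparse state, with a rare intermediate state, the occupancy profile
  reported for three-state resting-state analyses of this design — with
  dwells of 150 / 220 / 35 time points. Long dwells in states 1-2 keep
  most 30-TR windows single-state; the rare state 3 is instead visited in
  short frequent bouts, which keeps its pooled window count stable from
  cohort to cohort (few long visits would make it a high-variance rare
  event).
* **Groups.** HC and HZ analogues share the base dynamics (the HZ group of
  the emulated design showed no dynamic differences); the PHN analogue
  shifts occupancy out of the strong state into the intermediate state
  (25 / 55 / 20 %) and dwells longer there (dwell 65), reproducing the
  lower-FW-in-state-1 / higher-FW-and-MDT-in-state-3 pattern, and adds
  per-state nodal edge perturbations in the strong state (one node's edges
  raised by 0.12, another's lowered by 0.18) as a topological group
  effect. Ages are normal (HC 58.2 +/- 6.5, HZ 60.4 +/- 10.2, PHN 63.8 +/-
  12.3 years) clipped to the 30-80 y inclusion range; gender is Bernoulli
  with the group-specific male fractions (14/27, 18/37, 10/18); pain
  scores (NRS 6.0 +/- 2.0 and 7.2 +/- 1.8) and disease duration are
  truncated at zero and absent for controls.

**What the generator does not emulate:** hemodynamics (no HRF convolution),
scanner noise and motion artifacts, bandpass-filtered autocorrelation
(samples are i.i.d. within a state), spatial atlas geometry, and any
voxel-level structure. Passing tests therefore demonstrate that the
pipeline recovers Markov-switching Gaussian structure at realistic SNR and
cohort size — not that any specific clinical finding would replicate on
real scans.

## Numerical choices and degenerate inputs

* L1 distances are computed by a compiled (numba) kernel with a
  scipy-`cdist` fallback that produces identical assignments; assignment
  ties go to the lowest centroid index.
* `arctanh` clipping bound 1 - 1e-7 (z caps at ~8.4); correlation matrices
  are symmetrized and clipped to [-1, 1] before transform.
* Elbow selection requires >= 3 candidate K values; with the default range
  2..8 only K = 3..7 are selectable (the endpoints have no second
  difference).
* A state never visited by a subject yields MDT 0 and drops the subject
  from that state's graph-metric contrasts; a contrast with fewer than two
  subjects per group in a state is skipped with a warning.
* Constant outcomes give permutation p = 1; constant covariates are
  dropped (logged) in pipeline contrasts, while the low-level
  `covariate_adjust` treats them as a rank-deficiency error naming the
  column.
* Betweenness is reported unnormalized (normalization is a config flag in
  the output tables' terms: divide by (N-1)(N-2)/2 if needed downstream).

## Known limitations

* Local efficiency is *not* monotone in sparsity (a new neighbor with no
  ties inside a neighborhood dilutes that node's Ne), so only global
  efficiency carries a monotonicity guarantee over nested thresholds.
* Exhaustive oracle verification of graph metrics covers every connected
  graph on <= 7 nodes (the graph atlas) plus seeded random graphs up to 12
  nodes; non-isomorphic enumeration beyond 7 nodes is not available
  in-process, so 8-node coverage is random rather than exhaustive.
* The elbow criterion on the default cohort is stochastic: across random
  cohorts it selects K = 3 in roughly 9 of 10 replicates, with failures
  concentrated in cohorts whose rare state happens to draw very few
  windows. The acceptance protocol therefore reports the modal selection
  over 20 replicate cohorts.
* Small-world sigma on a single graph has ~10% sampling noise from the
  observed graph's own clustering fluctuation; ensemble comparisons should
  average over graphs.
* The per-window (time-varying) reading of graph-metric variance is not
  computed by default; the pipeline's primary object is the state-mean
  network, and the per-window sweep is costly (windows x sparsities x
  metrics). The module functions accept per-window matrices directly if
  that reading is wanted.
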