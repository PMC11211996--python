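# Methods

## Model

The network diffusion model treats a regional pathology burden vector
`x(t)` as heat diffusing on a weighted brain graph: `dx/dt = −βHx`, solved
in closed form as `x(t) = expm(−βHt)x₀`. `H` is the random-walk graph
Laplacian `I − D⁻¹C` of the conditioned connectome (row-sum normalisation
compensates for differences in region size); a symmetric-normalised variant
`I − D^{−1/2}CD^{−1/2}` is available via `laplacian_kind="symmetric"`.
Isolated nodes get an all-zero Laplacian row, so they hold their value
rather than being dropped — label alignment therefore never changes
silently under thresholding.

The propagator is evaluated by eigendecomposition of `H` (cached per
operator, so dense time grids and many seed vectors share one
factorisation), falling back to `scipy.linalg.expm` per timepoint when the
eigenvector basis is ill-conditioned (condition number above 1e10). The
eigendecomposition path agrees with the matrix exponential and with an
adaptive ODE integration to better than 1e-6 over the tested regime (the
test suite checks 1e-8 against the closed form).

Model assumptions worth keeping in mind: purely diffusive, conservative
transport (no production, clearance or reaction terms), a static connectome,
and a bilateral single-region seed. Because β and t enter only through their
product, β is fixed to 1 and only model time is scanned.

## Conditioning pipeline

`zero_negative_weights → proportional_threshold → row_normalize →
graph_laplacian`. Thresholding retains `k = ceil(fraction · E)` of the `E`
existing (nonzero) edges by weight; ties at the cut resolve in ascending
(row, column) order so runs are reproducible. The pipeline is idempotent
from the second application onward and thresholding is monotone in the
retained-edge set.

## Fitting

Trajectories are restricted to the labels of the measured pattern (the 68
cortical regions after standard preparation; subcortical nodes still
participate in the diffusion when present) and re-min-max-normalised over
that subset, matching the [0, 1] scaling of the measured data. SSE is
computed on the normalised states; near-constant snapshots (range < 1e-12)
are flagged degenerate and excluded from the argmin, and ties resolve to
the earliest time. The default scan grid is 500 geometrically spaced points
from 1e-3 to 1e3 plus t = 0 (501 total); tests and the acceptance script
use 51–201-point grids of the same span, which resolve the SSE minimum to
well below the jitter induced by observation noise. An optional
golden-section refinement polishes the optimum between its grid
neighbours.

## Multimodal combination

The combined connectome is the convex combination `Ĉ = Σ λ_k C_k` over
label-aligned modalities (intersection of region sets by default; union
with zero-padding behind a flag), with each modality pre-thresholded at its
unimodal optimum. Optimisation searches raw weights in `[0,1]^K` and
normalises each point onto the simplex — the direct reading of the
normalisation constraint; an all-zero raw vector maps to uniform weights.
The Gaussian-process minimiser is built on scikit-learn's
`GaussianProcessRegressor` (Matern 5/2 kernel, normalised targets) with
expected-improvement acquisition maximised over a random candidate set; the
default budget is 300 random starts plus 500 surrogate iterations,
config-scalable. The K one-hot vertices are always included in the initial
design, so the combined fit can never be worse in-sample than any single
modality (feasible-set dominance holds by construction rather than up to
optimiser tolerance). Candidate seed regions get independent optimisation
runs; the global best is returned, and the returned fit is re-computed from
the returned weights so results are reproducible from their own record.

## Null models and validation

Rewired nulls use weighted degree-preserving double-edge swaps
(A–B, C–D → A–D, C–B; weights travel with their edges; swaps creating
self-loops or duplicates are rejected). `swaps_per_edge × E` swaps are
*attempted* (default 10), mirroring the convention of standard
brain-connectivity toolboxes; binary degree sequence and the edge-weight
multiset are preserved exactly. Null ensembles default to 100 networks; the
observed `r_max`'s percentile rank uses the fraction of nulls strictly
below. The combination null partners the retained modalities with rewired
versions of the others and re-runs the full weight optimisation per repeat.

Cross-validation partitions subjects into k = 5 balanced random folds (no
stratification); the training-fold average pattern drives all selection
(seed, threshold, weights), and frozen selections are evaluated on the
held-out fold average with only the time scan re-run. Stability analysis
re-averages random 30-subject subsamples 100 times and reports the spread
of `r_max`.

## Pathology preparation

Tau SUVR vectors are min-max scaled to [0, 1] (per subject before group
averaging by default; group-level scaling behind a flag). Atrophy is scored
as `z = (mean_ctrl − v) / sd_ctrl` against controls within ±5 years of the
subject's age (window configurable), so positive z means more atrophy, then
mapped through the unit logistic — atrophied regions approach 1, matching
tau's convention. Cohort filters: amyloid positivity is summary SUVR
strictly above 1.11; elevated tau is a medial-temporal SUVR strictly above
the amyloid-negative mean plus two sample standard deviations. Both
boundaries are strict.

## Covariance networks

The morphological network regresses regional cortical thickness on
intercept, age, sex (0/1), age×sex and each subject's mean thickness, then
correlates residuals across subjects. Rank-deficient designs fail naming
the collinear covariate. The functional-style network is the
precision-matrix partial correlation (`−P_ij/√(P_ii P_jj)`), with
Ledoit-Wolf shrinkage when samples < 5 × regions and a small ridge
(1e-8 × mean diagonal) when the covariance is singular; the
microstructural-style network conditions only on the cortex-wide grand-mean
profile. Negative weights survive network construction and are zeroed by
the connectome-conditioning step, i.e. after any group averaging.

## Synthetic data

The generator emulates the study's inputs, not their exact distributions:
`distance`-style connectomes (exponential decay over mirror-symmetric 3-D
coordinates with lognormal noise) stand in for tractography/geodesic
networks, `modular` for community-structured networks, `dense-covariance`
(latent-factor correlation matrices) for morphological/microstructural
covariance. Multimodal sets share a latent backbone with a configurable
`shared_fraction` (default 0.3), each component scaled to unit mean edge
weight before mixing so the fraction is interpretable. The default world
uses the 68 real DK cortical labels (86-node variant adds 18 subcortical),
true weights (0.6, 0.2, 0.15, 0.05), a bilateral inferior-temporal seed,
generating time t* = 1 (mid-trajectory: neither seed-dominated nor
equilibrated), per-modality threshold 0.3, and observation noise sd 0.02 —
a level at which generating parameters are recoverable but fits are not
trivial. Cohorts draw i.i.d. Gaussian subject noise around the group
pattern.

What passing tests on these fixtures do **not** show: robustness to
spatially correlated measurement noise, to off-target PET binding, to
atlas misparcellation, or to connectomes whose weight distributions match
real tractography — the generator is qualitative by design.

## Numerical choices and edge cases

- Symmetry tolerance on input matrices: 1e-10 relative; asymmetric CSV
  input is symmetrised by averaging at read time, the diagonal zeroed.
- Degenerate (constant) trajectory snapshots are filled with 0.5 and
  excluded from fitting; a fit where all snapshots are degenerate fails
  loudly.
- Constant inputs to min-max scaling, zero control variance in atrophy
  scoring, and all-zero Wilcoxon differences are errors, not warnings.
- Every stochastic operation takes an integer seed; a top-level seed fans
  out to child seeds via numpy `SeedSequence` spawning, so any
  sub-computation is independently reproducible.
- Hotelling's dependent-correlation test uses the 1940 statistic with n − 3
  degrees of freedom (Williams' modification behind a flag); the effective
  n is the number of regions entering the correlations, ignoring spatial
  autocorrelation. The Wilcoxon statistic is the smaller signed-rank sum,
  exact for ≤ 25 nonzero differences.

## Known limitations

- Group-average targets only; no subject-level or longitudinal fitting.
- No accumulation/clearance/reaction dynamics (no epidemic or S-I-R
  variants).
- Undirected connectomes only.
- The GP surrogate treats the raw-weight box, not the simplex geometry;
  the normalisation makes the objective constant along rays, which wastes
  some of the surrogate's capacity but keeps the search space a box.
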