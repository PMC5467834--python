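# Methods

`roiglasso` estimates distributed EEG/MEG sources under a structural
prior: cortical activity is organised by functionally defined regions of
interest (ROIs), an ROI tends to be entirely silent or broadly active,
and the *same* ROI should be selected or rejected consistently across a
cohort of subjects. This note records the model, the synthetic data the
package is validated on, the numerical choices, and what the validation
does and does not show.

## Model

For subject k, sensor data `Y^k (N x T)` follow the linear forward model
`Y^k = F^k beta^k + eps`, with `F^k = [F_1^k ... F_R^k]` the lead field
partitioned into R ROIs and `eps ~ N(0, sigma^2 I)`. The inverse problem
is heavily underdetermined (p >> N), so estimates are regularised.

**Spatial reduction.** Forward columns vary smoothly across an ROI's
cortical patch, so each centred block `F_i^k` is effectively low rank.
The activity is constrained to the span of its top `K = 5` right singular
vectors `P_i^k` (a patch's pose has three positional plus two rotational
degrees of freedom): `beta_i^k = P_i^k b_i^k`. This smooths within an ROI
without smearing across functional borders, and replaces `F_i^k` by its
N x K principal-component scores `X_i^k = (F_i^k - col-means) P_i^k`.
The removed column means are absorbed by the intercept.

**Temporal reduction.** Activity is also restricted to the span of the
leading right singular vectors `V_d` of the sensor record, with `d` the
smallest dimension explaining 99% of its squared singular-value mass.
Because `V_d` has orthonormal columns, fitting the reduced observations
`Ytilde = Y V_d` is equivalent to fitting Y under the restriction — the
objectives differ by the constant energy outside span(V_d).

**Multi-subject stacking and the penalty.** Subject designs are stacked
block-diagonally; the group for ROI i collects that ROI's K columns from
*every* subject. The coefficients solve the matrix group elastic net

    min  1/2 ||Ytilde - 1 mu' - sum_i X_i b_i||_F^2
         + lambda sum_i gamma_i ||b_i||_F + alpha ||b||_F^2,

with `gamma_i = ||X_i||_F`. The Frobenius group penalty zeroes whole
ROI-across-subjects blocks — the pooling mechanism: an ROI weakly
supported in one subject survives if the cohort supports it, and a
spurious ROI is silenced by the cohort's collective evidence. The ridge
term stabilises coefficients among correlated lead-field columns; it is
kept fixed at `alpha = 0.01 ||X||_2^2` (spectral-norm scaled,
configurable) while lambda is searched along the path.

**Back-projection.** Vertex-space estimates are
`betahat^k = P^k btilde^k V_d'` per subject; they live in
span(P) x span(V_d) by construction, so the truth's spatial-projection
loss `||beta - P P' beta||_F^2 / (NT)` is a hard floor on any achievable
MSE (and the temporal loss is the analogous, much smaller, floor).

**Baseline.** The minimum-norm (ridge) inverse
`betahat = F'(F F' + lambda I)^{-1}(Y - 1 mu')` is computed per subject
in the original vertex space; the stacked multi-subject problem is block
diagonal and decouples, which is exactly why it cannot pool. Its ridge
grid is geometric from `s_max^2` down six decades over 50 points (s_max
the lead field's top singular value).

## Model selection

lambda is chosen by generalised cross-validation,
`GCV = (RSS/nt) / (1 - df/nt)^2`, evaluated in the space the fit was
produced in: `(N S) x d` for the group elastic net, `N x T` per subject
for the minimum norm (exact hat-matrix-trace df, intercepts included).
The two GCV curves live on different scales and are never compared with
each other. For the group elastic net, df has no closed form; the
estimator charges, per active group, d parameters for entry plus a
shrinkage fraction of the remaining block dimensions:

    df = d + sum_{i active} [ d + (||b_i|| / ||b_i^0||) (m_i d - d) ],

where `b^0` is an unpenalised reference fit on the active columns,
stabilised by a fixed ridge constant 1.0817e4 because the raw
least-squares reference on near-collinear lead-field columns is biased
downward. The shrinkage ratio is clipped to [0, 1], bounding df between
d and the active parameter count plus d. The estimator is validated
against the covariance-definition Monte-Carlo df on ridge-only problems
(within 10% over 200 noise replicates); on group-sparse fits it is
mildly conservative (it overestimates mid-path df), which errs toward
more regularised selections. Ties in the GCV minimum go to the larger
lambda.

## Synthetic data

The generator reproduces the study conditions the method was designed
for, at desk scale:

- **Geometry** — 18 named visual ROIs (V1, V2v, V2d, V3v, V3d, V4, V3A,
  LOC, MT per hemisphere) as abutting rectangular patches chained so
  that V2v and V4 are separated by V3v. Mean vertex counts 16–40 (V1
  largest; anatomical meshes have hundreds per ROI — the reduction is
  purely for runtime), jittered ±15% per subject.
- **Forwards** — `F_i = A_i S_i'` with 5 orthonormalised smooth
  low-frequency spatial fields `S_i` and Gaussian sensor patterns `A_i`;
  N = 128 sensors. 5% of Frobenius mass is unstructured roughness, so
  >99% of each centred block's variance sits in its top 5 singular
  directions. Entry RMS is ~30 (arbitrary units), which places the
  filtered designs' Gram eigenvalues in the regime where the published
  df stabiliser is a mild perturbation.
- **Cross-talk** — for each adjacent ROI pair, 2 of the 5 latent sensor
  patterns are mixed across the border with a weight drawn uniformly in
  (0.1, 0.8) *independently per subject*. Partial mixing leaves every
  ROI an identifiable subspace component (real visual areas are
  partially, not wholly, confusable), and the per-subject weights encode
  that confusability depends on idiosyncratic anatomy — the variation
  that lets a cohort settle attribution disputes no single subject can.
- **Activity** — contiguous clusters grown breadth-first over the vertex
  graph covering 30% of each active ROI (round half up, minimum one
  vertex), uniform amplitude per cluster drawn from U[1, 10], times one
  smooth unit-norm time course per active ROI: half-sine waves with
  ROI-specific phases over T = 91 samples, active across the whole
  epoch, with phases chosen off the grid's zero crossings. Two active
  ROIs give a signal of temporal rank exactly 2 (phase-shifted
  half-sines span {sin, cos}, so the rank also caps at 2 for more).
  Defaults activate V2v-L and V4-L.
- **Noise** — i.i.d. Gaussian sensor noise with sigma set so that
  Var(signal entries)/sigma^2 = 0.32 (noise three times stronger than
  signal).

**Temporal basis in simulations.** The protocol defines the SNR against
the modeled (pre-noise) sensor signal, and the temporal variance rule is
applied to that same record: with noise of this magnitude the 99% rule
on the *noisy* record would retain essentially every singular vector,
whereas on the modeled signal it recovers the signal's temporal rank —
typically d = 2 with two active ROIs (occasionally 1 when one amplitude
dominates). `stack_problem` therefore accepts the stacked modeled signal
for the basis; with real recordings one would pass the observations
themselves, which is the default.

**What the generator does not emulate:** anatomical meshes and BEM
physics (patch geometry and rank-5-plus-roughness forwards stand in for
them), correlated or non-stationary sensor noise, trial structure,
inter-ROI correlations beyond nearest-neighbour leakage, and source
orientation constraints. Passing benchmarks shows the method exploits
low-rank smooth forwards, partial cross-talk and cohort heterogeneity as
designed — not that it meets these numbers on real recordings.

## Benchmarks

`run_benchmark` simulates, for each cohort size and replicate: stack,
fit the group-elastic-net path (40 lambdas by default, geometric to
1e-3 of lambda_max), GCV-select, back-project, and score — and the same
data through the per-subject minimum norm. Replicate seeds are shared
across cohort sizes (the single subject is the first member of the
larger cohort, as when subsampling one subject pool), making cohort
contrasts paired. Scores: balanced-set AUC_close / AUC_far (per time
point on |activity|, averaged over time, then subjects), their average,
MSE `||beta - betahat||_F^2 / (NT)`, relative energy inside the truly
active set, and ROI-level AUC from sign-preserving ROI-mean time-course
energies — without averaging each subject's ROI is its own scored
instance; with averaging the cross-subject mean courses are scored (the
two coincide for S = 1). The default desk-scale profile runs 20
replicates at S in {1, 2, 4, 8}; `paper_scale=True` switches to 50
replicates and S up to 25.

Observed at desk scale (seeded, 20 replicates): pooling lifts the group
lasso's combined AUC from S=1 to S=8 by more than one standard error of
the paired difference while the decoupled minimum norm stays flat
within noise, and ROI-level AUC improves under cross-subject averaging
for both methods — with the group lasso reaching its ceiling far
earlier than the minimum norm.

## Numerical choices

- **Solver**: block coordinate descent with an exact per-group proximal
  step — eigendecomposition of the group Gram matrix plus a bracketed
  1-D root find (Brent) for the update's Frobenius norm; each block
  update is an exact minimisation, so the objective is monotone.
  Convergence requires both a full sweep with relative block changes
  below `tol` (1e-7 default) and a KKT residual below `tol` times the
  problem's correlation scale; non-convergence is reported, never
  silent. Warm starts along the decreasing lambda grid.
- **Intercepts** are profiled out by column-centring X and Y (exactly
  equivalent to joint optimisation; the ridge term does not touch the
  intercept).
- **Sign convention**: singular vectors are flipped so each column's
  largest-magnitude entry is positive, for reproducibility across
  linear-algebra backends.
- **Degenerate blocks**: K is capped at min(N-1, p_i); rank-deficient
  spatial bases are padded with an orthonormal completion and flagged
  (padded directions lie in the centred block's null space and
  contribute nothing).
- **Ties**: groups reaching the threshold simultaneously at lambda_max
  both enter; GCV ties resolve toward more regularisation.
- **Saturated fits** (df >= nt) get GCV = infinity rather than an error
  inside path sweeps.
- All randomness flows from one integer master seed through
  `numpy.random.SeedSequence` spawning (geometry, then per-subject
  forward/activity/noise streams; benchmark cells use
  `SeedSequence([master, replicate])`).

## Known limitations

- GCV targets prediction, not support recovery; with strong cross-talk
  it selects denser models than an oracle selector would, which is why
  larger cohorts help selection more than they help MSE (the MSE floor
  is set by the 5-component spatial projection, not by noise).
- The df estimator's stabiliser is a fixed published constant on the
  scale of the intended lead fields; problems at very different scales
  should override `ridge_stabilizer`.
- Overlapping ROIs and within-ROI sparsity (overlapped and sparse group
  lasso) are out of scope.
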