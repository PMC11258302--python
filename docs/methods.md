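# Methods

## Model

For each target gene g, velotf models RNA velocity from the expression of
the gene's annotated transcription factors (TFs) rather than from
spliced/unspliced read counts. Writing X ∈ R^{n_TF} for the TF abundances
and y for the target abundance, the dynamics are linear with first-order
degradation:

    dy/dt = W·X(t) − γ y(t),        γ > 0,

with a signed weight per TF (activation > 0, repression < 0). Instead of
integrating this ODE against an unknown time axis, the target's profile
over a gene-specific latent time t ∈ [0, 1) is parameterized directly as a
sine:

    y(t) = α sin(2πt + θ) + β,      α > 0, θ ∈ (−π, π), ω ≡ 2π.

The angular frequency is fixed at 2π so the profile is unimodal over one
cycle; unlike switch-time models, a sine captures dynamics that start
either with up- or down-regulation. Substituting the profile into the ODE
gives the closed form of the regulatory drive

    W·X(t) = α √(4π² + γ²) · sin(2πt + θ + φ) + βγ,   φ = arctan(2π/γ),

so a cell's state s_c = [W·X_c, y_c] lies on a closed ellipse in the phase
plane, which the drive traverses ahead of the target by the phase lead φ.
The fitting loss is the summed squared distance between observed states and
their nearest curve points,

    L = Σ_c (W·X_c − WX(t_c))² + (y_c − y(t_c))²,

with signed residuals e_c = sign(y_c − y(t_c))·‖s_c − ŝ(t_c)‖² modeled as
N(0, σ²); the corresponding Gaussian likelihood ranks genes by fit quality.

## Fitting: generalized EM

Parameters divide into three blocks — per-cell latent times t, TF weights
W, and curve shape (α, β, θ, γ) — updated in turn, each by an exact or
local constrained minimization, so the loss never increases (an
expectation–conditional-maximization scheme):

- **(a) latent times.** Grid search over 1000 equally spaced times; each
  cell takes the time of its nearest curve point (ties → smallest t).
- **(b) weights.** With t and the shape fixed, the model-side drive is a
  known vector, so W solves a box-constrained (|w_i| ≤ 20) linear least
  squares; the unconstrained normal-equations solution is used when it
  respects the box, the trust-region-reflective solver otherwise.
- **(c) shape.** Conditional on γ, the loss is *linear* least squares in
  (α cos θ, α sin θ, β) jointly over both phase-plane coordinates, so the
  block is solved globally by profiling γ over a log grid (0.05–50, 40
  points plus the current value) with bounded scalar refinement. A purely
  local shape update was found to stall in self-consistent ellipses of the
  wrong eccentricity.

Each iteration adds one further conditional pass: a joint solve of
(W, α, β, θ) with γ profiled (for fixed γ and t the whole set is one linear
least squares). Without it, the pairwise alternation of (b) and (c)
ratchets the drive amplitude and curve amplitude against each other and
needs hundreds of iterations; the joint pass converges within the default
20. All passes are loss-non-increasing, so the descent guarantee (and its
test) covers the complete iteration.

### Initialization

Correlation prior: W starts at the Spearman correlation of each TF with the
target; α and β come from the observed range of y; γ from the steady-state
relation γ = W·X/y evaluated on the top decile of y (floored at 0.01);
θ takes 4 evenly spaced starts in (−π, π).

Latent times are seeded from the data's own phase-plane geometry: the
leading principal time-courses of the TF matrix contain the shared drive,
which leads the target by φ, so pairing a drive mode with the target traces
an open ellipse whose polar angle orders the cells around the cycle. Among
the top six principal directions (orthogonalized against the target) the
quadrature mode is recognized as the one keeping the phase-plane radius
most nearly constant, and the polar angle is rank-uniformized (the ellipse
geometry warps the raw angle). Each multi-start flips the orientation of
this ordering, because a static snapshot determines the cyclic order only
up to reflection.

### Direction and model selection

The phase-portrait loss is invariant to reversing the cycle: an ellipse is
centrally symmetric, so a snapshot carries no arrow of time and the
time-reversed fit of any gene reaches essentially the same loss with a
reflected weight vector (and hence sign-flipped velocity). The direction
information lives in the biological prior already used for initialization:
activators correlate positively with their targets, repressors negatively.
Model selection therefore prefers, among the multi-start fits, those whose
weights correlate at least 0.15 with the signed TF–target correlations, and
takes the lowest loss within that pool (falling back to the global lowest
loss when no start qualifies). Genes whose fitted amplitude falls below
1e−3 are flagged low-dynamics and excluded from stream-gene selection.

Velocity is reported on the fitting scale (unit-standard-deviation
abundances) as W·X_c − γ y_c per cell; consumers needing raw units multiply
by the stored standard deviations.

## Preprocessing

Total mRNA counts (spliced + unspliced layers summed when present) are
used throughout. Genes detected (> 0) in fewer than 2% of cells are
dropped; the top 2000 genes by mean-binned normalized dispersion
(dispersion = variance/mean, z-scored within 20 mean-bins, ties broken by
gene name) are kept; each cell is scaled to the median total count. A
30-nearest-neighbor graph (Euclidean distances in the top 30 principal
components of log1p counts) supplies first-order moments: each cell's
expression is replaced by the plain mean over its neighbor set, the cell
itself included; smoothing happens on the linear normalized scale, the log
transform is used only for the graph. Per target gene, the TF set is the
prior regulators present in the data (case-insensitive symbol match),
cells with zero target expression are dropped (at least 10 must remain),
and the target and each TF row are scaled to unit standard deviation.

## Trajectory analysis

Per-gene velocities combine into a cell-to-cell transition matrix on the
same kNN graph: the weight of edge c→j is exp(cos(v_c, x_j − x_c)/0.1)
over the fitted-gene subspace, row-normalized; zero-velocity cells get
uniform rows. End cells are the top 2% of the stationary distribution of
the transition matrix (lazy power iteration, which converges on periodic
chains), root cells the same for the transposed, row-renormalized matrix.
Pseudotime is the expected number of walk steps from the root set, obtained
by truncated value iteration (500 steps) of τ = 1 + R·τ on the reversed
chain — exact hitting times are infinite whenever walker mass can avoid
the roots, which is routine on velocity graphs; truncation caps unreachable
cells, which map to pseudotime 1 after min-max scaling.

Because the sine profile is periodic, per-gene latent time is defined only
up to rotation; for stream construction it is cut at the longest run of at
least 3 empty bins in a 50-bin histogram and min-max rescaled. Stream genes
are those with mean per-cell loss in the bottom half whose normalized gene
time has Spearman correlation ≥ 0.5 with the pseudotime. Embedding arrows
are transition-probability-weighted neighbor displacements minus the
unweighted neighbor mean, so uninformative rows yield zero arrows.

## Evaluation metrics

Phase-portrait metrics standardize each coordinate by its standard
deviation: intra-class distance (squared distances of cells to their type
centroid; cohesion, lower better), inter-class distance (squared distances
between type centroids over ordered pairs; separation, higher better) and
fitting error (squared distances of cells to their matched curve points).
Stream metrics: CBDir (mean cosine between a boundary cell's velocity and
the displacements toward its annotated-next-type neighbors), ICCoh (mean
cosine between same-cluster neighbor velocities) and per-cell velocity
consistency (cosine between a cell's velocity and its neighbors' mean).
The cosine of a zero vector is defined as 0.

## Synthetic dynamics generator

The simulator provides ground truth for parameter recovery. Its defaults
define the benchmark: 200 genes × 1000 cells, 10 TFs per gene, weights
±U[0.5, 2] with at least two of each sign, γ ~ U[1, 5], targets integrated
by fixed-step RK4 (2000 steps per cycle) and observed with 10% relative
Gaussian noise. Latent time is shared across genes (uniform over the cycle;
an arc such as (0.05, 0.8) emulates a differentiation with genuine start
and end states and is used to validate pseudotime).

The trajectory design is dictated by identifiability, because several
superficially natural choices make the inverse problem ill-posed:

- **Phases couple to regulatory signs.** Activators share a gene-level
  base phase, repressors run in anti-phase (±π/12 TF jitter). With fully
  independent phases the TF design spans the same sinusoid space in either
  time direction and weight signs leave no signature in a snapshot —
  recovery would be at chance for any fitter.
- **Overtones individualize TFs.** Each TF carries harmonics of order 2–6
  (amplitude U[0.2, 0.45]·a_i, free phases) projected onto the null space
  of the true weight vector: they raise the TF design to full rank (ten
  single-frequency sinusoids span at most a 3-dim function space, leaving
  W undetermined) while cancelling exactly in the weighted drive, so the
  target still settles onto a pure sine orbit and the true parameters are
  the exact optimum. Tight phase clustering also pins γ: with looser
  phases, γ → γ′ with W → W − (γ−γ′)·X⁺y is an exact solution family.
- **Burn-in.** Integration runs three cycles before sampling so the target
  sits on its periodic orbit — the regime the sine profile describes —
  rather than on an arbitrary transient.
- **Observation noise on both sides.** The target carries 10% relative
  noise (the benchmark condition) and the observed TF trajectories 40%
  relative noise: regulator abundances are measurements, not latent
  activities, and noise-free regressors would make recovery unrealistically
  exact. These two levels are the calibrated study conditions for the
  recovery benchmark and are fixed.
- **Nonnegativity without resampling.** If the target orbit dips below a
  small floor, the baseline of the strongest activator is raised and the
  target shifted accordingly — an exact solution-preserving transform — so
  generation is deterministic.

What the generator does **not** emulate: count statistics (dropout,
negative-binomial noise, library-size variation), indirect or nonlinear
regulation, TF–TF correlation beyond the shared phase, and branching
trajectories. Passing recovery tests therefore demonstrates that the
estimator inverts its own model class under realistic noise — not that
real regulatory networks are recovered; on real data the regulatory prior
tables and the linearity assumption carry corresponding caveats.

Recovery scoring pools all genes: Spearman correlation of true vs fitted
weights (mapped back to raw scale via w_raw = w_fit·sd_y/sd_x) and of true
vs fitted per-cell velocities, plus F1 (sign of the fitted weight predicts
the sign of the true weight; positive class = activation) and AUROC (the
continuous fitted weight scores the true sign) computed by the
Mann–Whitney rank-sum identity with mid-ranks.

## Numerical choices and limitations

- Latent-time grid: 1000 points (finer than the cell count; cost is one
  matrix multiply). Assignment is exact on the grid; near the curve's
  center two branches can be almost equidistant, where grid refinement may
  legitimately switch branches.
- EM iterations: 20 (the benchmark setting), with early stop at relative
  loss change < 1e−6; the fitter is deterministic, the seed argument only
  pins any future stochastic restart strategy.
- Weight bounds ±20; γ floor 1e−6 (0.01 at initialization); θ is kept in
  (−π, π) by clamping at ±(π − 1e−6).
- Benchmark problem sizes in the test suite are scaled down (20-gene smoke
  recovery, 40-gene ablation at 400 cells, 15-gene pseudotime at 400
  cells) as the package's standard quick-validation sizes; the acceptance
  script runs the full 200 × 1000 benchmark.
- The noiseless EM plateaus around 1e−2 squared distance per cell rather
  than converging to machine zero: the fine-scale zigzag of block updates
  and the latent-time grid quantization dominate long before the recovery
  statistics are affected.
- Root/end detection reads "stationary states of the transition matrix and
  its transpose" as the top 2% of the respective stationary distributions;
  the upstream description this approximates is not fully specified, and
  on closed (cyclic) state manifolds no meaningful root exists.
- Pseudotime is normalized globally (min-max), not per branch; no fate
  probabilities or branch assignment are computed.
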