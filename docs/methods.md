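# Methods

## The model

`dtni` infers a directed gene regulatory network from expression
responses measured over both exposure **time** and **dose**.  The data
are log2 ratios x_i(t, d, c) of treated over time-matched control
expression for gene i at time t, dose d and compound c.  Two families of
linear ordinary-differential-equation constraints are imposed, sharing a
single interaction matrix A:

* **time equations** — the rate of change of each gene is a linear
  combination of the expression of all genes plus a compound-specific
  perturbation input:

      dx_i/dt (t, d, c) = Σ_j a_ij x_j(t, d, c) + b_i^c u_c(d, t)

* **dose equations** — expression also evolves with (log-)dose at fixed
  exposure time, again through the shared interactions plus an
  exposure-time term:

      dx_i/d(log10 d) (t, d, c) = Σ_j a_ij x_j(t, d, c) + h_i^c t

a_ij is the signed influence of gene j on gene i (positive = activation,
negative = inhibition); the diagonal is self-degradation and is never
reported as an edge.  The time-only system (the classic predecessor
method) is the special case without the dose block.  Multi-compound
datasets are pooled into one stacked system with one shared A; each
compound contributes its own input coefficient b^c and exposure-time
coefficient h^c.

The perturbation input u_c is a constant step of magnitude d by default;
a transient option u_c(d, t) = d·exp(−t/τ) is available.

### Derivative estimation

Dose-time designs sample sparsely and unevenly (the in vitro template is
2/8/24 h and doses at ratio 1:5:25).  Each time course and each dose
course is therefore interpolated onto a uniform grid — uniform in hours,
and uniform in log10-dose, because geometric dose designs become
equispaced there — and the derivatives entering the regressions are the
interpolant's analytic derivatives, never finite differences of raw
samples.  Courses of fewer than 5 points are interpolated exactly
(cubic, degree reduced for very short series); longer courses use a
cubic smoothing spline whose penalty is chosen by generalized
cross-validation, pooled over all genes of a course family and selected
from a fixed log-spaced grid.  Defaults: 20 grid points in time, 10 in
dose (performance saturates well below dense grids); no extrapolation
beyond the sampled range, ever.

### Weighting of the two equation blocks

The stacked regression standardizes each block by the root-mean-square
of its responses (the two blocks carry different units) **and** by the
square root of its row count, so that a block's influence on the joint
fit does not depend on how many rows the grid expansion gives it — the
number of dose-equation rows grows with the number of sampled time
points and would otherwise swamp the time equations at dense designs.
On top of this, the dose block enters at half the total weight of the
time block (`DOSE_BLOCK_WEIGHT = 0.5`): the time equations are the
generative dynamical model, while the dose equations are an auxiliary
regularity constraint whose derivatives rest on very few dose levels.

### Dimension reduction

Expression trajectories of co-regulated genes are strongly collinear.
The gene-state predictor block is reduced by SVD and the regression runs
on the top-k right singular directions; per-target coefficient vectors
are back-transformed as a_i = V_k α_i.  With `k="full"` (numerical rank)
the estimate equals the direct minimum-norm least-squares solution.  The
default `k="auto"` keeps the smallest k explaining 99.9% of the
gene-block variance: keeping near-null directions turns collinear gene
pairs into huge mutually cancelling coefficients (observed: |a| of order
10^4 on a 9-gene module whose two transcript species are nearly
proportional), which destroys edge ranking.

## Significance: residual permutation

Dose-time measurements are mutually dependent, so permuting the data is
invalid; residuals about a signal estimate are (approximately)
exchangeable and are permuted instead.  The test operates at the *data*
level and re-runs the entire pipeline — interpolation, assembly,
reduction (at the fitted k), estimation — on every pseudo-dataset.
Permuting only the derivative-level residuals while holding the
predictors fixed is measurably anticonservative (the predictors are
built from the same noisy data; in our null simulations the coefficient
null spread was underestimated almost two-fold).

Signal estimate and resampling, by data shape:

* **replicated data (R ≥ 2, the standard design)** — the signal
  estimate is the replicate mean; residual tuples (all R deviations of a
  sample cell) are transplanted between cells with replicate labels
  shuffled, plus an independent Gaussian top-up at variance σ̂²/R per
  gene.  The top-up restores the noise variance the replicate mean
  absorbs: without it the null spread of the re-estimated coefficients
  is smaller than their sampling spread and the test is anticonservative.
  σ̂² is the per-gene replicate-disagreement variance estimate.
* **unreplicated, ≥ 5 time points** — the signal estimate is the
  GCV-smoothed time course; the absorbed fraction is the smoother's
  degrees of freedom over points per course, with the analogous top-up.
* **unreplicated, < 5 time points** — residuals about an
  amplitude-calibrated reconstruction from the fitted ODE (matrix
  exponential with a stability margin on the estimated A).  This is the
  weakest scheme and is deliberately conservative.

Because the pseudo-data retain the signal estimate, the re-estimated
coefficients fluctuate around a stable centre; p-values compare the
observed |a_ij| against the centred permutation deviations
(add-one-corrected, so p ∈ [1/(n_perm+1), 1]; default n_perm = 1000).
Calibration was verified on global-null simulations: empirical type-I
error 0.03-0.04 at α = 0.05 and Kolmogorov-Smirnov distance from
uniformity ≈ 0.03 over > 1000 edge tests.

Raw permutation p-values are thresholded at α = 0.05 by default (no
multiplicity adjustment, matching how such networks are reported);
Benjamini-Hochberg is available by flag.  Edges are ranked for ROC
sweeps by p-value ascending with |strength| as tie-breaker.

**Degenerate input:** exactly noiseless replicated data (replicates
bit-identical) leave an empty residual pool; every edge then trivially
reaches the minimum p-value and the network is uninformative.  Any
nonzero noise restores a meaningful test.

### LOOCV consensus

With C ≥ 2 pooled compounds, the method is re-run on each
leave-one-compound-out subset; an edge is kept only if significant in
the full run and in *every* reduced run.  The consensus is a subset of
the full-run network by construction.  In simulation the consensus
raises PPV from ≈ 0.31 to ≈ 0.41 (6-time design); on the
information-starved 3-time anchor, where individual true edges are
barely detectable, the consensus can instead retain systematic artifacts
and *lower* PPV — a documented limitation.

## Synthetic data generators

### Linear ODE oracle

`make_linear_grn` draws a sparse signed interaction matrix, makes it
strictly diagonally dominant (hence stable), and scales it by
0.15 h⁻¹ so relaxation happens over 3-10 h — the timescale of
transcriptional responses, and the reason the 2/8/24 h design samples
where it does.  `simulate_linear` solves dx/dt = A x + b u(d) from
x(0) = 0 by matrix exponentials (exact for step inputs), giving a ground
truth correct to solver precision.  Exact recovery holds in the
identifiability regime: a per-gene perturbation panel (one compound per
gene), dense time sampling, no noise, full-rank reduction — relative
Frobenius error ≤ 1.2%, edge-ranking AUROC 1.0.  A *single* input
vector excites too few independent state directions for full recovery
no matter how densely time is sampled.

### Kinetic benchmark module

`ikb_nfkb_module` is a hand-built synthetic mass-action module — **not**
a transcription of any published model — reproducing the canonical
negative-feedback architecture of NF-kB signalling: cytoplasmic
sequestration of NF-kB by IkB, IKK-catalysed IkB degradation, nuclear
translocation, NF-kB-driven resynthesis of IkB and of the IKK inhibitor
A20, and a generic target transcript (9 species, 17 reactions).  Rates
are per hour and tuned so the response unfolds over the sampled 2-24 h
window; initial concentrations are the drug-free steady state, so
controls are stationary and log2 ratios isolate the response.  Four
drug species enter the pathway at different points (IKK induction, IkB
degradation, NF-kB induction, A20 degradation) — a synthetic stand-in
for a measured drug-reaction table.  The gold standard is the
structural Jacobian sparsity of the mass-action network: edge j → i iff
species j appears as reactant or modifier of a reaction whose net
stoichiometry changes species i.

Simulated datasets mimic the in vitro template: times (2, 8, 24) h,
doses at ratio 1:5:25, time-matched controls simulated by zeroing all
compound species, 2 replicates, and multiplicative log-normal noise
applied independently to the treated and control channel of every cell
*before* ratio formation (so log2 ratios carry noise of sd √2·σ).  The
default σ = 0.05 per channel represents moderate technical noise for
well-expressed genes; the benchmark sweeps go up to σ = 0.5.

What the generators do **not** emulate: probe-level measurement
artifacts, batch structure, shared time-matched controls across doses,
heteroscedasticity across expression levels, and biological
between-replicate variability beyond the homoscedastic noise model.
Passing benchmarks therefore demonstrate correctness of the machinery
and qualitative design effects, not field performance on real arrays.

## Evaluation protocol

`dtni.protocols` fixes the simulation studies (all desk-scale, seeds
reported, deterministic):

* **oracle recovery** — 4 runs, 5-8 genes, dense noiseless panel design.
* **null calibration** — 8 pure-noise datasets × 132 edges, n_perm=200.
* **method comparison** — kinetic anchor design (3×3, four pooled
  compounds, σ=0.05, 2 replicates), 20 seeds, n_perm=200.  The dose-time
  method beats the time-only baseline by ≈ 3-7% relative AUROC.
* **trend sweeps** — 20 seeds each: time points (3→6) and compound
  panel (1→4) at σ=0.05; dose levels (3→6→12) at σ=0.2, where the
  extra levels act as replication against noise; noise (0→0.2→0.5) and
  replicates (1→2) on the 6-time design, where there is performance to
  lose.
* **LOOCV** — 6-time, four-compound, σ=0.05, 10 seeds.

Known limitations surfaced by the protocol: at the 3-time anchor the
absolute AUROC is modest (the derivative of a quadratic through three
points is a crude estimate — with *exact* derivatives at the same three
time points the same fits reach AUROC ≈ 0.8); the α=0.05 geometric mean
peaks around 6 time points even though ranking quality (AUROC) keeps
improving through 24; and the σ=0 corner degenerates as described above.

## Numerical choices

* Stiff mass-action integration: LSODA, rtol 1e-8, atol 1e-10; ratio
  floor 1e-12 with a warning when a concentration hits it.
* SVD rank tolerance: s_max · max(m, n) · eps; `k` requests above the
  rank are clamped with a warning.
* Degenerate all-zero predictors return an all-zero model with a
  warning; numerically zero response blocks (RMS ≤ 1e-12) skip
  standardization.
* Edge order in outputs: |strength| descending, then lexicographic
  (source, target) — fully deterministic.
* One master seed per run; every random stream derives from it.
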