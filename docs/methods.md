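# Methods

## Compartment model

The receptor pool is modelled as a closed, linear, time-invariant
four-compartment system: plasma membrane (PM), Rab4⁺ sorting endosomes
(SE^Rab4), TfR-marked common recycling endosomes (RE^TfR) and Rab11⁺
recycling endosomes (RE^Rab11). Movement from donor *i* to acceptor *j* is
first order in the donor content (`J_ij = k_ij·x_i`), with exactly six
edges: the sequential loop PM→SE→RE^TfR→RE^Rab11→PM (`k01, k12, k23, k30`)
and two short-circuit returns to the PM (`k10` from SE, `k20` from RE^TfR).
No other edges are modelled, and there is no saturation, spatial structure
or ligand chemistry. The total labelled mass `x_T` is conserved exactly by
construction (the transfer-matrix columns sum to zero), and all labelled
receptor starts at the PM unless an explicit initial state is supplied.

Units are seconds and per-second throughout the library; masses are in the
arbitrary pixel-density units of the imaging assay, with the conventional
total `x_T = 2.0`. I/O accepts minute-tagged time columns (`time_min`) and
the polarized-cell compartment vocabulary (ASE/BSE, CRE, ARE) as aliases.

**Solver.** Because the system is linear and time invariant, the default
`simulate` path propagates the exact matrix exponential of the 4×4 transfer
matrix (one `expm` per distinct time step, so a uniform grid costs a single
factorisation). An implicit BDF integrator with the analytic Jacobian is
retained as `method="ivp"`; the two routes agree to better than 1e−8 on
random coefficient draws, which the test-suite checks explicitly. The exact
route is also what makes the 10⁶-point grid search affordable: grid blocks
are evaluated with a batched eigendecomposition of the transfer matrices,
with a per-row fallback to the matrix-exponential path whenever the
eigenvector matrix is near-singular or a non-finite error appears.

**Steady state and residence times.** The steady state is the unique
solution of `A·x = 0` on the conservation simplex; it requires all four
sequential coefficients positive (otherwise the loop is cut and the solver
raises a typed degeneracy error). Residence times are
`τ(i) = x_ss(i)/J_in(i)` with entering fluxes `J01, J12, J23`. For this
first-order network τ equals the reciprocal total exit rate of the
compartment, which is what the stochastic dwell-time oracle in the
test-suite verifies by simulating single-molecule sojourns.

## Fitting

The goodness of fit is `E(K) = Σ_{i=1..3} Σ_l (p(i,l) − x(i,l))²` over
replicate-averaged observations; replicates are averaged per
(compartment, time) before squaring, matching a fit to average time
courses. The model is solved exactly at the observation times, so no
interpolation error enters `E`; when a pre-computed trajectory is supplied
instead, predictions are linearly interpolated and extrapolation beyond the
trajectory is refused.

The three-stage procedure:

1. **Empirical seed `K0`** — supplied by the user (order-of-magnitude
   guesses suffice; the CLI default uses one-significant-figure scales).
2. **Grid search** — a Cartesian grid of `n_values` geometrically spaced
   values per coefficient spanning `[K0/100, 100·K0]` (10 values → 10⁶
   points). Enumeration is odometer-style over the coefficients in the
   canonical order `(k01, k12, k23, k30, k10, k20)`, ties broken by first
   occurrence; non-finite errors are excluded and counted. Because a
   geometric grid with an even number of values does not contain `K0`
   itself, the seed is kept as a fallback candidate so the staged errors
   are always monotone. Tests default to 6 values per coefficient (46,656
   points) to keep runtimes low; the 10-value design is exercised by the
   acceptance script.
3. **Steepest descent** — gradient descent on `E` over the four sequential
   coefficients only, in log-coefficient space (which enforces positivity),
   with central finite-difference gradients (step 1e−5 in log units), a
   backtracking Armijo line search that doubles the step after easy
   acceptances and halves it on non-finite errors, and termination on a
   relative `E`-improvement below 1e−10 or an exhausted line search. The
   short-circuit coefficients are held at their grid values by default:
   freeing them drives them to the non-negativity boundary on data with
   negligible short-circuit flux (the test-suite reproduces this failure
   mode), so the restricted default is the meaningful one.

**Known limitation.** The ~1.67× spacing of the 10-value grid cannot
represent arbitrary coefficient values, and the short-circuit coefficients
are only weakly constrained by the data; when the generating values fall
between grid points the grid stage tends to compensate through inflated
short circuits, which descent then inherits as fixed values, biasing the
sequential estimates by tens of percent. Recovery studies therefore place
the generating coefficients on the grid (equivalently: assume the empirical
seed was chosen well), and the acceptance script does the same. Users
fitting real data should treat the short-circuit values as
order-of-magnitude estimates.

## MCMC

Uncertainty in `(k01, k12, k23, k30)` is quantified with an adaptive
Metropolis sampler: Gaussian proposals whose covariance is initialised from
a finite-difference curvature estimate of `E` at the optimum (scaled by
2.38²/d), adapted every 200 steps during burn-in (10% of the chain) from
the running chain covariance, and frozen afterwards so the post-burn-in
chain is a proper Markov chain. The target is the likelihood of i.i.d.
Gaussian residuals with variance `σ² = E_fit/(n_obs − 4)` (fixed, not
re-estimated per step) under a flat non-negative prior. Credible intervals
are 2.5/97.5 posterior percentiles; the predictive envelope simulates the
model for up to 400 evenly spaced posterior draws and takes pointwise
2.5/97.5 percentiles per compartment. Acceptance rates outside [0.05, 0.8]
trigger a warning. With the chain seeded, all summaries are bit
reproducible; 10,000 iterations give CI endpoints within 10% of a
100,000-iteration chain on the synthetic designs tested, and a 50-repeat
frequentist study puts CI95 coverage of the generating coefficients in the
85–100% band.

## Monoexponential kinetics

Internalization and degradation are fitted with `y = y0 + A·e^(−x/t)`;
recycling with the saturating rise `y = y0 − A·e^(−x/t)` where `y0` is the
plateau (a literal growing exponential diverges and cannot describe a
plateauing assay). Fits use nonlinear least squares with `t` bounded
positive; flat series and non-positive time constants raise typed errors.
The half-time is `t½ = ln 2·t ≈ 0.693·t`, the exact form of the
conventional "69% of the decay constant". No plateau constraint is imposed
(fitted plateaus slightly above 100% are reported as-is). CI95s are
percentile bootstrap (default 2,000 resamples) over cells/replicates when
at least two are present, else over points (requiring ≥ 8); more than 20%
failed refits abort with diagnostics. Degradation band tables are
normalised as (target/control) divided by the time-0 ratio, making the
series start at 1 and invariant to common rescaling.

## Colocalization

Manders coefficients operate on pre-thresholded boolean masks:
`M_A = |A∩B|/|A|` and conversely, restricted to an ROI when given. For a
confocal stack, intersection and denominator counts are pooled across all
sections of the ROI (one cell) before dividing, giving one coefficient per
cell. An empty denominator channel yields an explicit undefined flag, never
a silent zero. A global-threshold helper (fixed value or Otsu) is shipped
for convenience but is not part of the coefficient definition, and no
segmentation, background subtraction or intensity-weighted variant is
attempted. Surface-biotinylation arithmetic follows
`(apical_s + basolateral_s) / [(apical_t + basolateral_t)/2 × 10]` (the /2
averages duplicate total determinations, the ×10 corrects a 10% lysate
aliquot) with the apical fraction `apical_s/(apical_s + basolateral_s)`.

## Synthetic data

The generator emulates the structure of the imaging assays: three
colocalization time courses sampled every 60 s over 0–2,700 s (a 45-minute
movie), six replicates, additive Gaussian noise truncated at zero with
sd 0.05 (2.5% of `x_T = 2.0`). The default ground-truth coefficients set
the sequential exit scales to exactly 1/622, 1/353 and 1/132 s⁻¹ — so the
three endosomal residence times are 622, 353 and 132 s by construction —
with small short circuits (1e−4 s⁻¹) and `k01 = 0.003975 s⁻¹`, which puts
~19% of the pool at the PM at steady state, the regime surface assays
report for a fast-recycling apical receptor. The 60-s cadence is a
placeholder for an unspecified movie frame rate. Monoexponential and mask
generators likewise return their generating parameters; mask pairs are
constructed with exact pixel counts.

What the generator does **not** emulate: correlated noise between
compartments or time points, photobleaching, focus drift, segmentation
error, cell-to-cell kinetic heterogeneity, or any spatial structure.
Passing recovery and coverage tests therefore demonstrate correctness of
the estimators under the stated noise model, not robustness to real
microscopy artefacts.

## Numerical choices and degenerate inputs

- Conservation is exact to machine precision in the closed-form solver;
  the test-suite enforces <1e−8·x_T on the numerical route.
- Grid ties resolve to the first point in enumeration order
  (`np.argmin` semantics with strict improvement across chunks).
- `steady_state`/`residence_times` refuse degenerate topologies (any
  sequential coefficient zero) with a typed error; `simulate` permits them.
- Zero-width MCMC proposals produce a frozen chain (degenerate but
  well-defined), used to test the envelope's collapse to a single
  trajectory.
- Noise truncation at zero biases generated means only where the clean
  value is near zero, by well under 3 standard errors at the default noise.
- Problem sizes in the test-suite (6-value grids, 20-repeat recovery,
  50-repeat coverage at 10,000 iterations, sub-sampled envelope draws) were
  chosen to exercise the full pipeline at desk scale; the acceptance script
  runs the full 10-value grid once.
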