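# endokin

Quantitative analysis of receptor endocytic recycling from live-imaging
colocalization data. The package is aimed at cell biologists who track a
surface-labelled receptor (for example an apical endocytic receptor such as
Megalin/LRP-2, or transferrin receptor) through the endosomal system and
want rate constants, residence times and uncertainty estimates instead of
qualitative time-lapse montages.

## The model

A labelled receptor pool of constant total mass `x_T` distributes over four
compartments — plasma membrane (PM, `x0`), Rab4⁺ sorting endosomes (`x1`),
TfR-marked common recycling endosomes (`x2`) and Rab11⁺ recycling endosomes
(`x3`). Transfer is first order in the donor content, with six edges: the
sequential loop and two short circuits back to the PM,

```
dx1/dt = k01·x0 − (k12 + k10)·x1
dx2/dt = k12·x1 − (k23 + k20)·x2
dx3/dt = k23·x2 − k30·x3
x0 + x1 + x2 + x3 = x_T
```

Each unidirectional flux is `J_ij = k_ij·x_i` (mass per second), and the
steady-state residence time in compartment *i* is `τ(i) = x_ss(i) / J_in(i)`
with entering fluxes `J01, J12, J23`.

Fitting minimises the sum of squared residuals between replicate-averaged
pixel densities `p(i, l)` and model predictions `x(i, l)` over the three
endosomal compartments,

```
E(K) = Σ_{i=1..3} Σ_l ( p(i,l) − x(i,l) )²
```

in three stages: an empirical seed `K0`; an exhaustive geometric grid of 10
values per coefficient spanning two decades either side of `K0` (10⁶
points); and steepest descent from the grid winner over the four sequential
coefficients, holding the short circuits fixed. Uncertainty in the
sequential coefficients comes from an adaptive Metropolis chain (10,000
iterations by default) under a Gaussian-residual likelihood, reported as
95% credible intervals and pointwise 95% predictive envelopes.

Around the compartment model the package provides monoexponential
endocytosis/recycling/degradation fits (`y = y0 + A·e^(−x/t)`, half-time
`t½ = ln 2 · t`), Manders colocalization coefficients on binary masks and
confocal stacks, surface-biotinylation ratio arithmetic, and seeded
synthetic-data generators with known ground truth.

## Worked example

```python
import numpy as np
import endokin as ek

K_true = ek.DEFAULT_K_TRUE
tau = ek.residence_times(K_true)
print(f"residence times (s): SE^Rab4 {tau.tau_1:.0f}, RE^TfR {tau.tau_2:.0f}, RE^Rab11 {tau.tau_3:.0f}")
ss = ek.steady_state(K_true)
print(f"steady-state PM fraction: {100 * ss[0] / ss.sum():.1f}%")

# six replicate movies, 45 min at 60-s cadence, noise sd 2.5% of the pool
obs, truth = ek.gen_timecourse(ek.GeneratorSpec(seed=7))

# three-stage fit: empirical seed -> geometric grid -> steepest descent
K0 = ek.RateCoefficientSet.from_array(K_true.as_array() * 10 ** -0.4)
fit = ek.fit_pipeline(K0, obs, n_values=6)
print(f"E: {fit.E0:.3f} -> {fit.E1:.3f} -> {fit.E_fit:.3f}")

ens = ek.run_mcmc(fit, obs, n_iter=10000, seed=7)
lo, hi = ek.credible_intervals(ens)["k30"]
print(f"k30 CI95: [{lo:.5f}, {hi:.5f}] (true {K_true.k30:.5f})")

series, _ = ek.gen_monoexp(0.19, 0.81, 1.74, "decay", n_cells=10,
                           noise_sd=0.03, seed=7)
mono = ek.fit_monoexp(series, "decay")
print(f"internalization t_half: {mono.t_half:.2f} min, plateau {100 * mono.y0:.0f}%")
```

Output:

```
residence times (s): SE^Rab4 622, RE^TfR 353, RE^Rab11 132
steady-state PM fraction: 19.0%
E: 2.395 -> 0.047 -> 0.044
k30 CI95: [0.00718, 0.00799] (true 0.00758)
internalization t_half: 1.18 min, plateau 19%
```

The residence times say the receptor dwells longest in the sorting
endosomes and shortest in the Rab11⁺ station; the error drops sharply at
the grid stage and descent polishes it; the credible interval brackets the
generating rate; and the internalization fit recovers a ~1.2-minute
half-time with ~19% of the label remaining at the surface at steady state.

A command-line interface mirrors the library
(`endokin synth|simulate|fit|mcmc|envelope|kinetics|coloc|run`); see
`endokin --help`.

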