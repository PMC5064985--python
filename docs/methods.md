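# Methods

## Model and estimation procedure

`mesens` adjusts the log hazard ratios (logHRs) of two continuous,
error-prone exposures in a Cox proportional-hazards model. The measurement
model is additive and classical: Q_i = α0_i + α1_i T_i + ε_i with errors
independent of the true exposures, possibly correlated with each other
(correlation ρ_ε). Under this structure the naive coefficients β_Q fitted to
the measurements satisfy β_Q = Λᵀ β_T with Λ = Σ_T Σ_Q⁻¹ (no systematic
bias), so the adjustment is β_T = (Λᵀ)⁻¹ β_Q.

Five ingredients are combined per Monte-Carlo iteration:

1. **β_Q draws.** Adaptive random-walk Metropolis on the Breslow-ties Cox
   partial-likelihood posterior with independent N(0, 10⁶) priors. The chain
   starts at zero; during a tuning phase the scalar step size adapts toward
   ~23 % acceptance and the proposal covariance is re-estimated from the
   second half of the tuning draws (scaled 2.38/√p), then both are frozen so
   the retained chain is Markovian. Defaults: 50,000 retained draws after
   5,000 burn-in and 5,000 tuning draws.
2. **Σ_Q draws.** The measurements are modelled bivariate normal. With a
   flat prior on the mean, marginalising it analytically gives the exact
   conjugate posterior Σ_Q | data ~ IW(Λ₀ + S, ν₀ + n − 1), with S the
   centred scatter matrix and the weakly informative prior IW(I₂, 2). This
   replaces a Metropolis chain for Σ_Q with exact draws; with cohort-scale n
   the likelihood dominates the prior either way.
3. **Validity draws.** A literature range (lower, upper) for each validity
   coefficient ρ_QiTi is interpreted as the central `ci_level` quantiles
   (default 0.90: the 0.05/0.95 quantiles) of a normal distribution on the
   Fisher-z scale; draws are tanh of normal deviates, hence inside (−1, 1).
   Non-positive draws — possible under wide priors — are rejected and
   redrawn, with the count logged. Defaults: 0.3–0.7 for the dietary
   questionnaire and 0.4–0.7 for self-reported smoking.
4. **Error-correlation draws.** No literature data exist for ρ_ε, so it is
   either fixed (sensitivity grids) or drawn uniformly over the admissible
   interval between 0 (all observed covariance from the true exposures) and
   the compatibility limit ρ_Q1Q2/√((1−ρ1²)(1−ρ2²)) (zero true-exposure
   correlation), clamped to [−1, 1]. Uniform is the maximum-entropy choice
   on a bounded interval. The limit is computed per iteration from that
   iteration's validity draws and the plug-in posterior-mean observed
   correlation, so every retained draw satisfies the covariance-conservation
   constraint.
5. **Reconstruction.** σ²_Ti = ρᵢ² σ²_Qi and
   σ_T1T2 = σ_Q1Q2 − ρ_ε σ_Q1 σ_Q2 √((1−ρ1²)(1−ρ2²)) give Σ_T, then Λ and
   the adjusted logHRs, all by closed-form 2×2 algebra vectorised over
   iterations. The univariate comparator divides each β_Qi by its
   attenuation factor ρᵢ²; the unadjusted draws pass through unchanged.

**Infeasible draws.** Iterations implying a non-positive-definite Σ_T, an
implied true-exposure correlation outside [−1, 1], or |det Λ| below 1e-10
times the product of Λ's diagonal magnitudes (separating genuine singularity
from float noise) have their validity/error-correlation draws redrawn, up to
100 attempts per slot; leftovers are dropped. The rejection rate is always
reported, and a rate above 0.5 raises an error advising that the priors are
incompatible with the observed covariance.

**Summaries.** Mean, SD, median, the (0.05, 0.95) quantile interval (a 90 %
credible interval), and the mode, estimated as the argmax of a Gaussian KDE
with Silverman bandwidth on a 512-point grid over the draw range. The mode
estimator matters: adjusted-logHR distributions are heavy-tailed because
draws with small validity multiply β_Q by large factors, so mean ≫ median ≫
mode in magnitude is common and expected.

## Systematic bias (α1 ≠ 1)

The default assumes no proportional scaling bias (α1 = 1), the usual setting
when the literature offers no information on α1. When a scaling bias is
supplied, Σ_T is built from σ_Ti = ρᵢσ_Qi/α1ᵢ and Λ generalises to
Σ_TQ Σ_Q⁻¹ with Σ_TQ[i, j] = α1ⱼ Σ_T[i, j]; this follows from the
regression-calibration identity β_Q = Σ_Q⁻¹ Cov(Q, T) β_T and is verified
against a joint-normal Monte-Carlo oracle in the test suite. The engine's
default path keeps α1 = (1, 1).

## Sensitivity grids

Three grids re-run only the combination step (the data chains are reused,
with common random numbers across cells so cells differ only through their
coordinates):

- **validity grid**: both validity coefficients fixed at grid points; the
  (1, 1) cell reproduces the unadjusted estimates exactly, since perfect
  validity forces Λ = I draw by draw.
- **error-correlation grid**: ρ_ε fixed per cell; each cell also reports the
  mean implied true-exposure correlation
  (ρ_Q1Q2 − ρ_ε√((1−ρ1²)(1−ρ2²)))/(ρ1ρ2) over retained draws.
- **ci-level grid**: the same literature limits assigned to 80/90/95/99 %
  central mass; lower levels widen the Fisher-z prior, inflating the spread
  of the adjusted estimates (dramatically so at 80 %, where near-zero
  validity draws produce extreme multipliers).

## Synthetic cohorts

The generator draws bivariate-normal true exposures, adds bivariate-normal
errors with SDs set from the target validities (σ_εi = σ_Ti√(1/ρᵢ² − 1)),
and generates event times from an exponential baseline hazard scaled by
exp(β_T·T) under independent exponential censoring — so the Cox model is
correctly specified on the true exposures and times are tie-free. Defaults
emulate the motivating cohort design on standardized exposure scales: n =
2,000, β_T = (−0.18, 0.16), validities 0.53/0.57 (the centres of the
literature ranges), true-exposure correlation 0.10, error correlation −0.05,
and baseline/censoring rates 0.03/0.07 giving ~30 % events. Under these
values the implied observed correlation is ≈ −0.005; a strongly negative
observed correlation cannot coexist with a positive true-exposure
correlation and weak negative error correlation, so the generator favours
internal consistency of the generating parameters over matching any
particular data set's observed correlation. What the generator does **not**
emulate: systematic reporting bias dependent on subject characteristics,
multiplicative error, replicate measurements (person-specific bias is not
identifiable here), non-proportional hazards, and covariates beyond the two
exposures — so passing tests demonstrate correctness of the adjustment under
its own assumptions, not robustness to their violation.

The replicated recovery experiment fits the full pipeline per simulated
cohort with validity priors degenerate at the generating values and ρ_ε
fixed at truth, and reports mean bias and the SD of the estimates per method.
At the defaults the multivariate estimator is nearly unbiased, the
univariate one retains the (small) contamination bias, and the unadjusted
one is strongly attenuated with the smallest spread.

## Numerical and design choices

- All 2×2 inversions are explicit closed forms; tests check them against
  generic linear solves at 1e-10.
- Three independent seeded streams (Cox chain, covariance draws,
  validity/error draws) derive from one master seed via `SeedSequence.spawn`
  and are paired by iteration index; identical seeds give bit-identical
  output, and output files carry the resolved configuration as a provenance
  header.
- The partial likelihood requires at least one event; the mathematical
  infeasibility guard in the cohort generator (|implied ρ_Q| ≥ 1) is
  unreachable for valid correlation inputs (Cauchy–Schwarz) and is retained
  only as a defensive check.
- Chain lengths in the test suite and acceptance script are reduced
  (1,500–10,000 retained draws) relative to the 50,000-draw defaults; the
  quantities asserted are orderings and Monte-Carlo means whose error at
  these sizes is well below the asserted margins.
- Ties are handled by the Breslow convention; the generator produces
  continuous, tie-free times, and Efron handling is out of the default path.
- Config files are YAML validated by explicit Python checks (unknown keys
  rejected) rather than a formal schema.

## Known limitations

- Exactly two exposures; k > 2 would need the general matrix path.
- The Λᵀ link between naive and true logHRs is itself an approximation in
  the Cox model (exact in linear models, accurate for modest hazard ratios);
  at the default effect sizes the residual approximation bias is within
  Monte-Carlo error.
- External validity coefficients are taken at face value up to the stated
  uncertainty; biased reference instruments in the source studies propagate
  here unexamined.
- Multiplicative error must be transformed to additive scale upstream.
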