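# mesens

Sensitivity analysis for **correlated measurement error in two exposure
variables** of a Cox proportional-hazards model, using externally reported
validity coefficients in place of internal validation data.

## The problem

In nutritional and lifestyle epidemiology, long-term exposures such as
fruit-and-vegetable intake and cigarette smoking are measured by self-report
questionnaires. Classical measurement error attenuates the log hazard ratio
(logHR) of each exposure toward zero, and — when the errors in the two
instruments are correlated — *contaminates* each coefficient with the other
exposure's error, biasing associations in either direction. The standard
remedy requires an internal validation study, which most cohorts do not have.

`mesens` implements an adjustment that replaces internal validation data with
*external* information: literature-reported ranges of the validity
coefficient ρ<sub>QT</sub> = corr(measurement, true exposure) for each
instrument, and a plausible range for the correlation between the errors.

## The model

For true exposures T₁, T₂ with Cox model
H(t | T) = H₀(t) · exp(β<sub>T₁</sub>T₁ + β<sub>T₂</sub>T₂) and additive
measurements Q<sub>i</sub> = α₀<sub>i</sub> + α₁<sub>i</sub>T<sub>i</sub> + ε<sub>i</sub>,
the naive ("unadjusted") coefficients fitted to Q relate to the true ones
through the attenuation–contamination matrix

    Λ = Σ_T Σ_Q⁻¹,        β_Q = Λᵀ β_T,   so   β_T = (Λᵀ)⁻¹ β_Q.

Σ_Q is estimable from the observed measurements; Σ_T is reconstructed from
the validity coefficients via σ²<sub>Ti</sub> = (ρ<sub>i</sub>σ<sub>Qi</sub>/α₁<sub>i</sub>)²
and the covariance split
σ<sub>T₁T₂</sub> = σ<sub>Q₁Q₂</sub> − ρ<sub>ε</sub>σ<sub>Q₁</sub>σ<sub>Q₂</sub>√((1−ρ₁²)(1−ρ₂²)).

Uncertainty is propagated by Monte Carlo: per iteration the engine pairs one
posterior draw of β_Q (adaptive Metropolis on the Breslow partial-likelihood
posterior, N(0, 10⁶) priors), one conjugate inverse-Wishart draw of Σ_Q, and
one draw of each validity coefficient from a **Fisher-z prior** whose
0.05/0.95 quantiles equal the literature limits (defaults 0.3–0.7 and
0.4–0.7), plus an error-correlation draw over its admissible range. The
output is the posterior distribution of the adjusted logHRs, alongside the
univariate comparator β<sub>Qi</sub>/ρ<sub>i</sub>² (which ignores
contamination) and the unadjusted draws.

## Worked example

Simulate a cohort with the default generating design (n = 2000, true
β_T = (−0.18, 0.16), validities 0.53/0.57, error correlation −0.05, ~30 %
deaths) and adjust it with the default literature priors:

```bash
mesens simulate --n 2000 --seed 1 --out cohort.csv
mesens adjust --data cohort.csv --seed 7 --out-dir out
```

which prints (10,000 retained draws):

```
                              mean        sd    median       q05       q95      mode
method       coefficient
multivariate exposure1   -0.193198  1.214177 -0.118420 -0.458112  0.015149 -0.069011
             exposure2    0.145583  0.193500  0.129339  0.002520  0.346522  0.097928
univariate   exposure1   -0.180797  0.684793 -0.120424 -0.454524  0.010044 -0.126801
             exposure2    0.151070  0.121860  0.132603  0.014120  0.345570  0.113901
unadjusted   exposure1   -0.034159  0.022091 -0.034067 -0.070105  0.002842 -0.026817
             exposure2    0.043317  0.024024  0.043445  0.004771  0.083073  0.048210
rejection rate: 0.0003
```

The naive fit (−0.034) understates the protective association by roughly a
factor of five; the adjusted posterior mean (−0.19) recovers the generating
value −0.18, at the price of much larger, heavy-tailed uncertainty — exactly
the qualitative behaviour the method is designed to expose. `out/` contains
the summary (CSV/JSON with a provenance header), the aligned draws, and a
run report with acceptance rates, effective sample sizes and the rejection
rate of infeasible draws.

A replicated bias comparison of the three estimators
(`mesens recover --reps 50 --n 2000 --seed 1`):

```
              bias_exposure1  bias_exposure2  sd_exposure1  sd_exposure2
method
multivariate        0.003816        0.006281      0.078093      0.055583
univariate          0.022123       -0.012810      0.076041      0.052512
unadjusted          0.135652       -0.112178      0.021360      0.017061
```

The multivariate adjustment is nearly unbiased, the univariate correction
leaves the contamination bias, and ignoring error entirely is badly biased
but deceptively precise.

The same functionality is available as sklearn-style estimators:

```python
from mesens import MeasurementErrorCoxAdjuster
est = MeasurementErrorCoxAdjuster(random_state=7).fit(X, y)  # X: (n,2) Q's
est.summary_                      # mean, sd, median, q05, q95, mode
est.sensitivity_error_corr_grid([-0.2, -0.1, 0.0, 0.1])
```

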