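# Methods

This note records the statistical model, the derivation of the closed-form
estimators, the defaults chosen where the method itself fixes none, and the
numerical decisions made in the implementation.

## Model and assumptions

Lifetimes `X > 0` follow the inverse Weibull distribution

```
G(x) = exp[ -(x σ)^(-λ) ],      g(x) = λ σ^(-λ) x^(-(λ+1)) exp[ -(x σ)^(-λ) ]
```

equivalently `Y = ln X` follows a Gumbel (maximum extreme-value)
distribution with location `μ = −ln σ` and scale `θ = 1/λ`:

```
F(y) = exp[ -e^{-(y-μ)/θ} ],    f(z) = exp(-z - e^{-z})  on the standard scale z = (y-μ)/θ
```

All estimation is done on the log scale and transformed back at the end
(`λ̂ = 1/θ̂`, `σ̂ = e^{−μ̂}`). Natural logarithms are used throughout.

**Censoring model.** A multiply type-II censored sample fixes, in advance,
the ranks `a_1 < a_2 < … < a_s` (1-based) out of `n` i.i.d. units; only the
order statistics at those ranks are observed. With `z_j` the standardized
observed log-values, the likelihood is

```
L ∝ θ^{-s} · F(z_1)^{a_1 - 1} · [1 - F(z_s)]^{n - a_s}
        · Π_j f(z_j) · Π_{j=2}^{s} [F(z_j) - F(z_{j-1})]^{a_j - a_{j-1} - 1}
```

i.e. a left-tail block, a right-tail block, the densities at the observed
points, and one probability block per unobserved interior gap. Complete
samples (`a_j = j`, `s = n`) are the special case in which the tail and gap
exponents all vanish; the same code path handles both.

## The AMLE linearization

The score equations `∂ln L/∂μ = 0` and `∂ln L/∂θ = 0` involve `e^{-z}`,
`e^{-z} z`, the hazard `f(z_s)/[1 − F(z_s)]`, and the gap ratios
`f(z_j)/[F(z_j) − F(z_{j-1})]`, none of which admit closed-form roots. Each
nonlinear term is replaced by its first-order Taylor expansion around the
plotting-position quantile

```
ξ_{a_j} = −ln(−ln p_{a_j}),      p_{a_j} = a_j/(n+1),  q_{a_j} = 1 − p_{a_j}
```

which is the standard-Gumbel quantile of the expected cdf value of the
`a_j`-th order statistic.

**The tangent line for `e^{-z}`.** The true first-order expansion is

```
e^{-z} ≈ e^{-ξ}(1 + ξ) − e^{-ξ} z
```

with constant coefficient `e^{-ξ}(1 + ξ)`. The shipped default variant,
`"derivation-consistent"`, uses this exact tangent everywhere it appears
(in `A_μ`, and in both pieces of the `θ`-equation coefficient `B_1`),
assembles `B_1` homogeneously in the residuals `w_j = y_j − μ̂`, takes the
gap-coefficient pairing `α1_j w_j − α2_j w_{j-1}`, and carries the `−Σ y`
term of `B_2` with a negative sign. A second variant, `"paper-literal"`,
retains an alternative coefficient assembly sometimes seen in typeset
presentations of this estimator — constant coefficient `e^{-ξ}(1 + ξ²)`, a
`+Σ y` sign in `B_2`, gap pairing `α1_j/γ2_j`, and a `e^{-ξ_1} ξ_1²` first
term in the `μ̂`-bracket of `B_1`. The literal assembly is not internally
consistent as a Taylor expansion and produces visibly different estimates;
it is retained only for auditing and sensitivity comparison, and
`"derivation-consistent"` is the default everywhere. The worked-example
fits shipped with the package (and asserted in the test suite to six
decimals) come from the derivation-consistent variant.

**Solving.** The linearized `μ`-score and `θ`-score are two equations
linear in `(μ, θ)`:

```
L1:  A_μ θ + B_μ − C_μ μ = 0
L2:  A_2 θ + B_2 − C_2 μ = 0
```

Eliminating `θ` gives `μ̂ = E/D` with `D = A_μ C_2 − A_2 C_μ` and
`E = A_μ B_2 − A_2 B_μ`. Substituting `μ̂` into the `θ`-score, with the
quadratic (tangent-times-`z`) treatment of `e^{-z} z` and the hazard term,
gives `s θ² + B_1 θ + C_1 = 0`, solved by the `+` branch

```
θ̂ = [ −B_1 + sqrt(B_1² − 4 s C_1) ] / (2 s)
```

Since `C_1` is typically negative the discriminant exceeds `B_1²` and the
`+` branch is positive. Estimation is sequential and non-iterative: `μ̂`
first, then `θ̂` given `μ̂`. Degenerate cases (`D = 0`, negative
discriminant, nonpositive root) raise `FitError` with diagnostics rather
than clamping — no silent fallback.

**Expansion coefficients.** The tail coefficients `κ1, δ1, κ2, δ2` are the
tangent coefficients of the hazard-type terms at `ξ_{a_s}`; the per-gap
families `(α, β, γ)_{1,2,4}` linearize the gap ratios, built on
`K_j = (f_j ξ_j − f_{j-1} ξ_{j-1})/Δp_j` with `Δp_j = p_{a_j} − p_{a_{j-1}}`
and `f_j = f(ξ_{a_j})`. They satisfy exact tangent identities, e.g.
`α1_j + β1_j ξ_j + γ1_j ξ_{j-1} = f_j/Δp_j` and `β2_j = −γ1_j`; the test
suite asserts these to 1e−10 over randomized schemes, which pins down the
coefficient algebra independently of any fitted data. Coefficients depend
only on `(n, a_1..a_s)`, so `expansion_coefficients(scheme)` can be computed
once and reused across replicates (`fit_amle(..., coeffs=...)`).

**Properties.** The estimator is exactly equivariant: shifting every
log-value by `d` shifts `μ̂` by `d` and leaves `θ̂` unchanged; equivalently
rescaling `x → c·x` maps `σ̂ → σ̂/c` and leaves `λ̂` unchanged. Against the
exact maximum likelihood estimate (obtained numerically from the full
censored likelihood), the AMLE is consistent in practice: in the shipped
simulations under the null, median `|λ̂_AMLE − λ̂_MLE|` at λ = 2 falls from
≈0.006 at n = 50 to ≈0.001 at n = 200.

## Goodness-of-fit diagnostics

Both diagnostics map a censored sample plus a parameter pair (by default
the AMLE fit, but any `IWParams` may be supplied) to a coordinate series
whose systematic departure from zero indicates misfit.

**Modified normalized sample Lorenz curve (MNSLC).** With
`r_i = 1 − G(x_{a_i}; σ̂, λ̂)` and the scaled total-time-on-test-style sums

```
MTSL(r_i) = Σ_{j≤i} (x_{a_j} − x_{a_1}) / Σ_{j≤s} (x_{a_j} − x_{a_1}) − r_i + 1
```

the plotted points are `(1 − r_i, 1 − MTSL(r_i)/MTSL_F(r_i))`, where
`MTSL_F` is the same functional evaluated on the fitted-model quantiles at
the same ranks. Both endpoints are exactly zero by construction.

**EDF-spacing plot.** With `F_j = G(x_{a_j}; σ̂, λ̂)`,

```
R_i = Σ_{j≤i} (F_j − F_1) / (F_s − F_1) + 1
P_i = Σ_{j≤i} (a_j − a_1) / (a_s − a_1) + 1
```

and the plotted points are `(a_i/(n+1), R_i/P_i − 1)`. The differences sit
*inside* the sums; this reading is forced by the requirement that data
lying exactly on the fitted plotting-position quantiles
(`F_j = a_j/(n+1)`) give `y ≡ 0`, which it does identically (the common
spacing factor cancels in the ratio). The first point is always zero.

**Shape classification.** `classify_shape(series, epsilon)` labels a
series `near_zero` if `max|y| ≤ ε`, `rise_then_fall` if the
largest-magnitude extremum is a positive interior maximum,
`fall_then_rise` if it is a negative interior minimum, and `other`
otherwise. The default `ε = 0.01` was chosen so that null-simulated
complete samples with `n ≥ 100` are predominantly classified `near_zero`
while typical alternative-family samples at the same size are not; it is a
package convention, configurable per call, not a formal critical value. No
test statistic or p-value is provided — the diagnostics are graphical, and
`null_band` (pointwise empirical envelopes under the null across seeded
replicates) is the supported way to calibrate what "near zero" means for a
given scheme.

## Simulator

`simulate_censored(spec, scheme, seed)` draws `n` i.i.d. values from the
requested family, sorts them, and keeps the order statistics at the
scheme's ranks — the exact sampling model of multiply type-II censoring.
Reproducibility contract: the same `(spec, scheme, seed)` gives bitwise
identical samples; independent replicate streams should be derived as
`np.random.default_rng([seed, r])`.

Supported families and default parameters (all overridable):

| family | defaults | rationale |
| --- | --- | --- |
| `inverse_weibull` | σ = 1, λ = 2 | null model; λ = 2 gives finite mean, moderate tail |
| `weibull` | shape 2, scale 1 | light-tailed alternative |
| `pareto` | minimum 1, index 2 | heavy-tailed alternative |
| `beta` | a = 2, b = 2 | bounded-support alternative |
| `lognormal` | log-mean 0, log-sd 0.5 | near-null alternative |
| `normal` | mean 10, sd 1 | thin-tailed alternative; draws ≤ 0 are rejected and redrawn (effective law is the positive-truncated normal) so that log-lifetimes exist |

Scope: only multiply type-II censoring is generated — no type-I, hybrid,
or progressive censoring, and no power tables or formal size/power claims.
The simulator exists for calibration (null bands) and for the qualitative
direction studies below.

## Numerical choices

- **Log-domain likelihood.** `censored_loglik` never forms tail or gap
  probabilities directly. With `t_j = e^{-z_j}`, the tail term is
  `(a_1 − 1)(−t_1)`, the upper tail uses `log(−expm1(−t_s))`, and each gap
  contributes `−t_j + log(−expm1(−(t_{j-1} − t_j)))`, so the likelihood is
  finite over the whole useful parameter range (it is used as the
  objective for the numeric MLE reference, optimized over `(μ, ln θ)` with
  Nelder–Mead).
- **Density guard.** The standard Gumbel pdf is computed as
  `exp(−z − e^{-z})` with the argument clamped only for `z < −30`, where
  the true value underflows to 0 anyway; large positive `z` needs no guard.
- **Exact root selection.** Always the `+` quadratic branch; failures
  raise, never clamp (see above).
- **Plotting positions** use `p = a/(n+1)` (the mean-rank convention);
  this is the convention under which the tangent identities and the
  perfect-fit `y ≡ 0` properties hold exactly.

## Study sizes

The replicate counts and sample sizes used in the shipped tests — e.g.
1000 replicates at n ∈ {30, 50, 100, 200} for recovery/RMSE, 100
replicates at n = 200 for the direction studies, 200 replicates for
AMLE-vs-MLE — are package conventions chosen to keep the full suite under
a few seconds while leaving wide margins on every stochastic assertion.
They are stated in the tests themselves and are not tuned to any
particular outcome.

## Known limitations

- **AMLE bias at small n.** The linearization is around expected order
  statistics, so for small `n` or very sparse schemes the AMLE can differ
  noticeably from the exact MLE (use `fit_mle_numeric` as a cross-check);
  the difference vanishes as `n` grows.
- **Rounded-input sensitivity.** The ball-bearing example illustrates that
  the fit is sensitive to input rounding: fitting the 3-decimal rounded
  inverse times instead of full-precision reciprocals moves λ̂ from
  2.121929 to 2.161319. The bundled loader therefore defaults to
  full-precision reciprocals, with `rounded=True` as a sensitivity mode.
- **Diagnostic direction claims do not all hold.** The direction of misfit
  is often described verbally as: MNSLC rises-then-falls under
  Pareto/Weibull alternatives and falls-then-rises under
  beta/lognormal/normal; EDF-spacing the reverse. Systematic checks — both
  seeded Monte-Carlo majority votes at n = 200 and noise-free
  population-level curves (exact alternative-family quantiles fed through
  the pipeline) across wide parameter grids — show that three of those ten
  claims are false for *every* parameterization tried: the Weibull
  alternative never yields a rise-then-fall MNSLC nor a fall-then-rise
  EDF-spacing curve, and the beta alternative never yields a fall-then-rise
  EDF-spacing curve. The corresponding acceptance tests are left failing on
  purpose rather than weakened; users should not rely on those three
  directions when reading the plots. The remaining directions (Pareto
  MNSLC rise-then-fall; beta/lognormal/normal MNSLC fall-then-rise;
  normal/lognormal EDF-spacing rise-then-fall) reproduce with ≥97/100
  majorities.
- **No formal inference.** No critical values, p-values, or interval
  estimates; the diagnostics are exploratory.
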