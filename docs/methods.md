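# Methods

## Model and assumptions

`sarscore` implements a score-driven location model for an `R`-vector
panel observed at `T` equally spaced times. The structural form combines
a first-order simultaneous autoregression in the response (spatial lag
`ρ1 W1 y_t`) and in the disturbances (`ρ2 W2 ε_t`) with a time-varying
signal `μ_t` and fixed effects `X_t β`:

    Z1 y_t = X_t β + μ_t + ε_t,   Z2 ε_t = η_t,   η_t ~ iid t_ν(0, Λ),

`Z1 = I − ρ1 W1`, `Z2 = I − ρ2 W2`. The weight matrices are required to be
row-stochastic with zero diagonal; this bounds their spectral radius by
one, so both filters are invertible for any `|ρ| < 1` and the reduced form
(and its von Neumann series interpretation, under which every region is
affected by every other with geometrically decaying weight) is valid.
`W` is static: neither the neighbourhood structure nor the spatial
parameters vary over time. Λ is a constant diagonal shape matrix
(`e^{2λ_r}` per region); there are no volatility dynamics.

The signal is not given a distribution of its own. Instead it follows an
observation-driven recursion, `μ_{t+1|t} = φ μ_{t|t-1} + K u_t`, whose
innovation `u_t = Z2 Z1 v_t / α_t` is proportional to the score of the
conditional log-density with respect to the location
(`∂ℓ_t/∂μ_{t|t-1} = ((ν+R)/ν) Z2' Λ⁻¹ u_t`, checked against numeric
gradients in the tests). The factor `α_t = 1 + q_t/ν`, with `q_t` the
squared Mahalanobis norm of the spatial prediction error, makes the update
robust: writing `u_t = Z2 Z1 v_t (1 − b_t)` with `b_t = 1 − 1/α_t` a
`Beta(R/2, ν/2)` variate shows that a fraction `b_t` of each prediction
error — large exactly when the error is extreme — is discarded before it
can move the signal. `u_t` is a martingale difference, and as `ν → ∞` the
filter, the density and the score all collapse to their Gaussian SARAR
counterparts.

Everything needed per step is exposed as a plain function
(`prediction_error`, `alpha_weight`, `beta_variate`, `score_innovation`,
`signal_update`, `conditional_logdensity`); `run_filter` executes the same
recursion in a numba-compiled loop so that likelihood-based Monte Carlo is
cheap, and a test pins the two routes together at 1e-10.

## Key parameters

| parameter | meaning | constraint | default used in studies |
|---|---|---|---|
| `ρ1` | spatial lag of the response | `\|ρ1\| < 1` | 0.7 |
| `ρ2` | spatial lag of the disturbances | `\|ρ2\| < 1` | 0 |
| `ν` | Student-t degrees of freedom (tail weight) | `ν > 0` | 5 |
| `λ_r` | per-region log-scale, Λ = diag(e^{2λ}) | — | 0 |
| `φ` | temporal persistence of the signal | `\|φ\| < 1` | 0.8 |
| `κ_r` | score loading of region r | `κ_r > 0` | 0.5 |
| `β` | fixed-effect coefficients (intercept first) | — | 0 |

The study values for `φ`, `ρ1`, `ρ2`, `ν` follow the parameter-recovery
design; `λ = 0`, `κ = 0.5` and an intercept-only `β = 0` were fixed once
as moderate-signal conditions (unit noise scale, signal loading half the
noise scale) and are used consistently in tests and in
`scripts/acceptance.py`.

## Simulation

`simulate_panel` iterates the exact stationary data-generating process:
`μ_{t+1} = φ μ_t + K η_t/(1 + η_t' Λ⁻¹ η_t / ν)`, `ε_t = Z2⁻¹ η_t`,
`y_t = Z1⁻¹(X_t β + μ_t + ε_t)`, with `η_t` drawn through the
normal/chi-square scale mixture. The recursion starts at `μ_0 = 0` (its
stationary mean) and discards a 500-step burn-in, long enough for the
geometric memory at `|φ| ≤ 0.9` to fade below double precision in the
discarded segment. A `gaussian` noise family replaces `η_t` by
`N(0, Λ)` draws and uses the `ν → ∞` limit of the signal update (no
winsorization); it exists for the misspecification experiment only.

What the generator emulates is the model's own probabilistic structure —
heavy-tailed, spatially filtered panels with a persistent latent location.
What it does **not** emulate are features of real recordings:
haemodynamic smoothing, scanner drift and preprocessing artefacts,
subject motion, volatility clustering, or mis-specified neighbourhoods.
Passing tests therefore certify the correctness of the implementation and
the finite-sample behaviour of the estimator *under the model*, not the
adequacy of the model for any particular dataset.

Covariate designs: intercept-only; intercept plus a fixed smooth
sinusoidal regressor; intercept plus a 0/1 boxcar switching every 20 steps
(period 40, duty cycle 0.5), mimicking a task stimulus. All designs keep
the limiting Gram matrix nonsingular.

## Estimation

The empirical likelihood is the sum of conditional log-densities along
the filter path started at `μ_{1|0} = 0`; filter invertibility (checked
empirically by `invertibility_diagnostic`, which fits the geometric decay
of initialization differences and estimates the top Lyapunov exponent of
the one-step map by central-difference Jacobian-vector products) makes the
initialization asymptotically irrelevant.

Optimization is quasi-Newton (L-BFGS-B, numerical gradients) in an
unconstrained space: `atanh` for `φ, ρ1, ρ2`, `log` for `ν` and `κ_r`,
identity for `β` and `λ`. `log ν` is bounded above by 30; a fit that hits
the bound is flagged `nu_at_bound` ("effectively Gaussian"). Default
starting values: pooled least squares for `β`, per-region log sample
standard deviations for `λ`, `ν = 10`, `φ = 0.5`, `ρ = 0`, `κ = 0.1`;
optional jittered multi-start. Convergence tolerances: relative function
1e-10, projected gradient 1e-6. Numerical failures inside a line search
return a large finite penalty rather than propagating.

Nested variants pin parts of θ (`sar_only`: ρ2 = 0; `sem_only`: ρ1 = 0;
`nonspatial`: both; `gaussian_sarar`: the static Gaussian SARAR
regression, ν = ∞, φ = 0, K = 0). The Gaussian variant and the scalar
nonspatial variant are each tested against independently coded likelihood
oracles (the determinant/quadratic-form decomposition of the Gaussian
SARAR likelihood, and a scalar dynamic-location Student-t recursion).

Standard errors are numeric: inverse Hessian of the negative
log-likelihood (central fourth-point differences, relative step 1e-4) by
default, with outer-product-of-gradients and sandwich combinations as
alternatives; per-observation score contributions come from central
differences of the per-t likelihood vector. Free-scale covariance is
delta-method mapped to the natural scale. Non-positive-definite curvature
falls back to a pseudo-inverse with a warning — this happens by design
when a direction is unidentified (e.g. `ρ` with a degenerate one-region
weight matrix). AIC/BIC use the number of free parameters of the variant.

## Detection

Activations are exceedances of the spatial residual `Z1 v̂_t` (with the
`Z2` filter applied additionally when the fitted variant has a spatial
error component) over per-region empirical quantiles of the rescaled
winsorized scores `κ̃_r û_{r,t}`, `κ̃_r = max(κ̂_r, 1)`, at
Bonferroni-corrected two-sided levels `α/(2R)` and `1 − α/(2R)`.
Quantiles use the median-unbiased interpolation rule, fixed for
reproducibility; a pooled-across-regions option exists behind a flag, but
per-region quantiles are the default because they respect heterogeneous
scales `λ_r`. The two-sided reading of the corrected level follows from
the `α/(2R)` form (a two-sided Bonferroni correction over `R`
simultaneous comparisons per time step).

Calibration depends on the tail regime. The flag rate matches the nominal
corrected mass `α/R` only when scores and residuals coincide, i.e. in the
effectively Gaussian regime — and for a multivariate t that requires
`ν ≳ 30R²`, since the first-order t-vs-normal density expansion term is
`((q² − 2Rq + R(R−2))/4ν` in the squared Mahalanobis distance `q`
(implemented as `gaussian_expansion_correction`). With genuinely heavy
tails the mean robustness weight is `E[α_t] ≈ 1 + R/(ν−2)` and residuals
systematically exceed the winsorized-score envelope; the resulting excess
flags are not false positives but the heavy-tail events the procedure is
designed to expose. The planted-outlier and calibration experiments are
therefore run at a near-Gaussian background (`ν = 10⁴` for `R = 10`),
where recall of 6-standard-deviation spikes and the Bonferroni budget are
both meaningful.

The Dice index `2|a∧b|/(|a|+|b|)` summarizes co-activation between two
binary region series; it is undefined (returned as NaN with a warning)
when both series are empty.

## Numerical choices and degenerate inputs

- All applications of `Z⁻¹` are linear solves on LU factors computed once
  per parameter value; log-determinants come from `slogdet` of the
  filters.
- The density is evaluated in log-gamma / `log1p` arithmetic, so `ν` up to
  1e12 is representable without a special Gaussian branch. For
  `ν/2 ≥ 1e7` the log-gamma difference `logΓ((ν+R)/2) − logΓ(ν/2)` is
  computed by a Stirling-based expansion in moderate-sized terms; direct
  subtraction of two ~1e9-magnitude values would lose the low-order bits
  that the Gaussian-limit agreement at `ν = 1e8` requires.
- `tanh` in the inverse reparameterization is clipped strictly inside
  (−1, 1): `tanh(25)` rounds to exactly 1.0 in double precision.
- Finite-difference step for gradient checks: `h = 1e-6 · max(1, |μ_r|)`,
  central differences.
- `R = 1` is supported with a degenerate `W = [[0]]` (the row-stochastic
  convention cannot hold for one region); the model then reduces to the
  univariate dynamic-location Student-t filter.
- Isolated regions in the fiber/distance weight construction (an all-zero
  fiber row) raise by default; an inverse-distance fallback fills the row
  on request. Row-wise normalization is used throughout: it is the unique
  scaling consistent with row-stochasticity, and within-row proportions —
  hence all downstream results — are invariant to whether one normalizes
  globally first.
- One weight matrix serves both filters by default (`W2 = W1`); two
  distinct matrices are accepted everywhere.

## Known limitations

- Standard errors rely on numeric curvature, not an analytic information
  matrix; directions that are unidentified in a given design surface as
  pseudo-inverse warnings rather than exact zeros.
- The invertibility diagnostic is a Monte-Carlo estimate along one data
  path, not a proof of contraction over the parameter space.
- Estimation treats each panel separately; there is no pooling across
  subjects.
- The Monte-Carlo studies in the test suite use lattice neighbourhoods of
  modest dimension (R = 5–10, T = 1000) — large enough for the asymptotic
  results to bite, small enough to run routinely; behaviour at much larger
  R (e.g. whole-brain parcellations) is extrapolation.
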