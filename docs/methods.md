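# Methods

This note documents the models, conventions and numerical choices
behind `emergentdrf`, and what the simulation-based tests do and do not
establish.

## The first-order severity model and its DRF

Illness severity is treated as the product of a dose term and a chain
of random cause sizes along a mode of action (MOA),
`Z = C0 · ∏_{i=1..t} C_i`.  A cause size is the magnitude of an
illness-initiating event — the fraction of a toxicant passed at an
organ, the degree of failure of a defensive mechanism.  Because each
cause scales the damage passed downstream, the kinetics are first-order
and severities multiply.  With the clinical illness definition
`Z ≥ Z* = 1` (arbitrary units), the severity per unit dose `W = Z/C0`
determines the critical dose `D = Z*/W = 1/W`: individuals with large
physiological amplification respond at small doses.  If `W` is Weibull
with shape `k` and scale `λ`, then `D = 1/W` is exactly Fréchet with
`η = k`, `ξ = 1/λ` (a change of variables; verified in the tests by
Monte-Carlo ECDF comparison).  The population DRF is the CDF of `D`.

If the log cause sizes were independent and many, `log Z` would be
asymptotically normal (CLT) and severity lognormal.  Two departures
push the distribution towards Weibull instead: the number of effective
increments along an MOA is small, and cause sizes are autocorrelated
(common causes; larger upstream failures stress downstream mechanisms
harder), both of which prevent the CLT from symmetrizing the
accumulated log severity.

## The severity-chain simulator

`simulate_chain` realizes the log cause sizes as a stationary lag-1
autoregressive process with configurable mean, standard deviation and
autocorrelation `ρ ∈ [0, 1)`.  The innovations are, by default, a
mean-centred *reflected exponential* (skewness −2): a cause modelled as
a failure fraction is bounded above by complete failure but has a long
lower tail, so its log is left-skewed.  This choice matters: a strictly
Gaussian AR(1) makes `log Z` exactly normal for every `ρ` and `t`
(linear combinations of Gaussians are Gaussian), i.e. severity exactly
lognormal, and no Weibull preference could ever emerge from it.  With
left-skewed innovations the accumulated log severity keeps a negative
skew — the Gumbel-minimum direction, which is exactly the log of a
Weibull — whenever the effective number of increments is modest.
Gaussian innovations remain available via `innovations="gaussian"`.

Consequences verified in the tests:

* `ρ = 0`, large `t` (300): `log Z` is consistent with a normal
  distribution (KS) — the lognormal limit.
* `ρ = 0.8`, moderate `t` (5): a two-parameter Weibull ML fit to `Z`
  attains higher log-likelihood than a lognormal ML fit — the Weibull
  emergence, tested as a relative-fit property because the underlying
  argument is asymptotic, not an identity.
* `Z = D·W` holds exactly per draw; raising `C0` shifts the severity
  distribution up in the first-order stochastic dominance sense.

Stationarity of the AR(1) start is enforced by a 200-step burn-in with
variance-matched initialization.  The chain parameters are user-facing
and make no claim of matching a specific biological system; the
simulator's role is to exhibit the mechanism and to generate test data.

## Response models

* Fréchet: `F(d) = exp{−[(d−d0)/ξ]^−η}` for `d > d0`, else 0.  The
  `d ≤ d0 → 0` convention is the limit of the closed form and is
  implemented without overflow (the kernel evaluates
  `exp(−exp(−η ln a))` under an errstate guard; an overflowing inner
  exponential collapses cleanly to 0).
* Backgrounds: DMB `c + (1−c)F` (an independent background pathway);
  CMB `exp{−[d_b + max((d−d0)/ξ, 0)]^−η}` (background stress on the
  scaled-dose axis, *replacing* the kernel argument rather than
  wrapping the CDF).  At their null settings (`c = 0`, `d_b = 0`) both
  reduce bitwise to the base model.
* Multistage `1 − exp(−q0 − q1 d − … − qk d^k)` (default degree 2,
  configurable) and lognormal `Φ((ln d − μ)/σ)` for comparison.  Both
  tabulated background variants of the lognormal use response mixing
  with a fraction labelled `c`; a "CMB" request for the lognormal is
  honoured with the same map (the two variants differ only in
  labelling for this family — a deliberate simplification, documented
  rather than hidden).

### Mixtures

Common mode: all stressors share one `η`; the kernel argument is
`Σ d_j/ξ_j + Σ_{j<k} ξ_{j,k}·g(d_j, d_k) − d0 + d_b` clipped at 0.
The pairwise interaction kernel `g` defaults to the geometric mean
`√(d_j d_k)`, which keeps interaction "doses" of the same order as the
scaled individual doses and vanishes when either dose is zero; the raw
product is available via `kernel="product"`.  With the published
benzene-toluene parameters (ξ₁=3, ξ₂=30, ξ₁₂=−0.095, η=1, d0=4.2) the
geometric kernel yields the observed J-shaped toluene slice at fixed
high benzene (minimum near 400 mmol/kg/d), whereas the raw product
would drive the response monotonically to zero — one reason the
geometric kernel is the default.

Dissimilar mode: per-pathway effective doses
`d′_i = max[max(d_i − d0_i, 0)/ξ_i + Σ_k ξ_{i,k}·max(g(d_i,d_k) − d0_{i,k}, 0), 0]`,
combined as the union of independent events.  The union complement is
computed in log space (`−expm1(Σ log1p(−F_i))`) because the direct
product loses union probabilities below ~1e−16 to cancellation.  Each
`d′` is fully scaled, so the per-pathway Fréchet kernels take unit
scale and zero threshold.  Pair sums run over unordered pairs counted
once.  A common-mode sub-mixture can be collapsed to a scalar dose
(`nested_common_mode_dose`) and used as one coordinate of an outer
dissimilar-mode model.  Three-way and higher interactions are out of
scope.

## Fitting and goodness of fit

Counts are moved to the plotting position
`n → min(max(0.25, n), N − 0.25)` (identity on interior counts), which
lets 0- and N-responder groups contribute to the log-likelihood-based
GOF; the adjustment can be disabled per run to mirror analyses done on
raw counts.  The deviance

`Y* = 2 Σ_i [n_i ln(n_i/(N_i p_i)) + (N_i − n_i) ln((N_i − n_i)/(N_i(1 − p_i)))]`

is minimized over the free parameters; model probabilities are clipped
to `[1e−12, 1 − 1e−12]` inside the likelihood only, never in reported
predictions.  `m` counts only free parameters; anything fixed by the
user is excluded from the degrees of freedom.

GOF is the upper-tail chi-square probability of `Y*`.  The headline
p-value uses `df = I − m − 1`, one below the likelihood-ratio
asymptotics, charging one unit for the choice of parametric form.  This
is *deliberately strict*: under the true model these p-values are
stochastically smaller than uniform.  The calibrated variant at
`df = I − m` (`gof_pvalue(..., strict=False)`, `DRFResults.p_value_lr`)
is uniform under the true model, which the calibration test verifies by
simulation (200 replicates, KS).

Optimizer: bounded L-BFGS-B over 32 scrambled-Sobol starts spanning the
(transformed) bounds, with a Nelder-Mead fallback where quasi-Newton
stalls and a final Nelder-Mead polish; strictly positive parameters
(ξ, η, σ) are optimized in log space.  Multi-start is not optional
garnish: the deviance surface can have sharp, narrow minima
(particularly for background parameters), and single-start fits miss
them.  Default bounds: ξ ∈ [1e−6, 1e8], η ∈ [0.05, 50], c ∈ [0, 0.999],
d_b ∈ [0, 1e4], thresholds ∈ [0, max dose], all configurable per free
parameter.  Fits are bitwise deterministic given data, spec and seed.
Degenerate data (single repeated dose vector, no responders anywhere)
return a best-effort result flagged `converged=False` with a
diagnostic message.  Thresholds are fixed at 0 by default and freed
explicitly when wanted.

## Synthetic data as study conditions

Simulation-based tests use an 8-dose design spanning response ≈ 0.06
to 0.95 under the generating model, N = 500 per group — a large but
realistic chronic-bioassay scale that keeps boundary counts (0 or N
responders) rare, so the plotting-position adjustment stays inactive in
calibration runs.  Parameter recovery uses 100 replicates; GOF
calibration 200.  Within-test fits use 8 optimizer restarts (the
2-parameter surface is well-behaved; 32 remains the library default).
These synthetic bioassays emulate binomial sampling at fixed doses
only: no litter effects, dose-measurement error, time-to-event
structure or inter-study heterogeneity.  Passing tests therefore
establish the correctness and calibration of the machinery, not the
biological adequacy of any particular fit to real data.

## Known limitations

* The published chloroform/bromate/2-acetylaminofluorene/benzene-toluene
  dose-response tables exist only as journal supplementary files and are
  not redistributed here; the test asserting reproduction of the
  published p-values fails by design until those tables are transcribed
  to `tests/data/` (inventing the counts would be worse).
* No confidence intervals, benchmark-dose computation, or Bayesian
  (unconditional) DRFs; no time-to-tumor modelling; saturation
  (Michaelis-Menten) kinetics at high dose are not modelled.
* Which ξ belongs to which chemical in a two-stressor table is a
  labelling choice; configs carry explicit stressor names so both
  assignments can be expressed.

## Config formats

Single stressor:

```yaml
family: frechet            # frechet | lognormal | multistage
background: {mode: DMB, c: 0.05}
params: {xi: 1.0, eta: 2.0, d0: 0.0}
fit:                       # optional; marks free parameters
  free: {xi: null, eta: null, c: [0.0, 0.5]}   # null = default bounds
```

Mixtures name their stressors; free names use the canonical flat form
(`xi_1`, `eta`, `xi_1_2`, ...) with stressors numbered in listed order:

```yaml
family: common_mode
stressors: [benzene, toluene]
kernel: geometric
params:
  xi: {benzene: 3.0, toluene: 30.0}
  eta: 1.0
  d0: 4.2
interactions:
  - {pair: [benzene, toluene], xi: -0.095}
```

Severity-chain configs list `t, dose_C0, cause_log_mean, cause_log_sd,
autocorr_rho, n_draws, seed` (and optionally `innovations`).
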